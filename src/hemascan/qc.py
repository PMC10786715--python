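"""Phenotype quality control and normalization.

The QC pipeline runs in a fixed order: (1) univariate outlier masking —
any measurement beyond ``k`` median absolute deviations (MADs) of its
column median is masked (default k=4); (2) sample-level outlier removal —
donors are projected onto two independent components per
fluorophore-channel x condition block and removed when their distance to
the componentwise-median sample is robustly extreme (default k=2.5);
(3) rank-based inverse-normal (quantile) transformation per column.
A block-wise PCA then counts how many effective independent traits the
phenotype matrix carries (components to 90% cumulative variance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .config import CHANNELS, QcParameters

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826


def mad_outlier_filter(column: np.ndarray, k: float = 4.0) -> np.ndarray:
    """Boolean mask of cells removed by the k-MAD univariate filter.

    A cell is removed iff ``|x - median| > k x MAD`` over the non-missing
    entries.  When the MAD is zero (at least half the column is tied at
    the median) nothing is removed: discrete traits are legitimate and a
    zero denominator would otherwise discard every off-median value.
    """
    x = np.asarray(column, dtype=float)
    removed = np.zeros(x.shape, dtype=bool)
    ok = ~np.isnan(x)
    if ok.sum() == 0:
        warnings.warn("all-missing column skipped by MAD filter")
        return removed
    if ok.sum() < 3:
        return removed
    med = np.median(x[ok])
    mad = np.median(np.abs(x[ok] - med))
    if mad == 0:
        return removed
    removed[ok] = np.abs(x[ok] - med) > k * mad
    return removed


def ica_sample_outlier_filter(
    submatrix: pd.DataFrame, k: float = 2.5, seed: int = 0
) -> list[str]:
    """Donors flagged as outliers in a 2-D ICA projection of one block.

    The block holds all parameters of a single fluorophore channel under a
    single condition.  Missing values are median-imputed for the
    projection only.  Each donor's Euclidean distance to the
    componentwise-median sample is computed in component space; donors
    whose distance exceeds ``median + k x 1.4826 x MAD`` of the distance
    distribution are removed.  Falls back to PCA when the block is
    rank-deficient.  Deterministic for a fixed seed.
    """
    if submatrix.shape[0] < 10 or submatrix.shape[1] < 3:
        raise ValueError(
            f"need >= 10 donors and >= 3 parameters, got {submatrix.shape}"
        )
    X = submatrix.to_numpy(dtype=float)
    med = np.nanmedian(X, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    idx = np.where(np.isnan(X))
    X[idx] = med[idx[1]]
    # standardize so no single parameter dominates the projection
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    if Xs.shape[1] < 2 or np.linalg.matrix_rank(Xs) < 2:
        warnings.warn("block rank < 2; falling back to PCA projection")
        proj = PCA(n_components=min(2, max(1, Xs.shape[1]))).fit_transform(Xs)
        if proj.shape[1] == 1:
            proj = np.hstack([proj, np.zeros_like(proj)])
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            proj = FastICA(
                n_components=2, random_state=seed, whiten="unit-variance", max_iter=500
            ).fit_transform(Xs)
    center = np.median(proj, axis=0)
    dist = np.sqrt(((proj - center) ** 2).sum(axis=1))
    d_med = np.median(dist)
    d_mad = np.median(np.abs(dist - d_med))
    thresh = d_med + k * MAD_SCALE * d_mad
    flagged = dist > thresh
    return [d for d, f in zip(submatrix.index, flagged) if f]


def quantile_transform(column: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal scores: rank r of n maps to Phi^-1((r-0.5)/n).

    Ties receive the average rank; missing values stay missing.  A
    constant column maps to all zeros with a warning.
    """
    x = np.asarray(column, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n == 0:
        return out
    vals = x[ok]
    if np.unique(vals).size < 2:
        warnings.warn("constant column: quantile transform maps all values to 0")
        out[ok] = 0.0
        return out
    ranks = stats.rankdata(vals, method="average")
    out[ok] = stats.norm.ppf((ranks - 0.5) / n)
    return out


@dataclass
class QcResult:
    """Outcome of the full QC pipeline on one wide phenotype matrix."""

    matrix: pd.DataFrame  # transformed values, outliers/removed donors as NaN
    cell_mask: pd.DataFrame  # True where a cell was masked by the MAD filter
    removed_donors: dict[str, str] = field(default_factory=dict)  # donor -> reason
    report: pd.DataFrame | None = None  # long (donor, parameter, reason)
    transform_state: str = "quantile"


def run_qc(
    wide: pd.DataFrame,
    params: QcParameters | None = None,
    conditions: list[str] | None = None,
) -> QcResult:
    """Full QC: cell-level MAD filter -> sample-level ICA filter -> quantile
    transform, in that fixed order.

    ``conditions`` delimits the fluorophore-channel x condition blocks used
    for the sample-level filter (parameter names start with
    ``<CHANNEL>_<Condition>_``); when omitted, the whole matrix is one block.
    """
    params = params or QcParameters()
    work = wide.astype(float).copy()
    records = []

    # 1. univariate MAD filter per parameter column
    mask = pd.DataFrame(False, index=work.index, columns=work.columns)
    for col in work.columns:
        removed = mad_outlier_filter(work[col].to_numpy(), params.mad_multiplier)
        mask[col] = removed
        for donor in work.index[removed]:
            records.append({"donor": donor, "parameter": col, "reason": "mad_outlier"})
    work = work.mask(mask)
    logger.info(
        "MAD filter (k=%.3g) masked %d cells", params.mad_multiplier, int(mask.values.sum())
    )

    # 2. sample-level ICA filter per (channel, condition) block
    removed_donors: dict[str, str] = {}
    blocks: list[tuple[str, pd.DataFrame]] = []
    if conditions:
        for ch in CHANNELS:
            for cond in conditions:
                prefix = f"{ch}_{cond}_"
                cols = [c for c in work.columns if c.startswith(prefix)]
                if cols:
                    blocks.append((f"{ch}:{cond}", work[cols]))
    else:
        blocks.append(("all", work))
    for name, sub in blocks:
        if sub.shape[0] < 10 or sub.shape[1] < 3:
            continue
        for donor in ica_sample_outlier_filter(
            sub, params.ica_mad_multiplier, seed=params.seed
        ):
            removed_donors.setdefault(donor, f"ica_outlier:{name}")
            records.append(
                {"donor": donor, "parameter": "*", "reason": f"ica_outlier:{name}"}
            )
    if removed_donors:
        work.loc[list(removed_donors)] = np.nan
    logger.info(
        "ICA sample filter (k=%.3g) removed %d donors",
        params.ica_mad_multiplier,
        len(removed_donors),
    )

    # 3. quantile transform per column
    for col in work.columns:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            work[col] = quantile_transform(work[col].to_numpy())

    report = pd.DataFrame(records, columns=["donor", "parameter", "reason"])
    return QcResult(matrix=work, cell_mask=mask, removed_donors=removed_donors, report=report)


@dataclass
class IndependentTraitEstimate:
    per_block: dict[str, int]
    overall: int  # maximum over blocks (conservative aggregation)
    threshold: float


def estimate_independent_traits(
    blocks: dict[str, pd.DataFrame], threshold: float = 0.90
) -> IndependentTraitEstimate:
    """Components needed to reach the cumulative explained-variance threshold.

    Each block (a mostly complete donors x parameters matrix) is
    median-imputed, centred and decomposed by PCA; the block's count is the
    smallest number of leading components whose cumulative explained
    variance reaches the threshold.  The overall estimate aggregates
    blocks by their maximum, a deliberately conservative rule since blocks
    share structure.
    """
    per_block: dict[str, int] = {}
    for name, df in blocks.items():
        if df.shape[1] < 2:
            warnings.warn(f"block {name!r} has < 2 parameters; skipped")
            continue
        X = df.to_numpy(dtype=float)
        med = np.nanmedian(X, axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        idx = np.where(np.isnan(X))
        X[idx] = med[idx[1]]
        X = X - X.mean(axis=0)
        sv = np.linalg.svd(X, compute_uv=False)
        var = sv**2
        tot = var.sum()
        if tot == 0:
            per_block[name] = 1
            continue
        cum = np.cumsum(var) / tot
        per_block[name] = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    if not per_block:
        raise ValueError("no usable blocks")
    return IndependentTraitEstimate(
        per_block=per_block, overall=max(per_block.values()), threshold=threshold
    )
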