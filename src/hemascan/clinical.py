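"""Association of evoked blood traits with clinical endpoints.

Binary diagnoses are tested with covariate-adjusted logistic regression
(Wald z test), continuous labs with ordinary least squares (t test),
following the model ``outcome ~ readout + age + race + sex + draw_time``.
False discovery is controlled with Storey q-values (pi0 estimated on a
lambda grid with a cubic smoother).  The signed score matrix
(blood traits x endpoints) can be projected onto two independent
components to map the multivariate association structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

P_FLOOR = 1e-320


@dataclass
class AssocCell:
    beta: float
    stat: float  # Wald z (binary) or t (continuous)
    p: float
    n: int
    cases: int | None = None
    flag: str = ""  # non-empty when the model failed or was skipped


def _design(readout: pd.Series, covariates: pd.DataFrame | None) -> pd.DataFrame:
    parts = [readout.rename("readout")]
    if covariates is not None and covariates.shape[1]:
        cov = covariates.copy()
        cat = cov.select_dtypes(exclude=[np.number])
        if cat.shape[1]:
            # categorical factors dummy-coded, alphabetically first level
            # as reference
            dummies = pd.get_dummies(cat, drop_first=True, dtype=float)
            cov = pd.concat([cov.select_dtypes(include=[np.number]), dummies], axis=1)
        parts.append(cov)
    X = pd.concat(parts, axis=1)
    return sm.add_constant(X, has_constant="add")


def fit_binary_assoc(
    readout: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    min_cases: int = 10,
) -> AssocCell:
    """Logistic regression of a binary outcome on a blood readout.

    Complete-case rows only; the readout coefficient is tested with a
    Wald z test.  Separation, non-convergence or a constant readout flag
    the cell with missing statistics; outcomes with fewer than
    ``min_cases`` cases are skipped.
    """
    df = pd.concat([outcome.rename("y"), readout.rename("x")], axis=1)
    if covariates is not None:
        df = pd.concat([df, covariates], axis=1)
    df = df.dropna()
    n = len(df)
    cases = int(df["y"].sum())
    if cases < min_cases or n - cases < min_cases:
        warnings.warn(f"skipping outcome with {cases} cases (< {min_cases})")
        return AssocCell(np.nan, np.nan, np.nan, n, cases, flag="too_few_cases")
    if df["x"].nunique() < 2:
        return AssocCell(np.nan, np.nan, np.nan, n, cases, flag="constant_readout")
    X = _design(df["x"], df.drop(columns=["y", "x"]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(
                df["y"].astype(float), X.astype(float), family=sm.families.Binomial()
            )
            fit = model.fit(maxiter=100)
        beta = float(fit.params["readout"])
        se = float(fit.bse["readout"])
        if not np.isfinite(beta) or not np.isfinite(se) or se > 1e4:
            return AssocCell(np.nan, np.nan, np.nan, n, cases, flag="separation")
        z = beta / se
        p = max(2 * stats.norm.sf(abs(z)), P_FLOOR)
        return AssocCell(beta, z, p, n, cases)
    except Exception as exc:  # PerfectSeparation, convergence failures
        logger.warning("binary model failed: %s", exc)
        return AssocCell(np.nan, np.nan, np.nan, n, cases, flag="fit_failed")


def fit_continuous_assoc(
    readout: pd.Series,
    lab: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> AssocCell:
    """OLS of a continuous lab on a blood readout (two-sided t test)."""
    df = pd.concat([lab.rename("y"), readout.rename("x")], axis=1)
    if covariates is not None:
        df = pd.concat([df, covariates], axis=1)
    df = df.dropna()
    n = len(df)
    if n < 3 or df["x"].nunique() < 2:
        return AssocCell(np.nan, np.nan, np.nan, n, flag="degenerate")
    X = _design(df["x"], df.drop(columns=["y", "x"]))
    fit = sm.OLS(df["y"].astype(float), X.astype(float)).fit()
    beta = float(fit.params["readout"])
    se = float(fit.bse["readout"])
    if se == 0 or not np.isfinite(se):
        # perfect fit: t diverges, p floors
        return AssocCell(beta, np.inf if beta >= 0 else -np.inf, P_FLOOR, n)
    t = beta / se
    p = max(float(fit.pvalues["readout"]), P_FLOOR)
    return AssocCell(beta, t, p, n)


# ---------------------------------------------------------------------------
# Storey q-values


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 on a lambda grid with a cubic
    smoother, evaluated at the largest lambda (Storey-Tibshirani)."""
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    coeff = np.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.polyval(coeff, lambdas.max()))
    return min(max(pi0, 1e-8), 1.0)


def storey_qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    q_i = min over p_(j) >= p_(i) of pi0 * m * p_(j) / j, monotone
    non-decreasing in p.  With fewer than 20 p-values pi0 estimation is
    unreliable; the procedure falls back to Benjamini-Hochberg (pi0 = 1)
    with a warning.  Forcing ``pi0=1`` reproduces BH exactly.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        if m < 20:
            warnings.warn("fewer than 20 p-values; using Benjamini-Hochberg (pi0=1)")
            pi0 = 1.0
        else:
            pi0 = storey_pi0(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# ICA projection of the association score matrix


@dataclass
class IcaProjection:
    coordinates: pd.DataFrame  # endpoints x 2 independent components
    loadings: pd.DataFrame  # blood traits x 2 mixing loadings
    mask: pd.DataFrame  # True where the input cell was missing (set to 0)
    seed_used: int = 0


def ica_project(
    scores: pd.DataFrame, n_components: int = 2, seed: int = 0, max_restarts: int = 5
) -> IcaProjection:
    """Project clinical endpoints into independent-component space.

    ``scores`` is the blood-trait x endpoint matrix of signed test
    statistics.  Endpoints act as samples: a fastICA fixed-point fit with
    the logcosh contrast yields per-endpoint component coordinates and a
    mixing matrix whose rows are per-trait loadings.  Missing cells are
    set to 0 (mask recorded).  Components are ordered by descending
    variance of their mixing column and sign-fixed so the
    largest-magnitude loading is positive.  Deterministic for a fixed
    seed; restarts with derived seeds on non-convergence.
    """
    if scores.shape[0] < 3 or scores.shape[1] < 3:
        raise ValueError("need at least 3 traits and 3 endpoints")
    mask = scores.isna()
    X = scores.fillna(0.0).to_numpy(dtype=float).T  # endpoints x traits

    # near-Gaussian inputs are only weakly identifiable by ICA: flag when
    # no column shows significant excess kurtosis
    if X.shape[0] >= 20:
        with np.errstate(all="ignore"):
            pk = np.array([stats.kurtosistest(col).pvalue for col in X.T])
        if np.all(pk > 0.01):
            logger.warning(
                "score matrix is close to Gaussian; ICA components weakly identifiable"
            )

    last_exc: Exception | None = None
    for attempt in range(max_restarts):
        seed_k = (seed + attempt * 7919) % (2**31)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                ica = FastICA(
                    n_components=n_components,
                    fun="logcosh",
                    whiten="unit-variance",
                    random_state=seed_k,
                    max_iter=1000,
                )
                S = ica.fit_transform(X)  # endpoints x k
            A = ica.mixing_  # traits x k
            order = np.argsort(-A.var(axis=0))
            S, A = S[:, order], A[:, order]
            for k in range(A.shape[1]):
                if A[np.argmax(np.abs(A[:, k])), k] < 0:
                    A[:, k] = -A[:, k]
                    S[:, k] = -S[:, k]
            cols = [f"IC{k+1}" for k in range(n_components)]
            return IcaProjection(
                coordinates=pd.DataFrame(S, index=scores.columns, columns=cols),
                loadings=pd.DataFrame(A, index=scores.index, columns=cols),
                mask=mask,
                seed_used=seed_k,
            )
        except ConvergenceWarning as exc:
            last_exc = exc
            continue
    raise RuntimeError(
        f"fastICA failed to converge after {max_restarts} restarts"
    ) from last_exc


def select_top_traits(results: pd.DataFrame, regions, k: int = 3) -> list[str]:
    """Per clumped region, the k traits with the smallest association p
    among its member variants; de-duplicated union across regions."""
    chosen: list[str] = []
    for region in regions:
        sub = results[results["id"].isin(region.members)]
        best = sub.groupby("trait")["p"].min().sort_values()
        for t in best.index[:k]:
            if t not in chosen:
                chosen.append(t)
    return chosen


def association_matrix(
    phenotypes: pd.DataFrame,
    clinical: pd.DataFrame,
    binary_outcomes: list[str],
    continuous_labs: list[str],
    covariates: pd.DataFrame | None = None,
    min_cases: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All traits x all endpoints association table.

    Returns the long results table and the wide signed-score matrix
    (traits x endpoints) used for the ICA projection.
    """
    rows = []
    for trait in phenotypes.columns:
        readout = phenotypes[trait]
        for outc in binary_outcomes:
            cell = fit_binary_assoc(readout, clinical[outc], covariates, min_cases)
            rows.append(
                {
                    "trait": trait,
                    "endpoint": outc,
                    "kind": "binary",
                    "beta": cell.beta,
                    "stat": cell.stat,
                    "p": cell.p,
                    "n": cell.n,
                    "cases": cell.cases,
                    "flag": cell.flag,
                }
            )
        for lab in continuous_labs:
            cell = fit_continuous_assoc(readout, clinical[lab], covariates)
            rows.append(
                {
                    "trait": trait,
                    "endpoint": lab,
                    "kind": "continuous",
                    "beta": cell.beta,
                    "stat": cell.stat,
                    "p": cell.p,
                    "n": cell.n,
                    "cases": None,
                    "flag": cell.flag,
                }
            )
    long = pd.DataFrame(rows)
    ok = long["p"].notna()
    if ok.any():
        q = np.full(len(long), np.nan)
        q[ok.to_numpy()] = storey_qvalues(long.loc[ok, "p"].to_numpy())
        long["q"] = q
    else:
        long["q"] = np.nan
    wide = long.pivot(index="trait", columns="endpoint", values="stat")
    return long, wide
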