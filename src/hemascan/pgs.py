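"""Polygenic scores and delayed-entry survival analysis.

Scores are built by clumping and thresholding: association summary
statistics are LD-clumped on a reference panel (p1=0.5, r2=0.5, 100 kb by
default) and lead variants with p below the scoring threshold (0.1)
retain their per-dose betas as weights.  Disease outcomes are encoded as
counting-process records with delayed entry: subjects enter the risk set
at their first observed visit; diagnoses recorded within one year of
entry, and undated problem-list diagnoses, are treated as "instant
events" that occurred between birth and entry.  Cox proportional-hazards
models (Efron ties) and left-truncation-aware Kaplan-Meier curves come
from lifelines; per-cohort log hazard ratios are pooled with a REML
random-effects meta-analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import optimize, stats

from .config import PgsConfig, ScanConfig, SurvivalConfig
from .genotypes import GenotypeMatrix
from .gwas import clump

P_FLOOR = 1e-320


# ---------------------------------------------------------------------------
# Clumping + thresholding PGS


@dataclass
class PgsWeights:
    trait: str
    weights: pd.DataFrame  # columns: id, effect_allele, weight, p
    params: PgsConfig
    dropped: pd.DataFrame | None = None  # variants dropped at matching


def build_pgs(
    sumstats: pd.DataFrame,
    reference: GenotypeMatrix,
    params: PgsConfig | None = None,
    trait: str | None = None,
) -> PgsWeights:
    """Clumping-and-thresholding weights for one trait.

    ``sumstats`` needs columns id, chrom, pos, ref, alt, beta, p (the alt
    allele is the dosage/effect allele).  Variants absent from the
    reference panel or with mismatched alleles are dropped with a report.
    Clumping runs at (clump_p1, clump_r2, clump_kb) on reference LD; lead
    variants with p < score_p keep their scan betas as weights.
    """
    params = params or PgsConfig()
    trait = trait or (
        str(sumstats["trait"].iloc[0]) if "trait" in sumstats.columns else "trait"
    )
    ref_v = reference.variants.set_index("id")
    dropped_rows = []
    keep_rows = []
    for row in sumstats.itertuples(index=False):
        if row.id not in ref_v.index:
            dropped_rows.append({"id": row.id, "reason": "absent_from_reference"})
            continue
        ref_row = ref_v.loc[row.id]
        if str(row.ref) != str(ref_row["ref"]) or str(row.alt) != str(ref_row["alt"]):
            dropped_rows.append({"id": row.id, "reason": "allele_mismatch"})
            continue
        keep_rows.append(row)
    stats_df = pd.DataFrame(keep_rows)
    dropped = pd.DataFrame(dropped_rows, columns=["id", "reason"])

    if stats_df.empty:
        warnings.warn("no variants matched the reference panel")
        return PgsWeights(trait, _empty_weights(), params, dropped)

    # reuse the association clumper at the PGS thresholds; all hits carry
    # the same trait so the multi-trait support rule is disabled here
    clump_cfg = ScanConfig(
        significance=params.clump_p1,
        clump_r2=params.clump_r2,
        clump_kb=params.clump_kb,
        min_supporting_traits=1,
    )
    stats_df = stats_df.assign(trait=trait)
    regions = clump(stats_df, reference, clump_cfg)
    leads = {r.lead for r in regions}
    sel = stats_df[stats_df["id"].isin(leads) & (stats_df["p"] < params.score_p)]
    weights = pd.DataFrame(
        {
            "id": sel["id"].to_numpy(),
            "effect_allele": sel["alt"].to_numpy(),
            "weight": sel["beta"].to_numpy(dtype=float),
            "p": sel["p"].to_numpy(dtype=float),
        }
    )
    if weights.empty:
        warnings.warn(f"no variants passed the scoring threshold for {trait}")
        weights = _empty_weights()
    if weights["id"].duplicated().any():
        raise ValueError("duplicate variant ids in PGS weights")
    return PgsWeights(trait, weights.reset_index(drop=True), params, dropped)


def _empty_weights() -> pd.DataFrame:
    return pd.DataFrame(columns=["id", "effect_allele", "weight", "p"])


def score(genotypes: GenotypeMatrix, weights: PgsWeights | pd.DataFrame) -> pd.DataFrame:
    """Additive PGS per subject: sum of weight x dosage.

    Weights are oriented to the effect allele (dosages flipped to
    ``2 - dose`` when the effect allele is the reference allele); missing
    dosages are imputed to twice the effect-allele frequency of the
    scoring cohort.  Returns raw and z-scaled scores.
    """
    w = weights.weights if isinstance(weights, PgsWeights) else weights
    ids = list(genotypes.variants["id"])
    ref_alleles = dict(zip(ids, genotypes.variants["ref"]))
    alt_alleles = dict(zip(ids, genotypes.variants["alt"]))
    cols, wvec = [], []
    for row in w.itertuples(index=False):
        if row.id not in alt_alleles:
            continue
        j = ids.index(row.id)
        if str(row.effect_allele) == str(alt_alleles[row.id]):
            cols.append((j, False, float(row.weight)))
        elif str(row.effect_allele) == str(ref_alleles[row.id]):
            cols.append((j, True, float(row.weight)))
    if not cols:
        raise ValueError("no overlapping variants between weights and genotypes")
    G = np.empty((genotypes.n_donors, len(cols)))
    wvec = np.empty(len(cols))
    for k, (j, flip, wt) in enumerate(cols):
        d = genotypes.dosages[:, j]
        if flip:
            d = 2.0 - d
        freq = np.nanmean(d) / 2.0 if np.any(~np.isnan(d)) else 0.0
        d = np.where(np.isnan(d), 2.0 * freq, d)
        G[:, k] = d
        wvec[k] = wt
    raw = G @ wvec
    sd = raw.std(ddof=0)
    scaled = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    return pd.DataFrame(
        {"score": raw, "score_scaled": scaled}, index=genotypes.donors
    )


# ---------------------------------------------------------------------------
# Survival encoding


def encode_survival(
    records: pd.DataFrame, instant_window: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counting-process (start, stop, event] encoding with the instant-event
    rule.

    Input rows carry ``donor, entry_age, diagnosis_age, censor_age,
    problem_list_only``.  Encodings:

    * diagnosis at or after entry + window -> (entry, diagnosis, 1), normal;
    * diagnosis within the window of entry -> (0, entry, 1), instant_event
      (the event is taken to have occurred between birth and entry);
    * undated problem-list diagnosis -> (0, entry, 1), problem_list_interval;
    * no diagnosis -> (entry, censor, 0), censored.

    Rows whose stop would not exceed their start are dropped with a
    report; every input row lands in exactly one of output or report.
    """
    req = {"donor", "entry_age", "diagnosis_age", "censor_age", "problem_list_only"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    ages = records[["entry_age", "diagnosis_age", "censor_age"]].to_numpy(dtype=float)
    if np.nanmin(ages) < 0:
        raise ValueError("negative ages in survival records")
    out_rows, drop_rows = [], []
    for row in records.itertuples(index=False):
        entry = float(row.entry_age)
        dx = float(row.diagnosis_age) if pd.notna(row.diagnosis_age) else np.nan
        if bool(row.problem_list_only):
            rec = (0.0, entry, 1, "problem_list_interval")
        elif np.isfinite(dx):
            if dx < entry + instant_window:
                rec = (0.0, entry, 1, "instant_event")
            else:
                rec = (entry, dx, 1, "normal")
        else:
            rec = (entry, float(row.censor_age), 0, "censored")
        start, stop, event, reason = rec
        base = {"donor": row.donor, "start": start, "stop": stop, "event": event,
                "reason": reason}
        if "outcome" in records.columns:
            base["outcome"] = row.outcome
        if stop <= start:
            base["drop_reason"] = "nonpositive_interval"
            drop_rows.append(base)
        else:
            out_rows.append(base)
    cols = ["donor", "start", "stop", "event", "reason"]
    if "outcome" in records.columns:
        cols.append("outcome")
    encoded = pd.DataFrame(out_rows, columns=cols)
    dropped = pd.DataFrame(drop_rows, columns=cols + ["drop_reason"])
    return encoded, dropped


# ---------------------------------------------------------------------------
# Cox with delayed entry


def cox_delayed_entry(
    records: pd.DataFrame,
    covariate_cols: list[str],
    min_events: int = 2,
) -> pd.DataFrame:
    """Counting-process Cox proportional-hazards fit.

    ``records`` carries start/stop/event plus the covariate columns
    (typically sex, the first two genotype PCs and the scaled PGS).
    Risk sets honour delayed entry (subject at risk for start < t <= stop);
    ties are handled with Efron's method.  Returns one row per covariate
    with log HR, SE, z and p.
    """
    n_events = int(records["event"].sum())
    if n_events < min_events:
        raise ValueError(f"need >= {min_events} events, got {n_events}")
    df = records[["start", "stop", "event"] + covariate_cols].astype(float).dropna()
    for col in covariate_cols:
        sub = df[df["event"] == 1]
        if sub[col].nunique() == 1 and df[col].nunique() > 1:
            warnings.warn(f"covariate {col!r} has events in a single level; "
                          "monotone likelihood possible")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(
                df,
                duration_col="stop",
                event_col="event",
                entry_col="start",
            )
        except Exception as exc:
            raise RuntimeError(
                f"Cox fit failed to converge ({exc}); n={len(df)}, events={n_events}"
            ) from exc
    out = pd.DataFrame(
        {
            "covariate": cph.params_.index,
            "log_hr": cph.params_.to_numpy(),
            "se": cph.standard_errors_.to_numpy(),
        }
    )
    out["z"] = out["log_hr"] / out["se"]
    out["p"] = np.clip(2 * stats.norm.sf(np.abs(out["z"])), P_FLOOR, 1.0)
    return out


def km_quartiles(
    records: pd.DataFrame,
    scores: pd.Series,
    config: SurvivalConfig | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Left-truncation-aware Kaplan-Meier curves by score quartile.

    Cut points sit at the 0.25/0.5/0.75 score quantiles, ties assigned to
    the lower stratum.  Each stratum's product-limit estimator counts a
    subject at risk at t when start < t <= stop.  Returns the per-stratum
    survival curves and the per-subject quartile labels.
    """
    config = config or SurvivalConfig()
    if len(records) < 8:
        raise ValueError("need at least 8 subjects for quartile stratification")
    s = scores.reindex(records["donor"]).to_numpy(dtype=float)
    cuts = np.quantile(s[~np.isnan(s)], config.quartile_probs)
    stratum_idx = np.array([int(np.sum(v > cuts)) for v in s])
    labels = pd.Series(
        [f"Q{k+1}" for k in stratum_idx], index=records.index, name="quartile"
    )
    if len(set(stratum_idx)) == 1:
        warnings.warn("identical scores: a single stratum covers all subjects")
    curves: dict[str, pd.DataFrame] = {}
    for q in sorted(set(stratum_idx)):
        sub = records[stratum_idx == q]
        if sub.empty:
            warnings.warn(f"empty stratum Q{q+1}; curve omitted")
            continue
        km = KaplanMeierFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km.fit(
                durations=sub["stop"],
                event_observed=sub["event"],
                entry=sub["start"],
                label=f"Q{q+1}",
            )
        curves[f"Q{q+1}"] = km.survival_function_
    return curves, labels


# ---------------------------------------------------------------------------
# REML random-effects meta-analysis


@dataclass
class MetaResult:
    estimates: np.ndarray
    ses: np.ndarray
    pooled: float
    pooled_se: float
    tau2: float
    z: float
    p: float
    q: float | None = None


def _reml_nll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return 0.5 * (
        np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
    )


def meta_random_effects(estimates, ses) -> MetaResult:
    """Random-effects pooling of per-cohort log hazard ratios.

    The between-study variance tau^2 maximizes the restricted likelihood
    (bounded below at 0); the pooled estimate is the inverse-variance
    weighted mean with weights 1/(SE^2 + tau^2).  Identical studies give
    tau^2 = 0 and pool to the common value; with tau^2 = 0 the pooled SE
    never exceeds the smallest per-study SE.
    """
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(ses, dtype=float) ** 2
    if y.size < 1:
        raise ValueError("need at least one study")
    if np.any(np.asarray(ses, dtype=float) <= 0):
        raise ValueError("standard errors must be > 0")
    if y.size == 1:
        tau2 = 0.0
    else:
        hi = max(10.0 * float(np.var(y, ddof=1) if y.size > 1 else 1.0), 1e-6)
        res = optimize.minimize_scalar(
            _reml_nll, bounds=(0.0, hi), args=(y, v), method="bounded",
            options={"xatol": 1e-12},
        )
        tau2 = max(float(res.x), 0.0)
        if _reml_nll(0.0, y, v) <= _reml_nll(tau2, y, v):
            tau2 = 0.0
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    z = pooled / pooled_se
    p = max(2 * stats.norm.sf(abs(z)), P_FLOOR)
    return MetaResult(
        estimates=y, ses=np.asarray(ses, dtype=float), pooled=pooled,
        pooled_se=pooled_se, tau2=tau2, z=float(z), p=float(p),
    )


def meta_table(results: dict[str, MetaResult]) -> pd.DataFrame:
    """Forest-plot-ready table with one pooled row per model plus q-values."""
    from .clinical import storey_qvalues

    rows = []
    for name, r in results.items():
        rows.append(
            {
                "model": name,
                "pooled_log_hr": r.pooled,
                "se": r.pooled_se,
                "ci_low": r.pooled - 1.96 * r.pooled_se,
                "ci_high": r.pooled + 1.96 * r.pooled_se,
                "tau2": r.tau2,
                "z": r.z,
                "p": r.p,
                "n_studies": r.estimates.size,
            }
        )
    df = pd.DataFrame(rows)
    if len(df) >= 1:
        df["q"] = storey_qvalues(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# CKD staging


def ckd_stage_from_egfr(egfr: float) -> str | None:
    """CKD stage from eGFR (ml/min/1.73 m^2): 45-59 -> 3a, 30-44 -> 3b,
    15-29 -> 4, <15 -> 5, >= 60 -> None.  Band edges are inclusive at the
    lower bound."""
    if egfr < 0:
        raise ValueError("eGFR must be >= 0")
    if egfr >= 60:
        return None
    if egfr >= 45:
        return "3a"
    if egfr >= 30:
        return "3b"
    if egfr >= 15:
        return "4"
    return "5"
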