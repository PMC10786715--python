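"""Simulation benchmarks that exercise every pipeline stage against known
ground truth.

Each function generates its own synthetic inputs from a seed, runs one
method, and returns the measured quantities (coverage rates, calibration
fractions, recovered effects).  They are deliberately self-contained so a
single script can re-derive the package's headline numbers from scratch.
"""

from __future__ import annotations

import time
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clinical import storey_qvalues
from .config import (
    CausalEffect,
    OutcomeEffect,
    PipelineConfig,
    QcParameters,
    ScanConfig,
    SimulationConfig,
)
from .gating import default_gate_definitions, default_ratio_definitions, featurize
from .genotypes import GenotypeMatrix
from .gwas import association_scan, clump, hwe_exact_test, king_kinship
from .pgs import cox_delayed_entry, encode_survival, meta_random_effects, score
from .qc import ica_sample_outlier_filter, mad_outlier_filter, quantile_transform
from .simulate import DonorState, simulate_events, simulate_genotypes


def _child(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31)


# ---------------------------------------------------------------------------
# 1. gating / featurization recovery


def ne2_fraction_recovery(
    seed: int,
    weights: tuple[float, ...] = (0.05, 0.25, 0.5),
    n_events: int = 10_000,
    repeats: int = 200,
) -> dict:
    """Coverage of the NE2/NE4 estimate within the 3-sigma binomial band.

    All WDF mass sits on the neutrophil gates; per repeat the estimator
    must land within 3 sqrt(w(1-w)/N_NE) of the configured NE2 fraction w.
    """
    out = {}
    for w in weights:
        cfg = SimulationConfig(
            n_donors=2, n_variants=1, events_per_sample=n_events,
            conditions=["Pam3CSK4_19h"], seed=0,
        )
        for g in cfg.gate_templates:
            if g.channel != "WDF":
                continue
            if g.name == "NE2":
                g.weights["Pam3CSK4_19h"] = w
            elif g.name in ("NE1", "NE3"):
                g.weights["Pam3CSK4_19h"] = (1 - w) / 2
            else:
                g.weights["Pam3CSK4_19h"] = 0.0
        gates = default_gate_definitions(cfg.gate_templates)
        ratios = default_ratio_definitions()
        hits = 0
        for r in range(repeats):
            cfg.seed = _child(seed, hash((round(w * 100), r)) % 65_536)
            state = DonorState("D0", 0, 0.0, {}, {})
            wdf = [t for t in simulate_events(state, "Pam3CSK4_19h", cfg)
                   if t.channel == "WDF"]
            row = featurize(wdf, gates, ratios)
            est = row["WDF_Pam3CSK4_19h_NE2/NE4"]
            n_ne = sum(row[f"WDF_Pam3CSK4_19h_{g}_Count"] for g in ("NE1", "NE2", "NE3"))
            tol = 3 * np.sqrt(w * (1 - w) / n_ne)
            hits += abs(est - w) <= tol
        out[w] = hits / repeats
    return out


# ---------------------------------------------------------------------------
# 2. QC filters


def mad_filter_benchmark(
    seed: int, n_clean: int = 10_000, n_outliers: int = 20, displacement: float = 10.0
) -> dict:
    """Planted-outlier recovery for the 4-MAD univariate filter.

    Clean cells are bounded (uniform) measurement noise; outliers are
    displaced by ``displacement`` column-MADs.
    """
    rng = np.random.default_rng(_child(seed, 1))
    clean = rng.uniform(-1.0, 1.0, n_clean)
    mad = np.median(np.abs(clean - np.median(clean)))
    col = np.concatenate([clean, np.median(clean) + displacement * mad
                          * rng.choice([-1, 1], n_outliers)])
    removed = mad_outlier_filter(col, k=4.0)
    fn = int(n_outliers - removed[n_clean:].sum())
    fp = int(removed[:n_clean].sum())
    return {"false_negatives": fn, "false_positive_rate": fp / n_clean}


def ica_filter_benchmark(
    seed: int, repeats: int = 40, n_donors: int = 200, n_params: int = 8,
    displacement: float = 20.0,
) -> dict:
    """Detection rate of a donor displaced ``displacement`` column-s.d."""
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(repeats):
            rng = np.random.default_rng(_child(seed, 100 + r))
            X = rng.standard_normal((n_donors + 1, n_params))
            X[0] = displacement
            df = pd.DataFrame(X, index=[f"D{i}" for i in range(n_donors + 1)])
            removed = ica_sample_outlier_filter(df, k=2.5, seed=_child(seed, 200 + r))
            hits += "D0" in removed
    return {"detection_rate": hits / repeats}


# ---------------------------------------------------------------------------
# 3. association-scan calibration and power


def scan_null_calibration(seed: int, n_donors: int = 2_000, n_variants: int = 5_000) -> dict:
    """Fraction of null p-values below 0.05 over independent variants."""
    cfg = SimulationConfig(
        n_donors=n_donors, n_variants=n_variants, ld_rho=0.0,
        maf_range=(0.1, 0.5), seed=_child(seed, 2),
    )
    gm = simulate_genotypes(cfg)
    rng = np.random.default_rng(_child(seed, 3))
    y = pd.Series(
        quantile_transform(rng.standard_normal(n_donors)), index=gm.donors
    )
    res = association_scan(y, gm)
    return {"fraction_p_below_05": float((res["p"] < 0.05).mean())}


def scan_power_benchmark(
    seed: int, repeats: int = 50, n_donors: int = 2_000, maf: float = 0.3,
    beta: float = 0.5,
) -> dict:
    """Detection and estimation of an injected per-allele effect."""
    detected = within = 0
    betas = []
    for r in range(repeats):
        rng = np.random.default_rng(_child(seed, 300 + r))
        g = rng.binomial(2, maf, n_donors).astype(float)
        y_raw = beta * g + rng.standard_normal(n_donors)
        y = pd.Series(quantile_transform(y_raw), index=[f"D{i}" for i in range(n_donors)])
        variants = pd.DataFrame(
            {"chrom": "1", "pos": [1000], "id": ["v0"], "ref": "A", "alt": "G"}
        )
        gm = GenotypeMatrix(g[:, None], list(y.index), variants)
        row = association_scan(y, gm).iloc[0]
        # the rank-normal transform rescales the trait to unit variance, so
        # compare against the effect on that scale
        beta_scaled = beta / np.sqrt(beta**2 * 2 * maf * (1 - maf) + 1.0)
        detected += row["p"] < 5e-8
        within += abs(row["beta"] - beta_scaled) <= 3 * row["se"]
        betas.append(row["beta"])
    return {
        "detection_rate": detected / repeats,
        "within_3se_rate": within / repeats,
        "mean_beta": float(np.mean(betas)),
    }


# ---------------------------------------------------------------------------
# 4. oracle equivalences


def oracle_equivalences(seed: int) -> dict:
    """Max deviations between each implementation and an independent oracle."""
    rng = np.random.default_rng(_child(seed, 4))
    out = {}

    # scan vs closed-form least squares
    n, m = 50, 20
    d = rng.binomial(2, rng.uniform(0.2, 0.5, m), size=(n, m)).astype(float)
    variants = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, m + 1) * 1000,
         "id": [f"v{j}" for j in range(m)], "ref": "A", "alt": "G"}
    )
    gm = GenotypeMatrix(d, [f"D{i}" for i in range(n)], variants)
    y = pd.Series(rng.standard_normal(n), index=gm.donors)
    res = association_scan(y, gm)
    worst = 0.0
    for j in range(m):
        D = np.column_stack([np.ones(n), d[:, j]])
        bhat, *_ = np.linalg.lstsq(D, y.to_numpy(), rcond=None)
        resid = y.to_numpy() - D @ bhat
        se = np.sqrt(resid @ resid / (n - 2) * np.linalg.inv(D.T @ D)[1, 1])
        worst = max(worst, abs(res["beta"].iloc[j] - bhat[1]), abs(res["se"].iloc[j] - se))
    out["scan_vs_ols_max_abs_diff"] = float(worst)

    # q-values vs Benjamini-Hochberg at pi0 = 1
    p = rng.uniform(size=500)
    q = storey_qvalues(p, pi0=1.0)
    order = np.argsort(p, kind="mergesort")
    bh = np.minimum.accumulate((p[order] * len(p) / np.arange(1, len(p) + 1))[::-1])[::-1]
    bh_full = np.empty_like(bh)
    bh_full[order] = np.minimum(bh, 1.0)
    out["qvalue_vs_bh_max_abs_diff"] = float(np.max(np.abs(q - bh_full)))

    # delayed-entry Cox vs standard Cox at zero entries
    from lifelines import CoxPHFitter

    n2 = 300
    x = rng.standard_normal(n2)
    t = rng.exponential(np.exp(-0.5 * x))
    c = rng.exponential(1.5, n2)
    df = pd.DataFrame(
        {"start": 0.0, "stop": np.minimum(t, c) + 1e-9,
         "event": (t <= c).astype(int), "x": x}
    )
    fit = cox_delayed_entry(df, ["x"]).set_index("covariate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = CoxPHFitter().fit(df[["stop", "event", "x"]], "stop", "event")
    out["cox_delayed_vs_standard_max_abs_diff"] = float(
        max(abs(fit.loc["x", "log_hr"] - std.params_["x"]),
            abs(fit.loc["x", "se"] - std.standard_errors_["x"]))
    )

    # PGS scoring vs brute-force dot product
    gm2 = GenotypeMatrix(d, gm.donors, variants)
    w = pd.DataFrame({"id": variants["id"], "effect_allele": "G",
                      "weight": rng.standard_normal(m)})
    s = score(gm2, w)["score"].to_numpy()
    out["score_vs_dot_max_abs_diff"] = float(
        np.max(np.abs(s - d @ w["weight"].to_numpy()))
    )

    # HWE exact test vs enumeration for totals <= 10
    import math

    def enum(n_aa, n_ab, n_bb):
        ntot = n_aa + n_ab + n_bb
        rare = 2 * min(n_aa, n_bb) + n_ab
        if rare == 0:
            return 1.0
        probs = {}
        for h in range(rare + 1):
            if (rare - h) % 2:
                continue
            hom_r = (rare - h) // 2
            hom_c = ntot - h - hom_r
            if hom_r < 0 or hom_c < 0:
                continue
            probs[h] = (math.comb(ntot, hom_r) * math.comb(ntot - hom_r, h)
                        * 2**h / math.comb(2 * ntot, rare))
        tot = sum(probs.values())
        return min(1.0, sum(v for v in probs.values()
                            if v <= probs[n_ab] * (1 + 1e-12)) / tot)

    worst = 0.0
    for total in range(1, 11):
        for n_aa in range(total + 1):
            for n_ab in range(total - n_aa + 1):
                n_bb = total - n_aa - n_ab
                worst = max(worst, abs(hwe_exact_test(n_aa, n_ab, n_bb)
                                       - enum(n_aa, n_ab, n_bb)))
    out["hwe_vs_enumeration_max_abs_diff"] = float(worst)
    return out


# ---------------------------------------------------------------------------
# 5. survival recovery and kinship


def survival_recovery_benchmark(
    seed: int, n: int = 5_000, log_hr: float = 0.3
) -> dict:
    """Delayed-entry Cox recovery of a binary-covariate log hazard ratio
    under the instant-event encoding (Weibull onset, ~20% instant events)."""
    rng = np.random.default_rng(_child(seed, 5))
    x = rng.integers(0, 2, n).astype(float)
    onset = 85.0 * (rng.exponential(1.0, n) / np.exp(log_hr * x)) ** (1 / 6.0)
    entry = rng.uniform(40, 60, n)
    censor = entry + rng.uniform(10, 25, n)
    dx = np.where(onset <= entry, entry + rng.uniform(0, 0.9, n),
                  np.where(onset <= censor, onset, np.nan))
    rec = pd.DataFrame(
        {"donor": [f"D{i}" for i in range(n)], "entry_age": entry,
         "diagnosis_age": dx, "censor_age": censor, "problem_list_only": False,
         "x": x}
    )
    enc, _ = encode_survival(rec)
    events = enc[enc["event"] == 1]
    enc = enc.merge(rec[["donor", "x"]], on="donor")
    fit = cox_delayed_entry(enc, ["x"]).set_index("covariate")
    b, se = float(fit.loc["x", "log_hr"]), float(fit.loc["x", "se"])
    return {
        "log_hr_estimate": b,
        "se": se,
        "abs_bias_over_se": abs(b - log_hr) / se,
        "instant_event_share": float((events["reason"] != "normal").mean()),
    }


def kinship_benchmark(seed: int, n_sites: int = 10_000) -> dict:
    rng = np.random.default_rng(_child(seed, 6))
    maf = rng.uniform(0.1, 0.5, n_sites)
    a = rng.binomial(2, maf).astype(float)
    b = rng.binomial(2, maf).astype(float)
    return {
        "duplicate_phi": float(king_kinship(a, a)),
        "unrelated_abs_phi": float(abs(king_kinship(a, b))),
    }


# ---------------------------------------------------------------------------
# 6. meta-analysis


def meta_benchmark(seed: int) -> dict:
    identical = meta_random_effects([0.2, 0.2], [0.05, 0.05])
    hetero = meta_random_effects([0.1, 0.9], [0.02, 0.02])
    return {
        "identical_pooled": identical.pooled,
        "identical_tau2": identical.tau2,
        "hetero_tau2": hetero.tau2,
        "hetero_pooled": hetero.pooled,
    }


# ---------------------------------------------------------------------------
# 7. end-to-end demo determinism


def demo_config(seed: int) -> PipelineConfig:
    return PipelineConfig(
        simulation=SimulationConfig(
            n_donors=200,
            n_variants=500,
            events_per_sample=2_000,
            conditions=["baseline", "Pam3CSK4_19h", "LPS_18h"],
            causal_effects=[
                CausalEffect(50, "Pam3CSK4_19h", "NE2", 1.0),
                CausalEffect(51, "Pam3CSK4_19h", "NE2", 0.8),
                CausalEffect(300, "LPS_18h", "RET1", 1.0),
            ],
            outcome_effects=[
                OutcomeEffect("tone", "T2D", 0.3),
                OutcomeEffect("NE2_Pam3CSK4_19h", "CKD", -0.2),
            ],
            latent_noise_sd=0.5,
        ),
        seed=seed,
    )


def demo_determinism(seed: int, outdir: str) -> dict:
    """Run the demo pipeline twice and compare output checksums."""
    import json
    import os

    from .pipeline import run_pipeline

    t0 = time.time()
    r1 = run_pipeline(demo_config(seed), os.path.join(outdir, "run1"))
    first = time.time() - t0
    r2 = run_pipeline(demo_config(seed), os.path.join(outdir, "run2"))
    m1 = json.load(open(r1.manifest_path))["files"]
    m2 = json.load(open(r2.manifest_path))["files"]
    regions = pd.read_csv(
        os.path.join(outdir, "run1", "clump", "regions.tsv"), sep="\t"
    )
    return {
        "byte_identical": m1 == m2,
        "first_run_seconds": first,
        "n_clumped_regions": len(regions),
        "n_output_files": len(m1),
    }
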