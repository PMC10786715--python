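"""Variant QC, covariate-adjusted linear association scans and LD clumping.

The scan regresses each (quantile-transformed) trait on allele dosage plus
variance-standardized covariates, one variant at a time, reporting the
per-dose effect, its standard error and a two-sided t-test p-value.
Significant variants are grouped by greedy LD clumping (r^2 and distance
thresholds) and a clumped region is only reported when at least two
distinct traits support it; the lead variant is the member with the
smallest p-value across all traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ScanConfig
from .genotypes import GenotypeMatrix

P_FLOOR = 1e-320  # guard against p-value underflow


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg test (Wigginton et al. construction).

    Sums the probabilities of all heterozygote counts that are no more
    likely than the observed one, conditional on the allele counts.
    Monomorphic sites return 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotype")
    rare = 2 * min(n_aa, n_bb) + n_ab
    if rare == 0:
        return 1.0

    # P(het = h | allele counts) satisfies a two-term recurrence; fill the
    # whole distribution starting from the mode for numerical stability.
    probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    # downward: het -> het - 2
    h = mid
    while h > 1:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    # upward: het -> het + 2
    h = mid
    while h <= rare - 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
    total = probs.sum()
    obs_het = n_ab
    p = probs[probs <= probs[obs_het] * (1 + 1e-12)].sum() / total
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# KING-robust kinship


def king_kinship(dosages_i: np.ndarray, dosages_j: np.ndarray) -> float:
    """KING-robust kinship coefficient between two individuals.

    phi = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j)) over jointly
    non-missing hard-called genotypes, where N_Aa,Aa counts
    double-heterozygote sites, N_AA,aa opposite-homozygote sites and
    N_Aa(.) heterozygous sites per individual.  Duplicate samples give
    0.5, unrelateds 0 in expectation.  Missing (NaN) when neither
    individual is heterozygous at any joint site.
    """
    gi = _hard_call(np.asarray(dosages_i, dtype=float))
    gj = _hard_call(np.asarray(dosages_j, dtype=float))
    ok = ~np.isnan(gi) & ~np.isnan(gj)
    gi, gj = gi[ok], gj[ok]
    if gi.size < 100:
        warnings.warn(
            f"only {gi.size} jointly observed sites; kinship estimate unstable"
        )
    het_het = np.sum((gi == 1) & (gj == 1))
    opp_hom = np.sum(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0)))
    denom = np.sum(gi == 1) + np.sum(gj == 1)
    if denom == 0:
        warnings.warn("zero heterozygote denominator; kinship undefined")
        return np.nan
    return float((het_het - 2.0 * opp_hom) / denom)


def _hard_call(d: np.ndarray) -> np.ndarray:
    out = np.full_like(d, np.nan)
    ok = ~np.isnan(d)
    out[ok] = np.where(d[ok] < 0.5, 0.0, np.where(d[ok] < 1.5, 1.0, 2.0))
    return out


def kinship_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """All-pairs KING-robust kinship via indicator matrix products."""
    calls = gm.hard_calls()
    M = (~np.isnan(calls)).astype(float)
    A1 = np.where(np.nan_to_num(calls, nan=-1.0) == 1.0, 1.0, 0.0)
    A0 = np.where(np.nan_to_num(calls, nan=-1.0) == 0.0, 1.0, 0.0)
    A2 = np.where(np.nan_to_num(calls, nan=-1.0) == 2.0, 1.0, 0.0)
    het_het = A1 @ A1.T
    opp = A0 @ A2.T + A2 @ A0.T
    het_i = A1 @ M.T  # het sites of i jointly observed with j
    denom = het_i + het_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (het_het - 2.0 * opp) / denom
    return phi


# ---------------------------------------------------------------------------
# Variant / sample QC


@dataclass
class QcReport:
    variant_exclusions: pd.DataFrame  # columns: id, reason
    donor_exclusions: pd.DataFrame  # columns: donor, reason


def variant_qc(
    gm: GenotypeMatrix,
    config: ScanConfig | None = None,
    check_kinship: bool = True,
    sample_missingness_ceiling: float = 0.10,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop variants and donors failing the scan thresholds.

    Variants fail on missingness, Hardy-Weinberg deviation, MAF or MAC;
    donors fail on call-rate or on kinship above the ceiling (one member
    of each flagged pair — the one with the higher missingness — is
    removed).  Every exclusion is listed exactly once with its reason.
    """
    config = config or ScanConfig()
    gm = GenotypeMatrix(gm.dosages.copy(), list(gm.donors), gm.variants.copy())
    gm.recompute_summaries()
    v = gm.variants
    v_records = []
    drop_v = np.zeros(gm.n_variants, dtype=bool)
    checks = [
        (v["missing_rate"].to_numpy() > config.missingness_ceiling, "missingness"),
        (v["hwe_p"].to_numpy() < config.hwe_p_floor, "hwe"),
        (v["maf"].to_numpy() < config.maf_floor, "maf"),
        (v["mac"].to_numpy() < config.mac_floor, "mac"),
    ]
    for mask, reason in checks:
        newly = mask & ~drop_v
        for vid in v.loc[newly, "id"]:
            v_records.append({"id": vid, "reason": reason})
        drop_v |= mask

    d_records = []
    drop_d = np.zeros(gm.n_donors, dtype=bool)
    donor_miss = np.mean(np.isnan(gm.dosages[:, ~drop_v]), axis=1) if (~drop_v).any() else np.zeros(gm.n_donors)
    for i in np.where(donor_miss > sample_missingness_ceiling)[0]:
        d_records.append({"donor": gm.donors[i], "reason": "sample_missingness"})
        drop_d[i] = True

    if check_kinship and gm.n_donors >= 2 and (~drop_v).any():
        sub = gm.subset(np.where(~drop_d)[0], np.where(~drop_v)[0])
        phi = kinship_matrix(sub)
        miss = np.mean(np.isnan(sub.dosages), axis=1)
        n = sub.n_donors
        flagged = set()
        iu, ju = np.triu_indices(n, k=1)
        with np.errstate(invalid="ignore"):
            hits = np.where(phi[iu, ju] > config.kinship_ceiling)[0]
        for k in hits:
            i, j = int(iu[k]), int(ju[k])
            if i in flagged or j in flagged:
                continue
            # remove the member with higher missingness (ties: second member)
            victim = i if miss[i] > miss[j] else j
            flagged.add(victim)
        for i in sorted(flagged):
            d_records.append({"donor": sub.donors[i], "reason": "kinship"})
            drop_d[gm.donors.index(sub.donors[i])] = True

    report = QcReport(
        variant_exclusions=pd.DataFrame(v_records, columns=["id", "reason"]),
        donor_exclusions=pd.DataFrame(d_records, columns=["donor", "reason"]),
    )
    out = gm.subset(np.where(~drop_d)[0], np.where(~drop_v)[0])
    out.recompute_summaries()
    return out, report


def genotype_pcs(gm: GenotypeMatrix, n_pcs: int = 10) -> pd.DataFrame:
    """Genotype principal components by SVD of centred, frequency-standardized
    dosages (missing set to the frequency mean).  Sign-fixed so each PC's
    largest-magnitude donor loading is positive."""
    freq = gm.allele_frequencies()
    sd = np.sqrt(np.maximum(2 * freq * (1 - freq), 1e-12))
    Z = (np.nan_to_num(gm.dosages - 2 * freq, nan=0.0)) / sd
    Z = Z - Z.mean(axis=0)
    n_pcs = min(n_pcs, min(Z.shape) - 1) if min(Z.shape) > 1 else 1
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    pcs = U[:, :n_pcs] * S[:n_pcs]
    for k in range(pcs.shape[1]):
        if pcs[np.argmax(np.abs(pcs[:, k])), k] < 0:
            pcs[:, k] = -pcs[:, k]
    return pd.DataFrame(
        pcs, index=gm.donors, columns=[f"PC{k+1}" for k in range(pcs.shape[1])]
    )


# ---------------------------------------------------------------------------
# Association scan


def _covariate_design(
    covariates: pd.DataFrame | None, index: pd.Index
) -> tuple[np.ndarray, list[str]]:
    """Intercept + variance-standardized covariates, categoricals dummy-coded;
    collinear columns dropped with a warning."""
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((len(index), 1)), ["const"]
    cov = covariates.loc[index]
    num = cov.select_dtypes(include=[np.number])
    cat = cov.select_dtypes(exclude=[np.number])
    parts = [num]
    if cat.shape[1]:
        parts.append(pd.get_dummies(cat, drop_first=True, dtype=float))
    X = pd.concat(parts, axis=1)
    arr = X.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    arr = (arr - mean) / sd
    names = ["const"] + list(X.columns)
    design = np.column_stack([np.ones(arr.shape[0]), arr])
    # drop collinear columns by pivoted rank check
    q, r = np.linalg.qr(design)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping collinear covariates: {dropped}")
        design = design[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    return design, names


def association_scan(
    trait: pd.Series,
    gm: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    trait_name: str | None = None,
) -> pd.DataFrame:
    """Per-variant OLS of a trait on allele dosage plus covariates.

    Uses Frisch-Waugh-Lovell residualization: trait and dosages are
    projected off the covariate design once, then each variant reduces to
    a one-parameter regression; estimates, standard errors and t-test
    p-values are algebraically identical to the full multiple regression.
    Variants with missing dosages are refit on their complete rows.
    Returns one row per variant: trait, chrom, pos, id, ref, alt, n, beta,
    se, t, p (NaN for skipped variants).
    """
    trait_name = trait_name or (trait.name if trait.name is not None else "trait")
    trait = trait.reindex(gm.donors)
    y_all = trait.to_numpy(dtype=float)
    base_ok = ~np.isnan(y_all)
    if covariates is not None:
        cov = covariates.reindex(gm.donors)
        base_ok &= ~cov.isna().any(axis=1).to_numpy()
    else:
        cov = None
    idx = np.where(base_ok)[0]
    donors_used = pd.Index([gm.donors[i] for i in idx])
    y = y_all[idx]
    if len(idx) < 3:
        res = gm.variants[["chrom", "pos", "id", "ref", "alt"]].copy()
        res.insert(0, "trait", trait_name)
        for k in ("n", "beta", "se", "t", "p"):
            res[k] = 0 if k == "n" else np.nan
        return res
    X, _ = _covariate_design(cov, donors_used) if cov is not None else (
        np.ones((len(idx), 1)),
        ["const"],
    )
    p_cov = X.shape[1]
    G = gm.dosages[idx, :]

    n_var = gm.n_variants
    out = {
        "beta": np.full(n_var, np.nan),
        "se": np.full(n_var, np.nan),
        "t": np.full(n_var, np.nan),
        "p": np.full(n_var, np.nan),
        "n": np.zeros(n_var, dtype=int),
    }

    # hat projection off the covariates (thin QR)
    Q, _ = np.linalg.qr(X)
    y_res = y - Q @ (Q.T @ y)
    yy = float(y_res @ y_res)

    no_miss = ~np.isnan(G).any(axis=0)
    if no_miss.any():
        Gc = G[:, no_miss]
        G_res = Gc - Q @ (Q.T @ Gc)
        gg = np.einsum("ij,ij->j", G_res, G_res)
        gy = y_res @ G_res
        df = len(y) - p_cov - 1
        valid = (gg > 1e-12) & (df > 0)
        beta = np.where(valid, gy / np.where(gg > 0, gg, 1.0), np.nan)
        rss = np.maximum(yy - beta**2 * gg, 0.0)
        sigma2 = rss / max(df, 1)
        se = np.sqrt(np.where(valid, sigma2 / np.where(gg > 0, gg, 1.0), np.nan))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / se
        pvals = np.clip(2 * stats.t.sf(np.abs(tstat), df), P_FLOOR, 1.0)
        cols = np.where(no_miss)[0]
        out["beta"][cols] = np.where(valid, beta, np.nan)
        out["se"][cols] = se
        out["t"][cols] = tstat
        out["p"][cols] = np.where(valid, pvals, np.nan)
        out["n"][cols] = len(y)

    for j in np.where(~no_miss)[0]:
        g = G[:, j]
        ok = ~np.isnan(g)
        n_used = int(ok.sum())
        if n_used < p_cov + 2:
            continue
        Xj = X[ok]
        Qj, _ = np.linalg.qr(Xj)
        yr = y[ok] - Qj @ (Qj.T @ y[ok])
        gr = g[ok] - Qj @ (Qj.T @ g[ok])
        gg = float(gr @ gr)
        dfj = n_used - p_cov - 1
        if gg <= 1e-12 or dfj <= 0:
            continue
        beta = float(yr @ gr) / gg
        rss = max(float(yr @ yr) - beta**2 * gg, 0.0)
        se = np.sqrt(rss / dfj / gg)
        tstat = beta / se if se > 0 else np.inf * np.sign(beta)
        pval = max(2 * stats.t.sf(abs(tstat), dfj), P_FLOOR)
        out["beta"][j], out["se"][j], out["t"][j], out["p"][j] = beta, se, tstat, pval
        out["n"][j] = n_used

    res = gm.variants[["chrom", "pos", "id", "ref", "alt"]].copy()
    res.insert(0, "trait", trait_name)
    for k in ("n", "beta", "se", "t", "p"):
        res[k] = out[k]
    return res


def scan_traits(
    traits: pd.DataFrame,
    gm: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stacked association results across all trait columns."""
    frames = [
        association_scan(traits[c], gm, covariates, trait_name=c)
        for c in traits.columns
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# LD clumping with multi-trait support


@dataclass
class ClumpedRegion:
    lead: str
    lead_trait: str
    lead_p: float
    members: list[str]
    supporting_traits: set[str] = field(default_factory=set)
    chrom: str = ""
    span: tuple[int, int] = (0, 0)


def ld_r2(gm: GenotypeMatrix, id_i: str, id_j: str) -> float:
    ids = list(gm.variants["id"])
    gi = gm.dosages[:, ids.index(id_i)]
    gj = gm.dosages[:, ids.index(id_j)]
    ok = ~np.isnan(gi) & ~np.isnan(gj)
    if ok.sum() < 2:
        return np.nan
    r = np.corrcoef(gi[ok], gj[ok])[0, 1]
    return float(r**2) if np.isfinite(r) else np.nan


def clump(
    results: pd.DataFrame,
    gm: GenotypeMatrix,
    config: ScanConfig | None = None,
) -> list[ClumpedRegion]:
    """Greedy LD clumping of significant associations across traits.

    Repeatedly takes the unassigned significant variant with the smallest
    p (ties broken by position) as an index, assigns all unassigned
    significant variants within ``clump_kb`` and with genotype r^2 above
    ``clump_r2`` to its region, then discards regions supported by fewer
    than ``min_supporting_traits`` distinct traits.  The lead variant is
    the member with the minimum p across all traits.
    """
    config = config or ScanConfig()
    sig = results[results["p"] < config.significance].copy()
    if sig.empty:
        return []
    var_ids = list(gm.variants["id"])
    var_pos = dict(zip(gm.variants["id"], gm.variants["pos"]))
    var_chrom = dict(zip(gm.variants["id"], gm.variants["chrom"]))

    # per significant variant: best p across traits
    best = (
        sig.sort_values(["p", "pos", "trait"]).groupby("id", sort=False).first()
    )
    unassigned = set(best.index)
    # trait support per variant (significant hits only)
    support: dict[str, set[str]] = {
        vid: set(sub["trait"]) for vid, sub in sig.groupby("id")
    }

    dist_limit = config.clump_kb * 1000.0
    regions: list[ClumpedRegion] = []
    order = best.sort_values(["p", "pos"]).index.to_list()
    for index_var in order:
        if index_var not in unassigned:
            continue
        members = [index_var]
        unassigned.discard(index_var)
        for other in sorted(unassigned, key=lambda v: var_pos[v]):
            if var_chrom[other] != var_chrom[index_var]:
                continue
            if abs(var_pos[other] - var_pos[index_var]) >= dist_limit:
                continue
            r2 = ld_r2(gm, index_var, other)
            if np.isfinite(r2) and r2 > config.clump_r2:
                members.append(other)
        for m in members[1:]:
            unassigned.discard(m)

        traits = set().union(*(support[m] for m in members))
        if config.require_distinct_variants:
            # require two significant (variant, trait) hits with both the
            # variants and the traits distinct
            pairs = sig[sig["id"].isin(members)][["id", "trait"]].drop_duplicates()
            ok = False
            for _, r1 in pairs.iterrows():
                for _, r2_ in pairs.iterrows():
                    if r1["id"] != r2_["id"] and r1["trait"] != r2_["trait"]:
                        ok = True
                        break
                if ok:
                    break
            supported = ok and len(traits) >= config.min_supporting_traits
        else:
            supported = len(traits) >= config.min_supporting_traits
        if not supported:
            continue

        msub = sig[sig["id"].isin(members)]
        lead_row = msub.sort_values(["p", "pos", "trait"]).iloc[0]
        pos = [int(var_pos[m]) for m in members]
        regions.append(
            ClumpedRegion(
                lead=str(lead_row["id"]),
                lead_trait=str(lead_row["trait"]),
                lead_p=float(lead_row["p"]),
                members=sorted(members, key=lambda v: var_pos[v]),
                supporting_traits=traits,
                chrom=str(var_chrom[index_var]),
                span=(min(pos), max(pos)),
            )
        )
    return regions


def regions_to_frame(regions: list[ClumpedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lead": r.lead,
                "lead_trait": r.lead_trait,
                "lead_p": r.lead_p,
                "chrom": r.chrom,
                "span_start": r.span[0],
                "span_end": r.span[1],
                "n_members": len(r.members),
                "members": ",".join(r.members),
                "supporting_traits": ",".join(sorted(r.supporting_traits)),
            }
            for r in regions
        ],
        columns=[
            "lead",
            "lead_trait",
            "lead_p",
            "chrom",
            "span_start",
            "span_end",
            "n_members",
            "members",
            "supporting_traits",
        ],
    )
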