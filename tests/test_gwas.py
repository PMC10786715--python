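"""Genetic association: HWE, kinship, variant QC, scan, clumping."""

import math

import numpy as np
import pandas as pd
import pytest

from hemascan.config import ScanConfig, SimulationConfig
from hemascan.gwas import (
    association_scan,
    clump,
    genotype_pcs,
    hwe_exact_test,
    king_kinship,
    variant_qc,
)
from hemascan.simulate import simulate_genotypes

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# HWE exact test


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Brute-force conditional enumeration of heterozygote counts."""
    n = n_aa + n_ab + n_bb
    rare = 2 * min(n_aa, n_bb) + n_ab
    common = 2 * n - rare
    if rare == 0:
        return 1.0

    def prob(h):
        if (rare - h) % 2:
            return 0.0
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        if hom_r < 0 or hom_c < 0:
            return 0.0
        # multinomial genotype arrangements x 2^h phase choices over
        # C(2n, rare) equally likely allele assignments
        return (
            math.comb(n, hom_r)
            * math.comb(n - hom_r, h)
            * 2**h
            / math.comb(2 * n, rare)
        )

    probs = {h: prob(h) for h in range(rare + 1)}
    total = sum(probs.values())
    obs = probs[n_ab]
    return min(1.0, sum(p for p in probs.values() if p <= obs * (1 + 1e-12)) / total)


class TestHweExactTest:
    def test_monomorphic_site_p_one(self):
        assert hwe_exact_test(25, 0, 0) == 1.0

    def test_all_heterozygotes_two_diploids(self):
        assert hwe_exact_test(0, 2, 0) == pytest.approx(
            hwe_enumeration_oracle(0, 2, 0)
        )

    def test_extreme_homozygote_excess(self):
        assert hwe_exact_test(50, 0, 50) < 1e-20

    def test_matches_enumeration_for_all_small_tables(self):
        for total in range(1, 11):
            for n_aa in range(total + 1):
                for n_ab in range(total - n_aa + 1):
                    n_bb = total - n_aa - n_ab
                    got = hwe_exact_test(n_aa, n_ab, n_bb)
                    want = hwe_enumeration_oracle(n_aa, n_ab, n_bb)
                    assert got == pytest.approx(want, abs=1e-12), (n_aa, n_ab, n_bb)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


# ---------------------------------------------------------------------------
# KING kinship


class TestKingKinship:
    def test_duplicate_samples_phi_half(self, rng):
        g = rng.integers(0, 3, 500).astype(float)
        assert king_kinship(g, g) == pytest.approx(0.5)

    def test_unrelated_pair_phi_near_zero(self, rng):
        maf = rng.uniform(0.1, 0.5, 10_000)
        a = rng.binomial(2, maf).astype(float)
        b = rng.binomial(2, maf).astype(float)
        assert abs(king_kinship(a, b)) < 0.05

    def test_parent_offspring_phi_quarter(self, rng):
        maf = rng.uniform(0.2, 0.5, 10_000)
        h1, h2 = rng.binomial(1, maf), rng.binomial(1, maf)
        parent = (h1 + h2).astype(float)
        transmitted = np.where(rng.random(10_000) < 0.5, h1, h2)
        child = (transmitted + rng.binomial(1, maf)).astype(float)
        assert king_kinship(parent, child) == pytest.approx(0.25, abs=0.05)

    def test_no_heterozygotes_undefined(self):
        with pytest.warns(UserWarning):
            phi = king_kinship(np.zeros(200), np.full(200, 2.0))
        assert np.isnan(phi)


# ---------------------------------------------------------------------------
# Variant QC


class TestVariantQc:
    def test_high_missingness_excluded_with_reason(self, rng):
        d = rng.binomial(2, 0.3, size=(100, 3)).astype(float)
        d[:15, 0] = np.nan  # 15% missing
        gm = make_genotypes(d)
        _, report = variant_qc(gm, ScanConfig(), check_kinship=False)
        row = report.variant_exclusions.set_index("id").loc["v0"]
        assert row["reason"] == "missingness"

    def test_low_maf_excluded(self, rng):
        d = rng.binomial(2, [0.04, 0.3, 0.3], size=(2000, 3)).astype(float)
        gm = make_genotypes(d)
        out, report = variant_qc(gm, ScanConfig(mac_floor=0), check_kinship=False)
        assert "v0" in report.variant_exclusions["id"].tolist()
        assert out.n_variants == 2

    def test_clean_panel_zero_exclusions(self):
        # enough weakly linked sites that kinship noise stays below 0.177
        cfg = SimulationConfig(
            n_donors=100, n_variants=500, ld_rho=0.2, maf_range=(0.2, 0.5), seed=0
        )
        gm = simulate_genotypes(cfg)
        out, report = variant_qc(gm, ScanConfig(), check_kinship=True)
        assert report.variant_exclusions.empty
        assert report.donor_exclusions.empty
        assert out.n_variants == 500

    def test_duplicate_donor_pruned_by_kinship(self, rng):
        d = rng.binomial(2, rng.uniform(0.2, 0.5, 200), size=(40, 200)).astype(float)
        d[1] = d[0]  # planted duplicate pair
        d[1, :10] = np.nan  # the copy has higher missingness
        gm = make_genotypes(d)
        out, report = variant_qc(gm, ScanConfig(missingness_ceiling=0.5), check_kinship=True)
        excl = report.donor_exclusions
        assert excl["reason"].tolist().count("kinship") == 1
        assert excl.loc[excl["reason"] == "kinship", "donor"].iloc[0] == gm.donors[1]

    def test_each_exclusion_listed_exactly_once(self, rng):
        d = rng.binomial(2, 0.02, size=(60, 5)).astype(float)  # fails maf and mac
        d[:20, 0] = np.nan
        gm = make_genotypes(d)
        _, report = variant_qc(gm, ScanConfig(), check_kinship=False)
        assert not report.variant_exclusions["id"].duplicated().any()


# ---------------------------------------------------------------------------
# Association scan


def ols_oracle(y, g, X):
    """Full-matrix least squares with explicit normal equations."""
    import scipy.stats as ss

    D = np.column_stack([X, g])
    beta_all, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta_all
    df = len(y) - D.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(D.T @ D)
    beta, se = beta_all[-1], np.sqrt(cov[-1, -1])
    t = beta / se
    return beta, se, t, 2 * ss.t.sf(abs(t), df)


class TestAssociationScan:
    def test_noiseless_fit_recovers_slope(self, rng):
        g = rng.integers(0, 3, 100).astype(float)
        gm = make_genotypes(g[:, None])
        y = pd.Series(0.5 * g, index=gm.donors)
        res = association_scan(y, gm)
        assert res["beta"].iloc[0] == pytest.approx(0.5, abs=1e-10)
        assert res["p"].iloc[0] >= 1e-320  # underflow guarded

    def test_matches_least_squares_oracle_with_covariates_and_missingness(self, rng):
        n, m = 50, 20
        d = rng.binomial(2, rng.uniform(0.2, 0.5, m), size=(n, m)).astype(float)
        d[rng.random((n, m)) < 0.05] = np.nan  # exercise per-variant refits
        gm = make_genotypes(d)
        cov = pd.DataFrame(
            {"age": rng.uniform(30, 70, n), "sex": rng.integers(0, 2, n)},
            index=gm.donors,
        )
        y = pd.Series(rng.standard_normal(n), index=gm.donors)
        res = association_scan(y, gm, cov)
        # oracle: standardize covariates exactly as the scan does
        C = cov.to_numpy(dtype=float)
        C = (C - C.mean(axis=0)) / C.std(axis=0, ddof=1)
        X = np.column_stack([np.ones(n), C])
        for j in range(m):
            g = d[:, j]
            ok = ~np.isnan(g)
            beta, se, t, p = ols_oracle(y.to_numpy()[ok], g[ok], X[ok])
            assert res["beta"].iloc[j] == pytest.approx(beta, abs=1e-8)
            assert res["se"].iloc[j] == pytest.approx(se, abs=1e-8)
            assert res["p"].iloc[j] == pytest.approx(p, rel=1e-6)

    def test_null_p_values_roughly_uniform(self, rng):
        from scipy.stats import kstest

        n, m = 400, 400
        d = rng.binomial(2, rng.uniform(0.2, 0.5, m), size=(n, m)).astype(float)
        gm = make_genotypes(d)
        y = pd.Series(rng.standard_normal(n), index=gm.donors)
        res = association_scan(y, gm)
        assert kstest(res["p"], "uniform").statistic < 0.08

    def test_skips_trait_with_too_few_rows(self, rng):
        gm = make_genotypes(rng.binomial(2, 0.3, size=(30, 2)).astype(float))
        y = pd.Series(np.nan, index=gm.donors)
        y.iloc[0] = 1.0
        res = association_scan(y, gm)
        assert res["beta"].isna().all()

    def test_t_equals_beta_over_se(self, rng):
        gm = make_genotypes(rng.binomial(2, 0.3, size=(80, 5)).astype(float))
        y = pd.Series(rng.standard_normal(80), index=gm.donors)
        res = association_scan(y, gm)
        np.testing.assert_allclose(res["t"], res["beta"] / res["se"], atol=1e-9)


# ---------------------------------------------------------------------------
# Clumping


def clump_oracle(sig: pd.DataFrame, gm, r2_thresh, kb, min_traits):
    """Naive reimplementation: greedy index selection with explicit loops."""
    ids = list(gm.variants["id"])
    pos = dict(zip(gm.variants["id"], gm.variants["pos"]))

    def r2(a, b):
        ga, gb = gm.dosages[:, ids.index(a)], gm.dosages[:, ids.index(b)]
        ok = ~np.isnan(ga) & ~np.isnan(gb)
        c = np.corrcoef(ga[ok], gb[ok])[0, 1]
        return c * c

    best_p = {}
    for _, row in sig.iterrows():
        if row["id"] not in best_p or row["p"] < best_p[row["id"]]:
            best_p[row["id"]] = row["p"]
    remaining = set(best_p)
    regions = []
    while remaining:
        index = min(remaining, key=lambda v: (best_p[v], pos[v]))
        members = {index}
        for other in list(remaining - {index}):
            if abs(pos[other] - pos[index]) < kb * 1000 and r2(index, other) > r2_thresh:
                members.add(other)
        remaining -= members
        traits = set(sig[sig["id"].isin(members)]["trait"])
        if len(traits) >= min_traits:
            sub = sig[sig["id"].isin(members)]
            lead = sub.sort_values(["p", "pos", "trait"]).iloc[0]["id"]
            regions.append((lead, frozenset(members), frozenset(traits)))
    return regions


class TestClump:
    def _sig_frame(self, gm, entries):
        rows = []
        pos = dict(zip(gm.variants["id"], gm.variants["pos"]))
        for vid, trait, p in entries:
            rows.append(
                {"trait": trait, "id": vid, "chrom": "1", "pos": pos[vid], "p": p}
            )
        return pd.DataFrame(rows)

    def test_perfect_ld_trio_collapses_to_one_region(self, rng):
        g = rng.binomial(2, 0.4, 200).astype(float)
        gm = make_genotypes(np.column_stack([g, g, g]), positions=[1000, 2000, 3000])
        res = self._sig_frame(
            gm, [("v0", "t1", 1e-10), ("v1", "t2", 1e-9), ("v2", "t1", 1e-8)]
        )
        regions = clump(res, gm, ScanConfig())
        assert len(regions) == 1
        assert regions[0].lead == "v0"
        assert regions[0].supporting_traits == {"t1", "t2"}

    def test_single_trait_region_discarded(self, rng):
        g = rng.binomial(2, 0.4, 200).astype(float)
        gm = make_genotypes(g[:, None])
        res = self._sig_frame(gm, [("v0", "t1", 1e-10)])
        assert clump(res, gm, ScanConfig()) == []

    def test_distant_uncorrelated_variants_split(self, rng):
        a = rng.binomial(2, 0.4, 500).astype(float)
        b = rng.binomial(2, 0.4, 500).astype(float)
        gm = make_genotypes(np.column_stack([a, b]), positions=[1_000, 301_000])
        res = self._sig_frame(
            gm,
            [("v0", "t1", 1e-10), ("v0", "t2", 1e-9),
             ("v1", "t1", 1e-8), ("v1", "t3", 1e-9)],
        )
        regions = clump(res, gm, ScanConfig())
        assert len(regions) == 2
        assert {r.lead for r in regions} == {"v0", "v1"}

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        cfg = SimulationConfig(
            n_donors=150, n_variants=50, ld_rho=0.9, ld_block_size=10,
            maf_range=(0.2, 0.5), seed=0,
        )
        gm = simulate_genotypes(cfg)
        scan_cfg = ScanConfig(significance=1e-4)
        for trial in range(5):
            k = rng.integers(5, 15)
            vids = rng.choice(gm.variants["id"], size=k, replace=True)
            traits = rng.choice(["t1", "t2", "t3"], size=k)
            ps = 10.0 ** rng.uniform(-12, -5, size=k)
            res = self._sig_frame(gm, list(zip(vids, traits, ps)))
            got = clump(res, gm, scan_cfg)
            want = clump_oracle(res, gm, scan_cfg.clump_r2, scan_cfg.clump_kb, 2)
            assert len(got) == len(want)
            got_set = {(r.lead, frozenset(r.members), frozenset(r.supporting_traits))
                       for r in got}
            assert got_set == set(want)

    def test_no_significant_hits_empty_list(self, rng):
        gm = make_genotypes(rng.binomial(2, 0.3, size=(50, 3)).astype(float))
        res = pd.DataFrame(
            {"trait": ["t"], "id": ["v0"], "chrom": ["1"], "pos": [1000], "p": [0.5]}
        )
        assert clump(res, gm, ScanConfig()) == []


class TestGenotypePcs:
    def test_shape_and_determinism(self, rng):
        gm = make_genotypes(rng.binomial(2, 0.3, size=(60, 40)).astype(float))
        p1 = genotype_pcs(gm, 5)
        p2 = genotype_pcs(gm, 5)
        assert p1.shape == (60, 5)
        pd.testing.assert_frame_equal(p1, p2)

    def test_population_split_separates_on_pc1(self, rng):
        f1, f2 = rng.uniform(0.1, 0.5, 100), rng.uniform(0.1, 0.5, 100)
        a = rng.binomial(2, f1, size=(50, 100)).astype(float)
        b = rng.binomial(2, f2, size=(50, 100)).astype(float)
        gm = make_genotypes(np.vstack([a, b]))
        pcs = genotype_pcs(gm, 2)
        grp = np.array([0] * 50 + [1] * 50)
        assert abs(np.corrcoef(pcs["PC1"], grp)[0, 1]) > 0.9
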