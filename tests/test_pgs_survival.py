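"""Polygenic scoring, survival encoding, Cox models, KM and meta-analysis."""

import numpy as np
import pandas as pd
import pytest

from hemascan.config import PgsConfig, SimulationConfig
from hemascan.pgs import (
    build_pgs,
    ckd_stage_from_egfr,
    cox_delayed_entry,
    encode_survival,
    km_quartiles,
    meta_random_effects,
    score,
)
from hemascan.simulate import simulate_genotypes

from conftest import make_genotypes


def _sumstats(gm, entries):
    """entries: list of (id, beta, p)"""
    v = gm.variants.set_index("id")
    rows = []
    for vid, beta, p in entries:
        rows.append(
            {
                "trait": "t",
                "id": vid,
                "chrom": v.loc[vid, "chrom"],
                "pos": v.loc[vid, "pos"],
                "ref": v.loc[vid, "ref"],
                "alt": v.loc[vid, "alt"],
                "beta": beta,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


class TestBuildPgs:
    def test_single_nominal_variant_retained(self, rng):
        gm = make_genotypes(rng.binomial(2, 0.3, size=(100, 1)).astype(float))
        w = build_pgs(_sumstats(gm, [("v0", 0.4, 0.05)]), gm)
        assert w.weights["id"].tolist() == ["v0"]
        assert w.weights["weight"].iloc[0] == 0.4

    def test_correlated_pair_keeps_smaller_p(self, rng):
        g = rng.binomial(2, 0.4, 300).astype(float)
        noise = rng.binomial(1, 0.05, 300)
        g2 = np.clip(g + noise - rng.binomial(1, 0.05, 300), 0, 2)  # r2 ~ 0.9
        gm = make_genotypes(np.column_stack([g, g2]), positions=[1_000, 51_000])
        w = build_pgs(_sumstats(gm, [("v0", 0.3, 0.01), ("v1", 0.2, 0.02)]), gm)
        assert w.weights["id"].tolist() == ["v0"]

    def test_above_score_threshold_excluded(self, rng):
        gm = make_genotypes(rng.binomial(2, 0.3, size=(100, 1)).astype(float))
        with pytest.warns(UserWarning, match="threshold"):
            w = build_pgs(_sumstats(gm, [("v0", 0.4, 0.2)]), gm)
        assert w.weights.empty

    def test_allele_mismatch_dropped_with_report(self, rng):
        gm = make_genotypes(rng.binomial(2, 0.3, size=(100, 2)).astype(float))
        ss = _sumstats(gm, [("v0", 0.4, 0.01), ("v1", 0.2, 0.01)])
        ss.loc[ss["id"] == "v1", "alt"] = "T"
        w = build_pgs(ss, gm)
        assert w.dropped["id"].tolist() == ["v1"]
        assert w.weights["id"].tolist() == ["v0"]


class TestScore:
    def test_single_weight_dosage_levels(self):
        gm = make_genotypes(np.array([[0.0], [1.0], [2.0]]))
        w = pd.DataFrame({"id": ["v0"], "effect_allele": ["G"], "weight": [0.5]})
        s = score(gm, w)
        assert s["score"].tolist() == [0.0, 0.5, 1.0]

    def test_matches_dot_product_oracle(self, rng):
        n, m = 100, 50
        d = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        gm = make_genotypes(d)
        weights = pd.DataFrame(
            {
                "id": [f"v{j}" for j in range(m)],
                "effect_allele": ["G"] * m,
                "weight": rng.standard_normal(m),
            }
        )
        s = score(gm, weights)
        expected = d @ weights["weight"].to_numpy()
        np.testing.assert_allclose(s["score"].to_numpy(), expected, atol=1e-12)

    def test_missing_dosage_imputed_to_twice_frequency(self, rng):
        d = np.array([[0.0], [1.0], [2.0], [np.nan]])
        gm = make_genotypes(d)
        w = pd.DataFrame({"id": ["v0"], "effect_allele": ["G"], "weight": [1.0]})
        s = score(gm, w)
        assert s["score"].iloc[3] == pytest.approx(2 * 0.5)  # freq of observed = 0.5

    def test_effect_allele_flip(self):
        gm = make_genotypes(np.array([[0.0], [2.0]]))
        w = pd.DataFrame({"id": ["v0"], "effect_allele": ["A"], "weight": [1.0]})
        s = score(gm, w)
        assert s["score"].tolist() == [2.0, 0.0]

    def test_no_overlap_errors(self, rng):
        gm = make_genotypes(rng.binomial(2, 0.3, size=(10, 1)).astype(float))
        w = pd.DataFrame({"id": ["zz"], "effect_allele": ["G"], "weight": [1.0]})
        with pytest.raises(ValueError, match="overlap"):
            score(gm, w)


class TestEncodeSurvival:
    def _records(self, rows):
        return pd.DataFrame(
            rows,
            columns=["donor", "entry_age", "diagnosis_age", "censor_age", "problem_list_only"],
        )

    def test_instant_event_encoding(self):
        rec = self._records([("a", 40.0, 40.5, 70.0, False)])
        enc, dropped = encode_survival(rec)
        row = enc.iloc[0]
        assert (row["start"], row["stop"], row["event"]) == (0.0, 40.0, 1)
        assert row["reason"] == "instant_event"
        assert dropped.empty

    def test_normal_event_encoding(self):
        enc, _ = encode_survival(self._records([("a", 40.0, 55.0, 70.0, False)]))
        row = enc.iloc[0]
        assert (row["start"], row["stop"], row["event"]) == (40.0, 55.0, 1)
        assert row["reason"] == "normal"

    def test_censored_encoding(self):
        enc, _ = encode_survival(self._records([("a", 40.0, np.nan, 70.0, False)]))
        row = enc.iloc[0]
        assert (row["start"], row["stop"], row["event"]) == (40.0, 70.0, 0)

    def test_problem_list_encoding(self):
        enc, _ = encode_survival(self._records([("a", 45.0, np.nan, 70.0, True)]))
        row = enc.iloc[0]
        assert (row["start"], row["stop"], row["event"]) == (0.0, 45.0, 1)
        assert row["reason"] == "problem_list_interval"

    def test_every_subject_in_output_or_drop_report(self):
        rec = self._records(
            [
                ("a", 40.0, 41.5, 70.0, False),
                ("b", 0.0, np.nan, 0.0, False),  # zero-length interval -> dropped
                ("c", 35.0, np.nan, 60.0, False),
            ]
        )
        enc, dropped = encode_survival(rec)
        assert sorted(enc["donor"]) + sorted(dropped["donor"]) == ["a", "c", "b"]

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            encode_survival(self._records([("a", -1.0, 5.0, 10.0, False)]))


class TestCoxDelayedEntry:
    def test_matches_counting_process_oracle(self):
        # frozen oracle: survival::coxph(Surv(start, stop, event) ~ x + z,
        # ties = "efron") on this fixture
        df = pd.DataFrame(
            {
                "start": [0, 0, 5, 5, 0, 3, 0, 8, 2, 0],
                "stop": [10, 12, 15, 9, 7, 13, 6, 18, 11, 14],
                "event": [1, 0, 1, 1, 0, 1, 1, 0, 1, 1],
                "x": [1, 0, 1, 0, 1, 0, 1, 1, 0, 0],
                "z": [0.5, -0.2, 1.1, 0.3, -0.7, 0.9, 0.0, -1.2, 0.4, 0.6],
            }
        )
        fit = cox_delayed_entry(df, ["x", "z"]).set_index("covariate")
        assert fit.loc["x", "log_hr"] == pytest.approx(-0.434725260877, abs=1e-6)
        assert fit.loc["x", "se"] == pytest.approx(0.883317214544, abs=1e-6)
        assert fit.loc["z", "log_hr"] == pytest.approx(0.511663923036, abs=1e-6)
        assert fit.loc["z", "se"] == pytest.approx(0.589502061003, abs=1e-6)

    def test_zero_entries_equal_standard_cox(self, rng):
        n = 400
        x = rng.standard_normal(n)
        t = rng.exponential(np.exp(-0.5 * x))
        c = rng.exponential(1.5, n)
        df = pd.DataFrame(
            {
                "start": 0.0,
                "stop": np.minimum(t, c) + 1e-9,
                "event": (t <= c).astype(int),
                "x": x,
            }
        )
        fit = cox_delayed_entry(df, ["x"]).set_index("covariate")
        from lifelines import CoxPHFitter

        std = CoxPHFitter().fit(
            df[["stop", "event", "x"]], duration_col="stop", event_col="event"
        )
        assert fit.loc["x", "log_hr"] == pytest.approx(std.params_["x"], abs=1e-6)
        assert fit.loc["x", "se"] == pytest.approx(std.standard_errors_["x"], abs=1e-6)

    def test_null_covariate_moderate_z(self, rng):
        n = 1000
        df = pd.DataFrame(
            {
                "start": rng.uniform(0, 1, n),
                "stop": 1 + rng.exponential(1, n),
                "event": rng.binomial(1, 0.5, n),
                "x": rng.standard_normal(n),
            }
        )
        fit = cox_delayed_entry(df, ["x"]).set_index("covariate")
        assert abs(fit.loc["x", "z"]) < 4

    def test_score_rescaling_inverts_log_hr(self, rng):
        n = 500
        x = rng.standard_normal(n)
        t = rng.exponential(np.exp(-0.4 * x))
        df = pd.DataFrame({"start": 0.0, "stop": t, "event": 1, "x": x})
        b1 = cox_delayed_entry(df, ["x"])["log_hr"].iloc[0]
        df2 = df.assign(x=df["x"] * 2)
        b2 = cox_delayed_entry(df2, ["x"])["log_hr"].iloc[0]
        assert b2 == pytest.approx(b1 / 2, rel=1e-4)

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"start": [0.0], "stop": [1.0], "event": [1], "x": [0.2]})
        with pytest.raises(ValueError, match="events"):
            cox_delayed_entry(df, ["x"])


class TestKmQuartiles:
    def _records(self, n, rng, hazard_by_score=False):
        scores = pd.Series(rng.standard_normal(n), index=[f"D{i}" for i in range(n)])
        rate = np.exp(1.5 * scores.to_numpy()) if hazard_by_score else np.ones(n)
        t = rng.exponential(1.0 / rate)
        rec = pd.DataFrame(
            {"donor": scores.index, "start": 0.0, "stop": t + 1e-9, "event": 1}
        )
        return rec, scores

    def test_identical_scores_single_stratum_warns(self, rng):
        rec, _ = self._records(20, rng)
        with pytest.warns(UserWarning, match="single stratum"):
            curves, labels = km_quartiles(rec, pd.Series(1.0, index=rec["donor"]))
        assert len(curves) == 1

    def test_no_censoring_matches_empirical_survival(self, rng):
        rec, scores = self._records(40, rng)
        curves, labels = km_quartiles(rec, scores)
        q1 = labels[labels == "Q1"].index
        times = rec.loc[q1, "stop"].sort_values().to_numpy()
        curve = curves["Q1"]
        # at the k-th event time the KM estimate is 1 - k/n
        n = len(times)
        for k, t in enumerate(times, start=1):
            km_at_t = curve[curve.index <= t + 1e-12]["Q1"].iloc[-1]
            assert km_at_t == pytest.approx(1 - k / n, abs=1e-9)

    def test_high_hazard_quartile_curve_lies_below(self, rng):
        rec, scores = self._records(400, rng, hazard_by_score=True)
        curves, _ = km_quartiles(rec, scores)
        t_grid = np.linspace(0.05, 1.0, 10)
        for t in t_grid:
            s_low = np.interp(t, curves["Q1"].index, curves["Q1"]["Q1"])
            s_high = np.interp(t, curves["Q4"].index, curves["Q4"]["Q4"])
            assert s_high <= s_low + 1e-9

    def test_small_cohort_rejected(self, rng):
        rec, scores = self._records(5, rng)
        with pytest.raises(ValueError, match="8 subjects"):
            km_quartiles(rec, scores)


class TestMetaRandomEffects:
    def test_identical_studies_pool_to_common_value(self):
        m = meta_random_effects([0.2, 0.2], [0.05, 0.05])
        assert m.pooled == pytest.approx(0.2)
        assert m.tau2 == 0.0
        assert m.pooled_se <= 0.05

    def test_single_study_identity(self):
        m = meta_random_effects([0.3], [0.1])
        assert m.pooled == 0.3 and m.tau2 == 0.0 and m.pooled_se == pytest.approx(0.1)

    def test_heterogeneous_studies_positive_tau2(self):
        m = meta_random_effects([0.1, 0.9], [0.02, 0.02])
        assert m.tau2 > 0
        assert 0.1 < m.pooled < 0.9

    def test_matches_metafor_reml_oracle(self):
        # frozen oracle: metafor::rma(yi, sei, method="REML")
        m = meta_random_effects([0.12, 0.35, 0.20], [0.08, 0.10, 0.06])
        assert m.tau2 == pytest.approx(0.0026036060, abs=1e-4)
        assert m.pooled == pytest.approx(0.2085778709, abs=1e-4)
        assert m.pooled_se == pytest.approx(0.0533300683, abs=1e-4)
        m2 = meta_random_effects([0.1, 0.9], [0.02, 0.02])
        assert m2.tau2 == pytest.approx(0.3196, abs=1e-4)
        assert m2.pooled == pytest.approx(0.5, abs=1e-6)

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            meta_random_effects([0.1], [0.0])


class TestCkdStaging:
    @pytest.mark.parametrize(
        "egfr, stage",
        [
            (90, None), (60, None), (59.9, "3a"), (50, "3a"), (45, "3a"),
            (44.9, "3b"), (30, "3b"), (29.9, "4"), (15, "4"), (14.9, "5"),
            (10, "5"), (0, "5"),
        ],
    )
    def test_band_edges(self, egfr, stage):
        assert ckd_stage_from_egfr(egfr) == stage

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ckd_stage_from_egfr(-1)
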