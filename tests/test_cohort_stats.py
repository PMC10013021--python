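"""Normality gate, dual-test rule, subgroup tests, discordance error
analysis and dose correlations."""

import numpy as np
import pandas as pd
import pytest

from cardiosleep.cohort_stats import (
    breathing_cohort_compare,
    discordance_regression,
    dose_correlations,
    dual_test,
    feature_discordance_tests,
    kruskal_subgroups,
    normality_gate,
)


class TestNormalityGate:
    def test_gaussian_sample_passes(self):
        rng = np.random.default_rng(0)
        false_calls = sum(
            not normality_gate(np.random.default_rng(i).standard_normal(10_000))
            for i in range(20)
        )
        assert false_calls >= 18  # joint 0.05-level tests; ~90% pass rate

    def test_exponential_sample_flagged(self):
        rng = np.random.default_rng(1)
        assert normality_gate(rng.exponential(size=200))

    def test_constant_sample_flagged_degenerate(self):
        assert normality_gate(np.full(50, 3.0))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 8"):
            normality_gate(np.arange(5.0))


class TestDualTest:
    def test_large_shift_detected(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(50)
        res = dual_test(x, x + 10.0)
        assert res.significant and res.p_mwu < 1e-6 and res.p_mood < 1e-6

    def test_null_rejection_rate_conservative(self):
        rej = 0
        n_rep = 200
        for i in range(n_rep):
            rng = np.random.default_rng(10_000 + i)
            res = dual_test(rng.standard_normal(30), rng.standard_normal(30))
            rej += res.significant
        # conjunction of two 0.05 tests: rate must stay below 0.05
        # plus 3 binomial standard errors
        assert rej / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_identical_samples_not_significant(self):
        x = np.arange(10.0)
        res = dual_test(x, x)
        assert not res.significant

    def test_all_tied_data_degenerate(self):
        res = dual_test(np.full(5, 1.0), np.full(5, 1.0))
        assert res.p_mwu == 1.0 and res.p_mood == 1.0 and res.degenerate

    def test_conjunction_never_less_conservative(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            res = dual_test(rng.standard_normal(20),
                            rng.standard_normal(20) + rng.uniform(0, 1))
            if res.significant:
                assert res.p_mwu < 0.05 and res.p_mood < 0.05

    def test_group_order_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(25), rng.standard_normal(25) + 0.5
        a, b = dual_test(x, y), dual_test(y, x)
        assert a.p_mwu == pytest.approx(b.p_mwu)
        assert a.p_mood == pytest.approx(b.p_mood)


class TestKruskal:
    def test_exchangeable_groups_not_rejected(self):
        g = {"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}
        H, p = kruskal_subgroups(g)
        assert H == pytest.approx(0.0, abs=1e-9) and p > 0.99

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(5)
        g = {
            "a": rng.standard_normal(30),
            "b": rng.standard_normal(30),
            "c": rng.standard_normal(30) + 10.0,
        }
        _, p = kruskal_subgroups(g)
        assert p < 0.01

    def test_null_rejection_calibrated(self):
        rej = 0
        n_rep = 200
        for i in range(n_rep):
            rng = np.random.default_rng(20_000 + i)
            g = {k: rng.standard_normal(20) for k in "abc"}
            _, p = kruskal_subgroups(g)
            rej += p < 0.05
        assert abs(rej / n_rep - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            kruskal_subgroups({"only": [1, 2, 3]})


class TestFeatureDiscordanceScreen:
    def _tidy(self, rng, rr_shift=0.0):
        rows = []
        for stage in ("N1", "N2"):
            for feature in ("rr_bpm", "rmssd_ms"):
                for stratum, shift in (("concordant", 0.0),
                                       ("discordant",
                                        rr_shift if feature == "rr_bpm" else 0.0)):
                    for v in rng.standard_normal(40) + shift:
                        rows.append(dict(feature=feature, stage=stage,
                                         stratum=stratum, value=v))
        return pd.DataFrame(rows)

    def test_planted_effect_recovered_with_direction(self):
        table = feature_discordance_tests(
            self._tidy(np.random.default_rng(6), rr_shift=2.0))
        rr = table[table["feature"] == "rr_bpm"]
        assert rr["significant"].all()
        assert (rr["direction"] > 0).all()

    def test_null_feature_not_flagged(self):
        table = feature_discordance_tests(
            self._tidy(np.random.default_rng(7), rr_shift=0.0), alpha=0.01)
        assert not table[table["feature"] == "rmssd_ms"]["significant"].any()

    def test_no_silent_drops(self):
        df = self._tidy(np.random.default_rng(8))
        # remove one stratum entirely for one pair
        df = df[~((df.feature == "rmssd_ms") & (df.stage == "N2")
                  & (df.stratum == "discordant"))]
        table = feature_discordance_tests(df)
        assert len(table) == 4  # 2 features x 2 stages, all present
        row = table[(table.feature == "rmssd_ms") & (table.stage == "N2")]
        assert row["skipped"].item() and not row["significant"].item()


class TestDiscordanceRegression:
    def test_planted_support_recovered_exactly(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((200, 20)),
                         columns=[f"f{i}" for i in range(20)])
        eta = 0.1 * X[["f2", "f7", "f13"]].to_numpy() @ np.array([1.0, -0.8, 0.5]) - 1.5
        y = np.clip(np.exp(eta) - 1e-3, 0.0, 1.0)
        m = discordance_regression(X, y, seed=0)
        assert m.selected_features == ["f2", "f7", "f13"]
        assert m.r_squared > 0.99

    def test_null_design_rarely_rejects(self):
        hits = 0
        n_rep = 20
        for i in range(n_rep):
            rng = np.random.default_rng(30_000 + i)
            X = pd.DataFrame(rng.standard_normal((200, 20)))
            y = rng.uniform(0.05, 0.95, 200)
            m = discordance_regression(X, y, seed=i)
            assert m.r_squared <= 0.1
            hits += np.isfinite(m.f_p) and m.f_p < 0.05
        assert hits / n_rep <= 0.10

    def test_duplicate_columns_handled(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.standard_normal((100, 5)),
                         columns=[f"f{i}" for i in range(5)])
        X["f0_dup"] = X["f0"]
        eta = 0.2 * X["f0"].to_numpy() - 1.5
        y = np.clip(np.exp(eta) - 1e-3, 0.0, 1.0)
        m = discordance_regression(X, y, seed=0)
        assert set(m.selected_features) <= {"f0", "f0_dup"}
        assert m.r_squared > 0.95

    def test_constant_outcome_rejected(self):
        X = pd.DataFrame(np.random.default_rng(11).standard_normal((50, 3)))
        with pytest.raises(ValueError, match="constant"):
            discordance_regression(X, np.full(50, 0.3), seed=0)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.standard_normal((60, 8)))
        y = rng.uniform(0.1, 0.9, 60)
        a = discordance_regression(X, y, seed=5)
        b = discordance_regression(X, y, seed=5)
        assert a.selected_features == b.selected_features
        assert a.r_squared == b.r_squared


class TestDoseCorrelations:
    def test_linear_relation_perfect_both(self):
        dose = np.arange(1.0, 11.0)
        out = dose_correlations(dose, 2 * dose)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["spearman_rho"] == pytest.approx(1.0)
        assert out["associated"]

    def test_monotone_nonlinear_relation(self):
        dose = np.arange(1.0, 21.0)
        out = dose_correlations(dose, dose**3)
        assert out["spearman_rho"] == pytest.approx(1.0)
        assert out["pearson_r"] < 1.0

    def test_independent_draws_rarely_associated(self):
        flagged = 0
        n_rep = 50
        for i in range(n_rep):
            rng = np.random.default_rng(40_000 + i)
            out = dose_correlations(rng.standard_normal(160),
                                    rng.standard_normal(160))
            flagged += out["associated"]
        assert flagged / n_rep <= 0.10

    def test_zero_variance_missing(self):
        out = dose_correlations(np.full(10, 2.0), np.arange(10.0))
        assert np.isnan(out["pearson_r"]) and not out["associated"]


class TestBreathingCohortCompare:
    def test_planted_rate_difference_flagged(self):
        rng = np.random.default_rng(13)
        n_icu, n_lab = 80, 190
        feats = pd.DataFrame({
            "rr_bpm": np.concatenate([
                rng.normal(17.4, 2.0, n_icu), rng.normal(14.0, 2.0, n_lab)
            ]),
            "ibi_s": np.concatenate([
                rng.normal(3.8, 0.5, n_icu), rng.normal(4.7, 0.5, n_lab)
            ]),
        })
        cohort = np.array(["icu"] * n_icu + ["lab"] * n_lab)
        table = breathing_cohort_compare(feats, cohort)
        assert table.set_index("feature")["significant"].all()

    def test_identical_cohorts_stay_quiet(self):
        rng = np.random.default_rng(14)
        feats = pd.DataFrame({
            f"f{i}": rng.standard_normal(120) for i in range(5)
        })
        cohort = np.array(["a"] * 60 + ["b"] * 60)
        table = breathing_cohort_compare(feats, cohort)
        assert table["significant"].sum() <= 1  # ~alpha-level false hits

    def test_gaussian_feature_routes_to_ttest(self):
        rng = np.random.default_rng(15)
        feats = pd.DataFrame({
            "gauss": rng.standard_normal(200),
            "skewed": rng.exponential(size=200),
        })
        cohort = np.array(["a", "b"] * 100)
        table = breathing_cohort_compare(feats, cohort).set_index("feature")
        assert table.loc["gauss", "test"] == "t-test"
        assert table.loc["skewed", "test"] == "mwu+mood"

    def test_tiny_cohort_skipped(self):
        feats = pd.DataFrame({"f": np.arange(12.0)})
        cohort = np.array(["a"] * 10 + ["b"] * 2)
        table = breathing_cohort_compare(feats, cohort)
        assert table.loc[0, "test"] == "skipped"
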