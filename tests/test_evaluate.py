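import warnings

import numpy as np
import pandas as pd
import pytest

from actisurv import evaluate as ev
from actisurv.spls import SparsePLSCoxScorer

from conftest import make_survival


def harrell_oracle(lp, t, d):
    conc = ties = npairs = 0
    n = len(t)
    for i in range(n):
        if d[i] != 1:
            continue
        for j in range(n):
            if t[i] < t[j]:
                npairs += 1
                if lp[i] > lp[j]:
                    conc += 1
                elif lp[i] == lp[j]:
                    ties += 1
    return (conc + 0.5 * ties) / npairs


class TestHarrellC:
    def test_perfect_and_reversed_ranking(self):
        t = np.array([1.0, 2.0, 3.0])
        d = np.array([1, 1, 0])
        assert ev.harrell_c(np.array([3.0, 2.0, 1.0]), (t, d)) == 1.0
        assert ev.harrell_c(np.array([1.0, 2.0, 3.0]), (t, d)) == 0.0

    def test_matches_brute_force_pair_count(self, rng):
        for _ in range(5):
            n = 200
            t = rng.exponential(5, n)
            d = (rng.random(n) < 0.5).astype(int)
            lp = np.round(rng.standard_normal(n), 1)  # force predictor ties
            assert ev.harrell_c(lp, (t, d)) == pytest.approx(
                harrell_oracle(lp, t, d), abs=1e-12)

    def test_negation_symmetry_without_ties(self, rng):
        n = 150
        t = rng.exponential(5, n)
        d = (rng.random(n) < 0.6).astype(int)
        lp = rng.standard_normal(n)
        assert ev.harrell_c(-lp, (t, d)) == pytest.approx(
            1.0 - ev.harrell_c(lp, (t, d)), abs=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            ev.harrell_c(np.ones(3), (np.arange(1.0, 4.0), np.zeros(3)))


class TestRoystonR2D:
    def test_null_predictor_near_zero(self):
        df, _ = make_survival(2000, [0.0], seed=30, baseline_rate=0.1)
        assert ev.royston_r2d(df["x0"].to_numpy(), df) < 0.02

    def test_monotone_in_effect_size(self):
        vals = []
        for b in (0.0, 0.2, 0.4, 0.8):
            df, truth = make_survival(5000, [b], seed=31, baseline_rate=0.1)
            vals.append(ev.royston_r2d(df["x0"].to_numpy(), df))
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v < 1.0 for v in vals)

    def test_constant_predictor_returns_zero_with_warning(self):
        df, _ = make_survival(100, [0.0], seed=32, baseline_rate=0.2)
        with pytest.warns(UserWarning):
            assert ev.royston_r2d(np.ones(100), df) == 0.0


class TestYouden:
    def test_perfect_separation(self):
        t = np.array([1.0, 2, 3, 9, 9, 9])
        d = np.array([1, 1, 1, 0, 0, 0])
        score = np.array([5.0, 6, 7, 1, 2, 3])
        cut, sens, spec = ev.youden_cutoff(score, (t, d))
        assert sens == 100.0 and spec == 100.0
        assert 3 < cut < 5

    def test_hand_built_matches_exhaustive_scan(self):
        score = np.array([0.1, 0.9, 0.3, 0.8, 0.2, 0.7])
        d = np.array([0, 1, 0, 1, 1, 0])
        t = np.ones(6)
        best = (-np.inf, None)
        uniq = np.sort(np.unique(score))
        for c in (uniq[:-1] + uniq[1:]) / 2:
            sens = np.mean(score[d == 1] > c)
            spec = np.mean(score[d == 0] <= c)
            if sens + spec - 1 > best[0] + 1e-12:
                best = (sens + spec - 1, (c, sens * 100, spec * 100))
        got = ev.youden_cutoff(score, (t, d))
        assert got == pytest.approx(best[1])

    def test_uninformative_score_has_small_youden_index(self, rng):
        df, _ = make_survival(2000, [0.0], seed=33, baseline_rate=0.05)
        score = rng.standard_normal(2000)
        _, sens, spec = ev.youden_cutoff(score, df)
        assert sens / 100 + spec / 100 - 1 < 0.08

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            ev.youden_cutoff(np.arange(4.0), (np.ones(4), np.ones(4)))


class TestHazardRatioPerSD:
    def test_null_feature_hr_near_one(self):
        df, _ = make_survival(2000, [0.0], seed=34, baseline_rate=0.1)
        df["x0"] /= df["x0"].std(ddof=1)
        fit = ev.fit_cox(df, ["x0"])
        hr, (lo, hi) = ev.hazard_ratio_per_sd(fit, "x0")
        assert abs(np.log(hr)) < 0.1
        # CI symmetric about the HR on the log scale
        assert np.log(hi) - np.log(hr) == pytest.approx(
            np.log(hr) - np.log(lo), abs=1e-10)

    def test_wald_formula(self):
        df, _ = make_survival(500, [0.4], seed=35, baseline_rate=0.15)
        df["x0"] /= df["x0"].std(ddof=1)
        fit = ev.fit_cox(df, ["x0"])
        hr, (lo, hi) = ev.hazard_ratio_per_sd(fit, "x0")
        b, se = fit.coef_[0], fit.se_[0]
        assert hr == pytest.approx(np.exp(b))
        assert (lo, hi) == pytest.approx((np.exp(b - 1.96 * se),
                                          np.exp(b + 1.96 * se)))

    def test_unstandardized_feature_rejected(self):
        df, _ = make_survival(300, [0.4], seed=36, baseline_rate=0.15)
        df["x0"] *= 3.0
        fit = ev.fit_cox(df, ["x0"])
        with pytest.raises(ValueError, match="standardized"):
            ev.hazard_ratio_per_sd(fit, "x0")


class TestModelComparison:
    def test_point_deltas_equal_full_sample_and_deterministic(self):
        df, _ = make_survival(300, [0.5, 0.0], seed=37, baseline_rate=0.15)
        a = ev.compare_nested_models(df, ["x0"], ["x0", "x1"], B=1, seed=5)
        b = ev.compare_nested_models(df, ["x0"], ["x0", "x1"], B=1, seed=5)
        assert a.to_dict() == b.to_dict()
        ref = ev.fit_cox(df, ["x0"])
        aug = ev.fit_cox(df, ["x0", "x1"])
        assert a.delta_aic == pytest.approx(aug.aic_ - ref.aic_)

    def test_signal_augmentation_detected(self):
        df, _ = make_survival(1500, [0.5, 0.0], seed=38, baseline_rate=0.1)
        res = ev.compare_nested_models(df, ["x1"], ["x1", "x0"], B=100,
                                       seed=1)
        assert res.delta_c > 0
        assert res.significant_c
        assert res.delta_aic < 0

    def test_non_nested_designs_rejected(self):
        df, _ = make_survival(200, [0.3, 0.0], seed=39, baseline_rate=0.2)
        with pytest.raises(ValueError):
            ev.compare_nested_models(df, ["x0"], ["x1"], B=1)

    def test_ci_bounds_ordered(self):
        df, _ = make_survival(400, [0.4, 0.0], seed=40, baseline_rate=0.12)
        res = ev.compare_nested_models(df, ["x0"], ["x0", "x1"], B=50, seed=2)
        assert res.ci_c[0] <= res.ci_c[1]
        assert res.ci_aic[0] <= res.ci_aic[1]


class TestSplineNonlinearity:
    def test_strong_quadratic_effect_detected(self):
        rng = np.random.default_rng(41)
        hits = 0
        for rep in range(5):
            n = 2000
            x = rng.standard_normal(n)
            lp = 0.5 * x ** 2 - 0.5
            t = rng.exponential(1 / (0.05 * np.exp(lp)))
            time = np.minimum(t, 8.0)
            df = pd.DataFrame({"s": x, "time_years": time,
                               "event": (t <= 8.0).astype(int)})
            p, stat = ev.spline_nonlinearity_test(df, "s")
            hits += p < 0.01
        assert hits >= 4

    def test_linear_effect_usually_not_flagged(self):
        ps = []
        for rep in range(10):
            df, _ = make_survival(800, [0.5], seed=200 + rep,
                                  baseline_rate=0.1)
            df = df.rename(columns={"x0": "s"})
            p, _ = ev.spline_nonlinearity_test(df, "s")
            ps.append(p)
        assert sum(p < 0.05 for p in ps) <= 3

    def test_low_variance_score_rejected(self):
        df, _ = make_survival(200, [0.0], seed=42, baseline_rate=0.2)
        df["s"] = np.concatenate([np.ones(190), np.full(10, 2.0)])
        with pytest.raises(ValueError, match="knots"):
            ev.spline_nonlinearity_test(df, "s")

    def test_rcs_basis_linear_in_tails(self):
        knots = np.array([-1.0, 0.0, 1.0])
        x = np.linspace(2.0, 6.0, 50)
        b = ev.rcs_basis(x, knots)[:, 0]
        slopes = np.diff(b) / np.diff(x)
        assert np.allclose(slopes, slopes[0], atol=1e-9)


class TestSubgroupAnalysis:
    def test_whole_sample_group_matches_unstratified(self):
        df, _ = make_survival(800, [0.5, 0.2], seed=43, baseline_rate=0.12)
        df = df.rename(columns={"x0": "score_1"})
        df["grp"] = "all"
        tab = ev.subgroup_analysis(df, "score_1", ["x1"], "grp", B=30, seed=3)
        fit = ev.fit_cox(df, ["x1", "score_1"])
        ci = fit.confidence_intervals().loc["score_1"]
        assert tab.loc[0, "hr"] == pytest.approx(np.exp(ci["coef"]))

    def test_zero_event_stratum_skipped_with_warning(self):
        df, _ = make_survival(400, [0.5], seed=44, baseline_rate=0.12)
        df = df.rename(columns={"x0": "score_1"})
        df["x1"] = np.random.default_rng(0).standard_normal(len(df))
        df["grp"] = np.where(np.arange(len(df)) < 20, "tiny", "rest")
        df.loc[df["grp"] == "tiny", "event"] = 0
        with pytest.warns(UserWarning, match="tiny"):
            tab = ev.subgroup_analysis(df, "score_1", ["x1"], "grp", B=20,
                                       seed=3)
        assert list(tab["group"]) == ["grp=rest"]

    def test_homogeneous_effect_consistent_across_strata(self):
        df, _ = make_survival(3000, [0.5, 0.0], seed=45, baseline_rate=0.12)
        df = df.rename(columns={"x0": "score_1"})
        df["grp"] = np.where(df["x1"] > 0, "a", "b")
        tab = ev.subgroup_analysis(df, "score_1", ["x1"], "grp", B=20, seed=3)
        # per-group CIs overlap under a homogeneous simulated effect
        assert tab.loc[0, "hr_lo"] < tab.loc[1, "hr_hi"]
        assert tab.loc[1, "hr_lo"] < tab.loc[0, "hr_hi"]


class TestExternalValidation:
    @pytest.fixture
    def model_and_cohorts(self):
        df, _ = make_survival(900, [0.5, -0.4, 0.0, 0.0], seed=46,
                              baseline_rate=0.1)
        X = df[[f"x{j}" for j in range(4)]]
        model = SparsePLSCoxScorer(n_components=1, eta=0.3).fit(X, df)
        ext, _ = make_survival(700, [0.5, -0.4, 0.0, 0.0], seed=47,
                               baseline_rate=0.1)
        for d in (df, ext):
            d["age"] = np.random.default_rng(1).standard_normal(len(d))
        return model, df, ext

    def test_identity_transport_reproduces_internal_panel(self,
                                                          model_and_cohorts):
        model, df, _ = model_and_cohorts
        X = df[[f"x{j}" for j in range(4)]]
        res = ev.external_validation(model, X, df, ["age"],
                                     standardization="derivation", B=10,
                                     seed=0)
        internal = df.copy()
        internal["score_1"] = model.transform(X)[:, 0]
        panel = ev.performance_panel(internal, ["age", "score_1"])
        assert res["model2"]["c_index"] == pytest.approx(panel.c_index)
        assert res["model2"]["aic"] == pytest.approx(panel.aic)

    def test_transportable_signal_detected(self, model_and_cohorts):
        model, _, ext = model_and_cohorts
        X = ext[[f"x{j}" for j in range(4)]]
        res = ev.external_validation(model, X, ext, ["age"], B=60, seed=1)
        assert res["hr"] > 1.0
        assert res["comparison"]["delta_c"] > 0

    def test_null_transport_hr_near_one(self):
        df, _ = make_survival(800, [0.6, 0.0], seed=48, baseline_rate=0.1)
        X = df[["x0", "x1"]]
        model = SparsePLSCoxScorer(n_components=1, eta=0.0).fit(X, df)
        nullext, _ = make_survival(800, [0.0, 0.0], seed=49,
                                   baseline_rate=0.1)
        nullext["age"] = np.random.default_rng(2).standard_normal(800)
        res = ev.external_validation(model, nullext[["x0", "x1"]], nullext,
                                     ["age"], B=10, seed=2)
        assert res["hr_ci"][0] < 1.0 < res["hr_ci"][1]


def test_performance_panel_fields_in_range():
    df, _ = make_survival(600, [0.5], seed=50, baseline_rate=0.12)
    panel = ev.performance_panel(df, ["x0"], B=25, seed=0)
    d = panel.to_dict()
    assert 0.0 <= d["c_index"] <= 1.0
    assert 0.0 <= d["r2d"] < 1.0
    assert 0.0 <= d["sensitivity_pct"] <= 100.0
    assert 0.0 <= d["specificity_pct"] <= 100.0
    assert d["c_index_ci"][0] <= d["c_index"] <= d["c_index_ci"][1]
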