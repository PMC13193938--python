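import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from habitatpipe.evaluation import (
    baseline_table_tests,
    calibration_curve,
    confusion_metrics,
    decision_curve,
    delong_test,
    km_logrank,
    mrecist_classify,
    nri_idi,
    roc_auc,
    roc_points,
    shapley_attributions,
    youden_cutoff,
)


class TestMrecist:
    @pytest.mark.parametrize("baseline,followup,enh,new,expected", [
        (100, 70, True, False, "PR"),    # 30% decrease threshold met
        (100, 120, True, False, "PD"),   # 20% increase threshold met
        (100, 71, True, False, "SD"),    # 29% < 30%
        (100, 119, True, False, "SD"),   # 19% < 20%
        (100, 50, False, False, "CR"),   # no residual enhancement
        (100, 90, True, True, "PD"),     # new lesions trump shrinkage
    ])
    def test_categories(self, baseline, followup, enh, new, expected):
        a = mrecist_classify(baseline, followup, enh, new)
        assert a.category == expected
        assert a.orr_positive == (expected in ("CR", "PR"))

    def test_invalid_sums_rejected(self):
        with pytest.raises(ValueError):
            mrecist_classify(0, 10, True, False)
        with pytest.raises(ValueError):
            mrecist_classify(100, -1, True, False)


class TestRocAuc:
    def test_exhaustive_pair_count_oracle(self):
        scores = [0.9, 0.8, 0.7, 0.1]
        labels = [1, 0, 1, 0]
        # concordant pairs: (0.9>0.8), (0.9>0.1), (0.7<0.8 -> 0), (0.7>0.1)
        assert roc_auc(scores, labels)["auc"] == pytest.approx(0.75)

    def test_random_instances_match_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.normal(size=20)
            labels = rng.integers(0, 2, 20)
            if len(np.unique(labels)) < 2:
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            brute = np.mean([(1.0 if p > n else 0.5 if p == n else 0.0)
                             for p in pos for n in neg])
            assert roc_auc(scores, labels)["auc"] == pytest.approx(brute, abs=1e-10)

    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r["auc"] == 1.0
        assert r["ci95"][1] == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])["auc"] == pytest.approx(0.5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=15)
        labels = np.array([0, 1] * 7 + [1])
        a1 = roc_auc(scores, labels)["auc"]
        a2 = roc_auc(np.exp(2.0 * scores), labels)["auc"]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_roc_staircase_monotone(self):
        rng = np.random.default_rng(3)
        pts = roc_points(rng.normal(size=30), rng.integers(0, 2, 30))
        assert pts.iloc[0].tolist() == [0.0, 0.0]
        assert pts.iloc[-1].tolist() == [1.0, 1.0]
        assert (pts.diff().dropna() >= -1e-12).all().all()


def _delong_cov_oracle(sa, sb, y):
    """Direct structural-component covariance computation on a small instance."""
    sa, sb, y = map(np.asarray, (sa, sb, y))
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    m, n = len(pos), len(neg)

    def psi(x, yv):
        return 1.0 if x > yv else (0.5 if x == yv else 0.0)

    out = {}
    for name, s in (("a", sa), ("b", sb)):
        auc = np.mean([psi(s[i], s[j]) for i in pos for j in neg])
        v10 = np.array([np.mean([psi(s[i], s[j]) for j in neg]) for i in pos])
        v01 = np.array([np.mean([psi(s[i], s[j]) for i in pos]) for j in neg])
        out[name] = (auc, v10, v01)
    cov10 = np.cov(np.vstack([out["a"][1], out["b"][1]]), ddof=1)
    cov01 = np.cov(np.vstack([out["a"][2], out["b"][2]]), ddof=1)
    var = (cov10[0, 0] + cov10[1, 1] - 2 * cov10[0, 1]) / m \
        + (cov01[0, 0] + cov01[1, 1] - 2 * cov01[0, 1]) / n
    return out["a"][0], out["b"][0], var


class TestDelong:
    def test_identical_scores_give_p_one(self):
        s = [0.9, 0.8, 0.7, 0.1]
        r = delong_test(s, s, [1, 0, 1, 0])
        assert r["z"] == 0.0 and r["p"] == 1.0

    def test_small_instance_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
            sa = rng.normal(size=8)
            sb = 0.5 * sa + rng.normal(size=8)
            auc_a, auc_b, var = _delong_cov_oracle(sa, sb, y)
            r = delong_test(sa, sb, y)
            assert r["auc_a"] == pytest.approx(auc_a, abs=1e-10)
            assert r["auc_b"] == pytest.approx(auc_b, abs=1e-10)
            if var > 1e-24:
                z_oracle = (auc_a - auc_b) / math.sqrt(var)
                assert r["z"] == pytest.approx(z_oracle, abs=1e-10)
            else:  # degenerate variance of the difference
                assert r["z"] == 0.0 and r["p"] == 1.0

    def test_type_one_error_near_nominal(self):
        # independent noise scores, n=60: rejection rate within [0.035, 0.065]
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 2000
        y = np.repeat([0, 1], 30)
        for _ in range(reps):
            sa = rng.normal(size=60)
            sb = rng.normal(size=60)
            if delong_test(sa, sb, y)["p"] < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065


class TestConfusion:
    def test_perfect_classifier(self):
        m = confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert all(m[k] == 1.0 for k in
                   ("accuracy", "sensitivity", "specificity", "ppv", "npv"))

    def test_hand_2x2_arithmetic(self):
        scores = np.concatenate([np.full(9, 0.9), np.full(1, 0.1),   # 9 TP, 1 FN
                                 np.full(2, 0.9), np.full(8, 0.1)])  # 2 FP, 8 TN
        labels = np.array([1] * 10 + [0] * 10)
        m = confusion_metrics(scores, labels, 0.5)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["ppv"] == pytest.approx(9 / 11)
        assert m["npv"] == pytest.approx(8 / 9)

    def test_all_positive_predictions_yield_sentinel_npv(self):
        m = confusion_metrics([0.9, 0.8], [1, 0], 0.0)
        assert m["specificity"] == 0.0
        assert np.isnan(m["npv"])


class TestNriIdi:
    def test_no_change_gives_zero(self):
        p = [0.2, 0.7, 0.4]
        r = nri_idi(p, p, [1, 0, 1])
        assert r["nri"] == 0.0 and r["idi"] == 0.0

    def test_perfect_upgrade_hand_computed(self):
        labels = [1, 1, 1, 0, 0, 0]
        r = nri_idi([0.5] * 6, labels, labels)
        assert r["nri"] == pytest.approx(2.0)
        assert r["idi"] == pytest.approx(1.0)  # mean separation gained

    def test_sign_symmetry(self):
        rng = np.random.default_rng(0)
        po, pn = rng.uniform(size=20), rng.uniform(size=20)
        y = rng.integers(0, 2, 20)
        fwd = nri_idi(po, pn, y)
        rev = nri_idi(pn, po, y)
        assert fwd["nri"] == pytest.approx(-rev["nri"])
        assert fwd["idi"] == pytest.approx(-rev["idi"])


class TestCalibration:
    def test_well_calibrated_simulation_slope_near_one(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 2000)
        y = (rng.uniform(size=2000) < p).astype(int)
        r = calibration_curve(p, y)
        assert 0.8 <= r["slope"] <= 1.2
        assert len(r["bins"]) >= 8

    def test_constant_probability_single_bin(self):
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
        r = calibration_curve(np.full(10, 0.52), y)
        assert len(r["bins"]) == 1
        assert r["bins"].iloc[0]["observed_rate"] == pytest.approx(0.5)

    def test_anticalibrated_slope_negative(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, 500)
        y = (rng.uniform(size=500) < (1 - p)).astype(int)
        assert calibration_curve(p, y)["slope"] < 0


class TestDecisionCurve:
    def test_treat_none_reference_is_zero(self):
        rng = np.random.default_rng(0)
        d = decision_curve(rng.uniform(size=50), rng.integers(0, 2, 50))
        assert (d["treat_none"] == 0).all()

    def test_treat_all_closed_form_on_grid(self):
        y = np.repeat([1, 0], 25)  # prevalence 0.5
        d = decision_curve(np.ones(50), y, thresholds=[0.25, 0.5, 0.75])
        for _, row in d.iterrows():
            pt = row["threshold"]
            expected = 0.5 - 0.5 * pt / (1 - pt)
            assert row["treat_all"] == pytest.approx(expected)
            assert row["net_benefit"] == pytest.approx(expected)  # model == treat-all

    def test_perfect_model_net_benefit_is_prevalence(self):
        y = np.repeat([1, 0], 20)
        d = decision_curve(y.astype(float), y, thresholds=np.linspace(0.1, 0.9, 9))
        np.testing.assert_allclose(d["net_benefit"], 0.5)

    def test_no_model_beats_perfect_classifier(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100)
        p = rng.uniform(size=100)
        grid = np.linspace(0.05, 0.95, 19)
        model = decision_curve(p, y, grid)["net_benefit"]
        perfect = decision_curve(y.astype(float), y, grid)["net_benefit"]
        assert (model <= perfect + 1e-12).all()


class TestShapley:
    def test_additive_model_closed_form(self):
        rng = np.random.default_rng(0)
        bg = rng.normal(size=(40, 3))
        inst = rng.normal(size=(5, 3))
        r = shapley_attributions(lambda x: x.sum(axis=1), bg, inst)
        np.testing.assert_allclose(r["attributions"], inst - bg.mean(axis=0),
                                   atol=1e-10)

    def test_ignored_feature_gets_zero(self):
        rng = np.random.default_rng(1)
        bg = rng.normal(size=(30, 3))
        inst = rng.normal(size=(4, 3))
        r = shapley_attributions(lambda x: x[:, 0] ** 2, bg, inst)
        np.testing.assert_allclose(r["attributions"][:, 1:], 0.0, atol=1e-12)

    def test_local_accuracy_identity(self):
        rng = np.random.default_rng(2)
        bg = rng.normal(size=(25, 4))
        inst = rng.normal(size=(20, 4))

        def model(x):
            return 1.0 / (1.0 + np.exp(-(x[:, 0] + 0.5 * x[:, 1] * x[:, 2])))

        r = shapley_attributions(model, bg, inst)
        np.testing.assert_allclose(r["base_value"] + r["attributions"].sum(axis=1),
                                   model(inst), atol=1e-6)

    def test_too_many_features_refused(self):
        with pytest.raises(ValueError, match="sampling"):
            shapley_attributions(lambda x: x.sum(1), np.zeros((2, 16)),
                                 np.zeros((1, 16)))


class TestYouden:
    def test_separated_scores_midpoint(self):
        assert youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == pytest.approx(0.5)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            scores = rng.normal(size=25)
            labels = rng.integers(0, 2, 25)
            if len(np.unique(labels)) < 2:
                continue
            t = youden_cutoff(scores, labels)
            uniq = np.unique(scores)
            mids = (uniq[:-1] + uniq[1:]) / 2

            def j(th):
                pred = scores >= th
                sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
                spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
                return sens + spec - 1

            best = max(j(th) for th in mids)
            assert j(t) == pytest.approx(best, abs=1e-12)
            # tie rule: no lower midpoint attains the same J
            assert not any(th < t and j(th) >= j(t) - 1e-12 for th in mids)

    def test_degenerate_constant_scores_warn(self):
        with pytest.warns(UserWarning):
            t = youden_cutoff([0.4, 0.4, 0.4], [1, 0, 1])
        assert t == 0.4


class TestKmLogrank:
    def test_identical_groups_null(self):
        t = np.arange(1.0, 11.0)
        r = km_logrank(np.concatenate([t, t]),
                       np.ones(20, int), np.repeat(["a", "b"], 10))
        assert r["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert r["p"] == pytest.approx(1.0)

    def test_uncensored_km_equals_empirical_survival_and_median(self):
        times = np.arange(1.0, 11.0)
        r = km_logrank(np.concatenate([times, [1.0, 2.0]]),
                       np.ones(12, int),
                       np.array(["a"] * 10 + ["b"] * 2))
        curve = r["curves"]["a"]
        surv = dict(zip(curve["time"], curve["survival"]))
        for i, t in enumerate(times, start=1):
            assert surv[t] == pytest.approx(1.0 - i / 10)
        assert r["medians"]["a"] == 5.0  # first time with S <= 0.5

    def test_logrank_power_under_true_hazard_ratio(self):
        rng = np.random.default_rng(0)
        hits = 0
        reps = 200
        for _ in range(reps):
            t1 = rng.exponential(10.0, 100)
            t2 = rng.exponential(5.0, 100)  # HR 2
            times = np.concatenate([t1, t2])
            r = km_logrank(times, np.ones(200, int), np.repeat(["lo", "hi"], 100))
            hits += r["p"] < 0.05
        assert hits / reps >= 0.8

    def test_positive_time_required(self):
        with pytest.raises(ValueError):
            km_logrank([0.0, 1.0], [1, 1], ["a", "b"])


class TestBaselineTable:
    def test_identical_groups_give_high_p(self):
        df = pd.DataFrame({"age": np.tile(np.arange(10.0), 2),
                           "sex": np.tile([0, 1], 10)})
        groups = np.repeat([0, 1], 10)
        out = baseline_table_tests(df, groups, ["age"], ["sex"])
        assert (out["p"] > 0.9).all()

    def test_fisher_matches_hypergeometric_enumeration(self):
        # 2x2 table (8,2 / 1,9)
        var = np.array([0] * 10 + [1] * 10)
        grp = np.array([0] * 8 + [1] * 2 + [0] * 1 + [1] * 9)
        df = pd.DataFrame({"v": var})
        out = baseline_table_tests(df, grp, [], ["v"])
        assert out.iloc[0]["test"] == "fisher"
        expected = stats.fisher_exact([[8, 2], [1, 9]])[1]
        assert out.iloc[0]["p"] == pytest.approx(expected, abs=1e-10)
        # independent check: two-sided exact p by enumerating the support
        table = np.array([[8, 2], [1, 9]])
        n1, n2 = table[0].sum(), table[1].sum()
        c1 = table[:, 0].sum()
        rv = stats.hypergeom(n1 + n2, n1, c1)
        probs = rv.pmf(np.arange(max(0, c1 - n2), min(c1, n1) + 1))
        p_obs = rv.pmf(8)
        manual = probs[probs <= p_obs * (1 + 1e-9)].sum()
        assert out.iloc[0]["p"] == pytest.approx(manual, abs=1e-10)

    def test_sparse_cell_routes_to_fisher(self):
        # expected cell counts ~3.2 in a 2x2 design
        var = np.array([0] * 24 + [1] * 8)
        grp = np.array(([0] * 12 + [1] * 12) + [0] * 4 + [1] * 4)
        out = baseline_table_tests(pd.DataFrame({"v": var}), grp, [], ["v"])
        assert out.iloc[0]["test"] == "fisher"

    def test_continuous_routing_by_normality(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"normal": rng.normal(size=60),
                           "skewed": rng.exponential(size=60) ** 3})
        grp = np.repeat([0, 1], 30)
        out = baseline_table_tests(df, grp, ["normal", "skewed"], [])
        routing = dict(zip(out["variable"], out["test"]))
        assert routing["normal"] == "t"
        assert routing["skewed"] == "mwu"
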