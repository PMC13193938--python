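import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from habitatpipe.modeling import (
    clinical_model,
    oof_probabilities,
    repeated_cv_stability,
    select_best,
    smote_oversample,
    stack_combined,
    train_candidates,
)

TINY_GRIDS = {
    "rf": [{"n_estimators": 50}],
    "xgb": [{"n_estimators": 50, "max_depth": 3}],
    "mlp": [{"hidden_layer_sizes": (16,)}],
    "extratrees": [{"n_estimators": 50}],
}


class TestSmote:
    def test_upsamples_to_parity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 3))
        y = np.array([1] * 8 + [0] * 22)
        xs, ys = smote_oversample(x, y, seed=0)
        assert (ys == 0).sum() == (ys == 1).sum() == 22
        np.testing.assert_array_equal(xs[:30], x)

    def test_balanced_input_unchanged(self):
        x = np.arange(12.0).reshape(6, 2)
        y = np.array([0, 1, 0, 1, 0, 1])
        xs, ys = smote_oversample(x, y, seed=0)
        np.testing.assert_array_equal(xs, x)
        np.testing.assert_array_equal(ys, y)

    def test_two_point_minority_interpolates_on_segment(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 0.0], [5.0, 1.0], [5.0, 2.0]])
        y = np.array([1, 1, 0, 0, 0])
        xs, ys = smote_oversample(x, y, k=1, seed=0)
        synth = xs[5:]
        # with k=1 the only neighbour is the other minority point, so every
        # synthetic sample lies on the segment (0,0)-(1,1)
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert np.all((synth >= 0.0) & (synth <= 1.0))

    def test_synthetic_points_colinear_with_minority_pairs(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(120, 2))
        y = (np.arange(120) < 20).astype(int)
        xs, ys = smote_oversample(x, y, k=5, seed=1)
        minority = x[y == 1]
        for p in xs[120:]:
            # colinearity: p = a + u (b - a) for some minority pair a, b
            diffs = minority - p
            cross = np.abs(diffs[:, None, 0] * diffs[None, :, 1]
                           - diffs[:, None, 1] * diffs[None, :, 0])
            d = np.linalg.norm(diffs, axis=1)
            between = (d[:, None] + d[None, :]
                       - np.linalg.norm(minority[:, None] - minority[None, :],
                                        axis=2))
            assert np.any((cross < 1e-8) & (np.abs(between) < 1e-8))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            smote_oversample(np.zeros((4, 2)), np.zeros(4), seed=0)


class TestTrainCandidates:
    def test_null_features_give_chance_level_auc(self):
        rng = np.random.default_rng(0)
        aucs = []
        for seed in range(5):
            x = rng.normal(size=(60, 4))
            y = rng.integers(0, 2, 60)
            if len(np.unique(y)) < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bundles = train_candidates(x, y, grids=TINY_GRIDS, seed=seed)
            xv = rng.normal(size=(60, 4))
            yv = rng.integers(0, 2, 60)
            aucs.extend(roc_auc_score(yv, b.predict_proba(xv)) for b in bundles)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_separable_toy_reaches_training_auc(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(60, 2))
        y = (x[:, 0] + x[:, 1] > 0).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundles = train_candidates(x, y, grids=TINY_GRIDS, seed=0)
        for b in bundles:
            assert roc_auc_score(y, b.predict_proba(x)) >= 0.99

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(50, 3))
        y = (x[:, 0] > 0).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b1 = train_candidates(x, y, algorithms=("rf",), grids=TINY_GRIDS, seed=5)[0]
            b2 = train_candidates(x, y, algorithms=("rf",), grids=TINY_GRIDS, seed=5)[0]
        np.testing.assert_allclose(b1.predict_proba(x), b2.predict_proba(x),
                                   atol=1e-12)


class TestSelectBest:
    def _bundle(self, probs, algorithm="rf"):
        class _Fixed:
            def __init__(self, p):
                self._p = np.asarray(p)

            def predict_proba(self, x):
                return np.column_stack([1 - self._p, self._p])

        from habitatpipe.modeling import ModelBundle
        return ModelBundle(region="r", algorithm=algorithm, hyperparameters={},
                           fitted_state=_Fixed(probs), training_seed=0)

    def test_single_bundle_returned(self):
        b = self._bundle([0.9, 0.1])
        assert select_best([b], np.zeros((2, 1)), [1, 0]) is b

    def test_higher_auc_wins(self):
        good = self._bundle([0.9, 0.8, 0.2, 0.1])
        bad = self._bundle([0.4, 0.6, 0.5, 0.6], algorithm="mlp")
        assert select_best([bad, good], np.zeros((4, 1)), [1, 1, 0, 0]) is good

    def test_auc_tie_broken_by_accuracy(self):
        # same ranking (AUC 1.0) but different 0.5-thresholded accuracy
        sharp = self._bundle([0.9, 0.8, 0.2, 0.1])
        shifted = self._bundle([0.45, 0.40, 0.2, 0.1], algorithm="mlp")
        assert select_best([shifted, sharp], np.zeros((4, 1)), [1, 1, 0, 0]) is sharp


class TestClinicalModel:
    def test_planted_or_recovered_within_band(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            z = rng.normal(size=n)
            noise = rng.normal(size=n)
            y = (rng.uniform(size=n) < 1 / (1 + np.exp(-np.log(3.0) * z))).astype(int)
            df = pd.DataFrame({"planted": z, "noise": noise})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                b = clinical_model(df, ["planted", "noise"], y)
            ors = b.metadata.get("odds_ratios", {})
            if "planted" in ors and 2.0 <= ors["planted"]["or"] <= 4.5:
                hits += 1
        assert hits >= 18  # >= 90% of sims

    def test_null_covariate_rarely_included(self):
        included = 0
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            n = 150
            df = pd.DataFrame({"noise": rng.normal(size=n)})
            y = rng.integers(0, 2, n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                b = clinical_model(df, ["noise"], y)
            included += "noise" in b.metadata["covariates"]
        assert included / 40 < 0.15  # ~5% nominal type-I rate

    def test_single_planted_predictor_is_final_model(self):
        rng = np.random.default_rng(37)
        n = 300
        z = rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-1.5 * z))).astype(int)
        df = pd.DataFrame({"planted": z, "n1": rng.normal(size=n),
                           "n2": rng.normal(size=n)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b = clinical_model(df, ["planted", "n1", "n2"], y)
        assert b.metadata["covariates"] == ["planted"]


class TestStacking:
    def test_identical_bases_add_nothing(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 80)
        p = np.clip(0.5 + (y - 0.5) * rng.uniform(0, 0.6, 80), 0.01, 0.99)
        combined = stack_combined(p, p, p, y)
        pc = combined.predict_proba(np.column_stack([p, p, p]))
        assert roc_auc_score(y, pc) == pytest.approx(roc_auc_score(y, p))

    def test_constant_base_gets_near_zero_weight(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 300)
        informative = np.clip(0.5 + (y - 0.5) * rng.uniform(0, 0.8, 300), 0.01, 0.99)
        flat = np.full(300, 0.5)
        combined = stack_combined(informative, flat, informative, y)
        coefs = combined.metadata["coefficients"]
        assert abs(coefs["radiomics_b"]) < 1e-2

    def test_two_informative_bases_do_not_hurt(self):
        # stacked AUC >= max(base AUCs) - 0.02 across seeds
        margin_ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 150
            z = rng.integers(0, 2, n)
            pa = np.clip(0.5 + (z - 0.5) * 0.3 + rng.normal(0, 0.15, n), 0.01, 0.99)
            pb = np.clip(0.5 + (z - 0.5) * 0.3 + rng.normal(0, 0.15, n), 0.01, 0.99)
            pc = np.clip(0.5 + rng.normal(0, 0.05, n), 0.01, 0.99)
            combined = stack_combined(pa, pb, pc, z)
            ps = combined.predict_proba(np.column_stack([pa, pb, pc]))
            base = max(roc_auc_score(z, pa), roc_auc_score(z, pb))
            margin_ok += roc_auc_score(z, ps) >= base - 0.02
        assert margin_ok >= 19

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            stack_combined(np.zeros(5), np.zeros(4), np.zeros(5), np.zeros(5))


class TestRepeatedCV:
    def _fit_predict(self, xt, yt, xv):
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(max_iter=500).fit(xt, yt)
        return clf.predict_proba(xv)[:, 1]

    def test_null_data_near_chance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 3))
        y = rng.integers(0, 2, 200)
        aucs = repeated_cv_stability(self._fit_predict, x, y, repeats=10, seed=0)
        assert abs(aucs.mean() - 0.5) < 0.08

    def test_planted_signal_detected(self):
        rng = np.random.default_rng(1)
        n = 120
        x = rng.normal(size=(n, 3))
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-2.5 * x[:, 0]))).astype(int)
        aucs = repeated_cv_stability(self._fit_predict, x, y, repeats=5, seed=0)
        assert aucs.mean() >= 0.8

    def test_oof_probabilities_cover_every_patient(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(60, 3))
        y = (x[:, 0] > 0).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = oof_probabilities("rf", {"n_estimators": 30}, x, y, seed=0)
        assert np.all(np.isfinite(p)) and np.all((p > 0) & (p < 1))
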