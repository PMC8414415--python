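"""CSP eigenstructure, log-variance features, CV decoding, confusion metrics."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from mirp.decode import (class_covariance, confusion_metrics, crossval_classify,
                         csp_features, fit_csp_binary, fit_csp_ovr)
from mirp.io import EpochSet, StageWindow, concat_epochs, extract_epochs, \
    split_subepochs
from mirp.preproc import fir_bandpass
from mirp.synth import StudyConfig, make_cohort, simulate_run

TASK = StageWindow("task", 0.5, 4.5)


def _epochset(data, labels, fs=500.0):
    n = data.shape[0]
    prov = pd.DataFrame({"subject": [1] * n, "session": [1] * n,
                         "run": [1] * n, "trial": range(n)})
    return EpochSet(data=data, labels=np.asarray(labels, dtype=object),
                    provenance=prov,
                    channels=[f"ch{i}" for i in range(data.shape[1])],
                    fs=fs, window=(0.0, data.shape[2] / fs))


class TestClassCovariance:
    def test_identical_epochs_equal_single_epoch_covariance(self, rng):
        x = rng.normal(size=(1, 4, 200))
        ep = _epochset(np.repeat(x, 5, axis=0), ["left"] * 5)
        C = class_covariance(ep, "left")
        X = x[0] - x[0].mean(axis=1, keepdims=True)
        single = X @ X.T / (X.shape[1] - 1)
        single /= np.trace(single)
        np.testing.assert_allclose(C, single + 1e-8 * np.mean(np.diag(single))
                                   * np.eye(4), atol=1e-12)

    def test_trace_is_one_plus_ridge(self, rng):
        ep = _epochset(rng.normal(size=(10, 6, 100)), ["a"] * 10)
        assert np.trace(class_covariance(ep, "a")) == pytest.approx(1.0, abs=1e-6)

    def test_white_noise_covariance_approaches_scaled_identity(self, rng):
        n_ch = 5
        ep = _epochset(rng.normal(size=(200, n_ch, 250)), ["a"] * 200)
        C = class_covariance(ep, "a")
        np.testing.assert_allclose(C, np.eye(n_ch) / n_ch, atol=0.01)

    def test_absent_label_rejected(self, rng):
        ep = _epochset(rng.normal(size=(4, 3, 50)), ["a"] * 4)
        with pytest.raises(ValueError, match="label"):
            class_covariance(ep, "b")


class TestCSPBinary:
    def test_two_channel_toy_closed_form(self):
        """cov_t=diag(4,1), cov_rest=diag(1,4): generalized eigenvalues of
        C_t w = lambda (C_t + C_rest) w are 4/5 and 1/5 with axis filters."""
        model = fit_csp_binary(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]),
                               n_filters=2)
        np.testing.assert_allclose(model.eigenvalues, [0.8, 0.2], atol=1e-12)
        first, last = model.filters
        assert abs(first[0]) > 100 * abs(first[1])   # ~ e1
        assert abs(last[1]) > 100 * abs(last[0])     # ~ e2

    def test_identical_covariances_give_half_eigenvalues(self, rng):
        A = rng.normal(size=(4, 4))
        C = A @ A.T + np.eye(4)
        model = fit_csp_binary(C, C.copy(), n_filters=4)
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=1e-10)

    def test_agrees_with_dense_eigensolver_on_random_spd_pairs(self, rng):
        for _ in range(5):
            A = rng.normal(size=(6, 6))
            B = rng.normal(size=(6, 6))
            Ca = A @ A.T + 0.1 * np.eye(6)
            Cb = B @ B.T + 0.1 * np.eye(6)
            model = fit_csp_binary(Ca, Cb, n_filters=6)
            ref = np.sort(scipy.linalg.eigvals(Ca, Ca + Cb).real)
            got = np.sort(model.eigenvalues)
            np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_first_filter_maximizes_variance_ratio(self, rng):
        A = rng.normal(size=(4, 4))
        B = rng.normal(size=(4, 4))
        Ca = A @ A.T + 0.1 * np.eye(4)
        Cb = B @ B.T + 0.1 * np.eye(4)
        model = fit_csp_binary(Ca, Cb, n_filters=2)
        w = model.filters[0]
        best = w @ Ca @ w / (w @ (Ca + Cb) @ w)
        dirs = rng.normal(size=(2000, 4))
        ratios = np.einsum("ij,jk,ik->i", dirs, Ca, dirs) / \
            np.einsum("ij,jk,ik->i", dirs, Ca + Cb, dirs)
        assert best >= ratios.max() - 1e-9

    def test_odd_filter_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            fit_csp_binary(np.eye(3), np.eye(3), n_filters=3)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            fit_csp_binary(bad, np.eye(2), n_filters=2)


class TestCSPOVR:
    def test_filter_count_three_classes(self, rng):
        data = rng.normal(size=(30, 5, 100))
        ep = _epochset(data, ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        models = fit_csp_ovr(ep, n_filters_per_class=4)
        assert len(models) == 3
        assert sum(m.n_filters for m in models) == 12

    def test_two_classes_degenerate_to_mirrored_subspaces(self, rng):
        data = rng.normal(size=(40, 6, 200))
        data[:20, 0] *= 3.0
        data[20:, 1] *= 2.0
        ep = _epochset(data, ["a"] * 20 + ["b"] * 20)
        m_a, m_b = fit_csp_ovr(ep, n_filters_per_class=4)
        # target-vs-rest for 2 classes is the same binary problem both ways
        span_a = scipy.linalg.orth(m_a.filters.T)
        span_b = scipy.linalg.orth(m_b.filters.T)
        angles = scipy.linalg.subspace_angles(span_a, span_b)
        assert np.max(angles) < 1e-6

    def test_small_class_rejected(self, rng):
        ep = _epochset(rng.normal(size=(3, 3, 50)), ["a", "a", "b"])
        with pytest.raises(ValueError, match="2 epochs"):
            fit_csp_ovr(ep)


class TestCSPFeatures:
    def test_scale_invariance(self, rng):
        data = rng.normal(size=(12, 4, 100))
        ep = _epochset(data, ["a"] * 6 + ["b"] * 6)
        models = fit_csp_ovr(ep, n_filters_per_class=4)
        f1 = csp_features(models, ep)
        ep10 = _epochset(10.0 * data, ["a"] * 6 + ["b"] * 6)
        np.testing.assert_allclose(csp_features(models, ep10), f1, atol=1e-10)

    def test_feature_dimension(self, rng):
        data = rng.normal(size=(30, 5, 100))
        ep = _epochset(data, ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        models = fit_csp_ovr(ep, n_filters_per_class=4)
        assert csp_features(models, ep).shape == (30, 12)

    def test_target_class_loads_first_filter(self, rng):
        # two channels, class a has high variance on ch0, class b on ch1
        data = rng.normal(size=(40, 2, 500))
        data[:20, 0] *= 2.0
        data[20:, 1] *= 2.0
        ep = _epochset(data, ["a"] * 20 + ["b"] * 20)
        m_a = fit_csp_ovr(ep, n_filters_per_class=2)[0]
        feats = csp_features([m_a], ep)
        share_first = feats[:20, 0]   # log variance share of top filter
        share_last = feats[:20, 1]
        assert share_first.mean() > share_last.mean()


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        res = confusion_metrics(list("aabbcc"), list("aabbcc"))
        assert res.accuracy == 1.0
        assert res.macro_f == 1.0

    def test_three_class_hand_oracle(self):
        """Confusion [[8,1,1],[2,7,1],[0,2,8]] (rows true): per-class P/R/F
        evaluated by hand give macro-F = (0.8 + 0.7 + 0.8)/3."""
        conf = np.array([[8, 1, 1], [2, 7, 1], [0, 2, 8]])
        y_true, y_pred = [], []
        for i, cls_t in enumerate("abc"):
            for j, cls_p in enumerate("abc"):
                y_true += [cls_t] * conf[i, j]
                y_pred += [cls_p] * conf[i, j]
        res = confusion_metrics(y_true, y_pred, ("a", "b", "c"))
        assert res.accuracy == pytest.approx(23 / 30)
        assert res.macro_f == pytest.approx((0.8 + 0.7 + 0.8) / 3, abs=1e-12)
        np.testing.assert_array_equal(res.confusion, conf)

    def test_accuracy_equals_mean_agreement(self, rng):
        y_true = rng.choice(list("abc"), size=100)
        y_pred = rng.choice(list("abc"), size=100)
        res = confusion_metrics(y_true, y_pred, ("a", "b", "c"))
        assert res.accuracy == np.mean(y_true == y_pred)

    def test_single_class_all_correct(self):
        res = confusion_metrics(["a"] * 5, ["a"] * 5, ("a",))
        assert res.macro_f == 1.0

    def test_zero_denominator_class_scores_zero(self):
        # class "b" never true and never predicted -> P = R = F = 0
        res = confusion_metrics(["a", "a"], ["a", "a"], ("a", "b"))
        assert res.per_class["b"] == {"precision": 0.0, "recall": 0.0, "f": 0.0}
        assert res.macro_f == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_metrics([], [])


class TestCrossval:
    def _epochs(self, cfg, tasks, seed, n_runs=2):
        profile = make_cohort(cfg, seed)[0]
        runs = [simulate_run(profile, cfg, 1, r, seed=seed)
                for r in range(1, n_runs + 1)]
        eps = [extract_epochs(fir_bandpass(r, 8, 30), TASK, tasks)
               for r in runs]
        return split_subepochs(concat_epochs(eps), 1.0)

    def test_strong_erd_decodes_above_80_percent(self):
        cfg = StudyConfig(erd_depth_range=(0.8, 0.8), coupling=1.0,
                          noise_scale=2.0, erd_session_sd=0.0,
                          erd_trial_sd=0.0)
        ep = self._epochs(cfg, ("left", "right", "feet"), seed=3)
        res = crossval_classify(ep, ("left", "right", "feet"), seed=0)
        assert res.accuracy > 0.8

    def test_fixed_fold_seed_is_bit_identical(self, rng):
        data = rng.normal(size=(60, 4, 100))
        data[:30, 0] *= 2.0
        ep = _epochset(data, ["a"] * 30 + ["b"] * 30)
        r1 = crossval_classify(ep, ("a", "b"), n_folds=5, seed=1)
        r2 = crossval_classify(ep, ("a", "b"), n_folds=5, seed=1)
        np.testing.assert_array_equal(r1.y_pred, r2.y_pred)
        assert r1.accuracy == r2.accuracy

    def test_label_shuffle_stays_at_chance(self, rng):
        """Mean CV accuracy on label-shuffled data must not exceed chance by
        more than 3 Monte-Carlo standard errors (50 repetitions)."""
        data = rng.normal(size=(60, 4, 100))
        data[:30, 0] *= 2.0  # structure present, labels destroyed below
        accs = []
        for rep in range(50):
            labels = rng.permutation(["a"] * 30 + ["b"] * 30)
            ep = _epochset(data, labels)
            accs.append(crossval_classify(ep, ("a", "b"), n_folds=5,
                                          seed=rep).accuracy)
        mc_se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert np.mean(accs) < 0.5 + 3 * mc_se + 1e-9

    def test_insufficient_class_count_rejected(self, rng):
        ep = _epochset(rng.normal(size=(12, 3, 50)), ["a"] * 6 + ["b"] * 6)
        with pytest.raises(ValueError, match="epochs"):
            crossval_classify(ep, ("a", "b"), n_folds=10)
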