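import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import reactime as rt
from conftest import make_epochs


def toy_epochs(rng, n=40, sep=4.0, n_sensors=4, n_times=6):
    """Linearly separable two-class epochs with constant class means."""
    labels = np.repeat([0, 1], n // 2)
    means = np.zeros((2, n_sensors))
    means[0, 0] = sep / 2
    means[1, 0] = -sep / 2
    data = 0.3 * rng.standard_normal((n, n_sensors, n_times))
    data += means[labels][:, :, None]
    return make_epochs(data, labels)


class TestBalanceClasses:
    def test_majority_reduced_to_minority(self, rng):
        ep = make_epochs(rng.standard_normal((100, 2, 3)),
                         np.r_[np.zeros(60, int), np.ones(40, int)])
        out = rt.balance_classes(ep, seed=0)
        assert np.sum(out.labels == 0) == 40 and np.sum(out.labels == 1) == 40

    def test_balanced_input_unchanged(self, rng):
        ep = make_epochs(rng.standard_normal((10, 2, 3)), np.repeat([0, 1], 5))
        out = rt.balance_classes(ep, seed=0)
        np.testing.assert_array_equal(out.data, ep.data)

    def test_minority_untouched_and_subset(self, rng):
        data = rng.standard_normal((50, 2, 3))
        labels = np.r_[np.zeros(30, int), np.ones(20, int)]
        ep = make_epochs(data, labels)
        out = rt.balance_classes(ep, seed=1)
        # minority rows all present, kept rows are a subset of input rows
        kept = {row.tobytes() for row in out.data}
        assert all(row.tobytes() in kept for row in data[30:])
        all_rows = {row.tobytes() for row in data}
        assert kept <= all_rows

    def test_single_class_rejected(self, rng):
        ep = make_epochs(rng.standard_normal((5, 2, 3)), np.zeros(5, int))
        with pytest.raises(ValueError):
            rt.balance_classes(ep, seed=0)


class TestDemean:
    def test_trial_mean_zero_and_class_difference_preserved(self, rng):
        ep = make_epochs(rng.standard_normal((20, 3, 8)) + 5.0, np.repeat([0, 1], 10))
        out = rt.demean(ep)
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-10)
        diff_before = ep.data[ep.labels == 0].mean(0) - ep.data[ep.labels == 1].mean(0)
        diff_after = out.data[out.labels == 0].mean(0) - out.data[out.labels == 1].mean(0)
        np.testing.assert_allclose(diff_before, diff_after, atol=1e-10)

    def test_single_trial_becomes_zero(self, rng):
        ep = make_epochs(rng.standard_normal((1, 2, 4)), np.array([0]))
        np.testing.assert_allclose(rt.demean(ep).data, 0.0, atol=1e-12)


class TestTrainLda:
    def test_closed_form_identity_covariance(self, rng):
        # class means (1,0) and (-1,0) with ~identity pooled covariance:
        # w proportional to (2, 0)
        n = 4000
        labels = np.repeat([0, 1], n // 2)
        data = rng.standard_normal((n, 2, 1))
        data[labels == 0, 0] += 1.0
        data[labels == 1, 0] -= 1.0
        model = rt.train_lda(make_epochs(data, labels), 0.0, gamma=0.0)
        assert model.weights[0] > 0
        assert abs(model.weights[1] / model.weights[0]) < 0.1

    def test_matches_sklearn_lsqr_shrinkage(self, rng):
        """Independent cross-check: direction agrees with sklearn's shrinkage LDA."""
        n = 60
        labels = np.repeat([0, 1], n // 2)
        data = rng.standard_normal((n, 5, 1))
        data[labels == 0, 0] += 1.0
        ours = rt.train_lda(make_epochs(data, labels), 0.0, gamma=0.05)
        sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.05)
        sk.fit(data[:, :, 0], 1 - labels)  # sklearn's positive class is 1
        w_sk = sk.coef_.ravel()
        cos = ours.weights @ w_sk / (np.linalg.norm(ours.weights) * np.linalg.norm(w_sk))
        assert cos > 0.99

    def test_identical_class_means_give_zero_weights(self, rng):
        half = rng.standard_normal((5, 3, 2))
        data = np.concatenate([half, half])  # classes share the exact same points
        model = rt.train_lda(make_epochs(data, np.repeat([0, 1], 5)), 0.0, gamma=0.05)
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-12)

    def test_default_gamma_recorded(self, rng):
        ep = toy_epochs(rng)
        assert rt.train_lda(ep, 0.0).gamma == 0.05


class TestEvidence:
    def test_dot_product_and_sign_flip(self):
        model = rt.DiscriminantModel(np.array([1.0, 0.0]), 0.0, 0.0)
        data = np.tile(np.array([2.0, 5.0])[None, :, None], (2, 1, 4))
        ep = make_epochs(data, np.array([0, 1]))
        vals, _ = rt.evidence(model, ep)
        np.testing.assert_allclose(vals[0], 2.0)   # class 0: positive as-is
        np.testing.assert_allclose(vals[1], -2.0)  # class 1: flipped

    def test_zero_model_gives_zero_evidence(self, rng):
        model = rt.DiscriminantModel(np.zeros(3), 0.0, 0.0)
        ep = make_epochs(rng.standard_normal((4, 3, 5)), np.array([0, 1, 0, 1]))
        vals, _ = rt.evidence(model, ep)
        np.testing.assert_allclose(vals, 0.0)


class TestCrossvalEvidence:
    def test_folds_partition_trials(self, rng):
        ep = toy_epochs(rng, n=50)
        ev = rt.crossval_evidence(ep, [0.0], k_folds=5, seed=0)
        counts = np.bincount(ev.folds, minlength=5)
        assert np.all(ev.folds >= 0)
        assert np.all(counts == 10)  # 20% per fold

    def test_separable_data_gives_positive_evidence(self, rng):
        ep = toy_epochs(rng, n=60, sep=8.0)
        ev = rt.crossval_evidence(ep, ep.times[:3], k_folds=5, seed=1)
        assert np.all(ev.values > 0)

    def test_scale_equivariance_of_accuracy(self, rng):
        ep = toy_epochs(rng, n=40, sep=2.0)
        ev1 = rt.crossval_evidence(ep, [0.0], k_folds=4, seed=2)
        ep2 = ep.copy()
        ep2.data *= 7.5
        ev2 = rt.crossval_evidence(ep2, [0.0], k_folds=4, seed=2)
        np.testing.assert_array_equal(np.sign(ev1.values), np.sign(ev2.values))
        a1 = rt.accuracy_matrix(ev1).values
        a2 = rt.accuracy_matrix(ev2).values
        np.testing.assert_allclose(a1, a2)

    def test_shuffled_labels_decode_at_chance(self, rng):
        ep = toy_epochs(rng, n=200, sep=4.0, n_times=10)
        ep.labels = rt.permute_labels(ep.labels, seed=5)
        ev = rt.crossval_evidence(ep, ep.times[:4], k_folds=5, seed=3)
        acc = rt.accuracy_matrix(ev).values.mean()
        assert 0.45 <= acc <= 0.55

    def test_fewer_trials_than_folds_rejected(self, rng):
        ep = toy_epochs(rng, n=4)
        with pytest.raises(ValueError):
            rt.crossval_evidence(ep, [0.0], k_folds=5)


class TestAccuracyMatrix:
    def test_counting(self):
        vals = np.array([1.0, 2.0, -0.5, 3.0]).reshape(4, 1, 1)
        ev = rt.EvidenceTensor(vals, np.array([0.0]), np.array([0.0]), 300.0,
                               np.zeros(4, int), np.array([0, 0, 1, 1]))
        assert rt.accuracy_matrix(ev).values[0, 0] == 0.75

    def test_all_positive_is_one(self):
        vals = np.ones((5, 2, 3))
        ev = rt.EvidenceTensor(vals, np.zeros(2), np.arange(3) / 300.0, 300.0,
                               np.zeros(5, int), np.zeros(5, int))
        assert np.all(rt.accuracy_matrix(ev).values == 1.0)
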