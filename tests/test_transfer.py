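"""LASSO cluster transfer, Hand–Till CV AUC, and In-Group Proportion."""

import numpy as np
import pytest

import mechstrat as ms
from mechstrat.transfer import hand_till_auc


def separable_toy(n_per_class=20, n_classes=2, gap=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(c * gap, 1.0, size=(n_per_class, 2)) for c in range(n_classes)]
    )
    y = np.repeat(np.arange(n_classes), n_per_class)
    return X, y


class TestTransferClassifier:
    def test_separable_training_accuracy(self):
        X, y = separable_toy()
        clf = ms.fit_transfer_classifier(X, y, lambda_grid=np.array([1e-4]))
        assert (clf.predict(X) == y).mean() == 1.0

    def test_huge_penalty_gives_prior_predictions(self):
        X, y = separable_toy(n_per_class=30, n_classes=3)
        clf = ms.fit_transfer_classifier(X, y, lambda_grid=np.array([1e6]))
        assert np.allclose(clf.coef_, 0.0, atol=1e-6)
        proba = clf.predict_proba(X)
        priors = np.bincount(y) / len(y)
        assert np.allclose(proba, priors, atol=1e-2)

    def test_noise_feature_shrunk_at_cv_lambda(self):
        rng = np.random.default_rng(1)
        n = 300
        y = rng.integers(0, 3, n)
        X = np.column_stack([
            (y == 1) + rng.normal(0, 0.3, n),
            (y == 2) + rng.normal(0, 0.3, n),
            rng.normal(0, 1.0, n),  # pure noise
        ])
        clf = ms.fit_transfer_classifier(X, y, seed=1)
        mags = np.abs(clf.coef_).max(axis=0)
        assert mags[2] < 0.1 * mags[:2].max()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ms.fit_transfer_classifier(np.random.rand(10, 2), np.zeros(10))

    def test_nonfinite_features_rejected(self):
        X, y = separable_toy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            ms.fit_transfer_classifier(X, y)


class TestCrossValidate:
    def test_perfect_separation_auc_one(self):
        X, y = separable_toy(n_per_class=40, n_classes=3)
        auc = ms.cross_validate(X, y, repeats=1, folds=4, seed=0)
        assert auc == pytest.approx(1.0, abs=1e-6)

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 5))
        y = rng.integers(0, 4, 200)
        auc = ms.cross_validate(X, y, repeats=3, folds=5, seed=2)
        assert 0.45 <= auc <= 0.55

    def test_class_smaller_than_folds_rejected(self):
        X, y = separable_toy(n_per_class=3)
        with pytest.raises(ValueError):
            ms.cross_validate(X, y, repeats=1, folds=5)


class TestAssignClusters:
    def test_self_assignment_consistency(self):
        X, y = separable_toy(n_per_class=25, n_classes=3)
        clf = ms.fit_transfer_classifier(X, y, seed=3)
        pred, proba = ms.assign_clusters(clf, X)
        assert (pred == clf.predict(X)).all()
        # argmax margin strictly positive
        srt = np.sort(proba, axis=1)
        assert (srt[:, -1] > srt[:, -2]).all()

    def test_probabilities_sum_to_one(self):
        X, y = separable_toy(n_per_class=25, n_classes=4)
        clf = ms.fit_transfer_classifier(X, y, seed=4)
        _, proba = ms.assign_clusters(clf, np.random.default_rng(0).normal(size=(50, 2)))
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-12)


class TestIGP:
    def test_self_match_is_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        labels = rng.integers(0, 4, 40)
        res = ms.igp(X, labels, X, labels)
        assert res.overall == 1.0
        assert all(v == 1.0 for v in res.per_cluster.values())

    def test_hand_crafted_instance_matches_brute_force(self):
        disc = np.array([[0.0], [1.0], [4.0], [5.0], [9.0], [10.0]])
        disc_lab = np.array([0, 0, 1, 1, 2, 2])
        val = np.array([[0.4], [4.6], [7.2], [9.9]])
        pred = np.array([0, 1, 1, 2])
        res = ms.igp(val, pred, disc, disc_lab)
        # brute-force nearest-neighbour enumeration
        exp_agree = []
        for i in range(len(val)):
            d = np.abs(disc[:, 0] - val[i, 0])
            exp_agree.append(disc_lab[int(np.argmin(d))] == pred[i])
        assert res.overall == pytest.approx(np.mean(exp_agree))
        assert res.per_cluster[1] == pytest.approx(
            np.mean([a for a, p in zip(exp_agree, pred) if p == 1])
        )

    def test_random_labels_expected_quarter(self):
        rng = np.random.default_rng(6)
        agree = total = 0
        for _ in range(10):
            disc = rng.normal(size=(80, 3))
            disc_lab = np.repeat(np.arange(4), 20)
            val = rng.normal(size=(50, 3))
            pred = rng.integers(0, 4, 50)
            res = ms.igp(val, pred, disc, disc_lab)
            agree += res.overall * 50
            total += 50
        # binomial CI around 0.25
        p_hat = agree / total
        assert abs(p_hat - 0.25) <= 3 * np.sqrt(0.25 * 0.75 / total)

    def test_invariant_under_label_renaming(self):
        rng = np.random.default_rng(7)
        disc = rng.normal(size=(30, 2))
        disc_lab = rng.integers(0, 3, 30)
        val = rng.normal(size=(20, 2))
        pred = rng.integers(0, 3, 20)
        res = ms.igp(val, pred, disc, disc_lab)
        mapping = {0: 2, 1: 0, 2: 1}
        res2 = ms.igp(
            val,
            np.vectorize(mapping.get)(pred),
            disc,
            np.vectorize(mapping.get)(disc_lab),
        )
        assert res.overall == res2.overall

    def test_empty_cluster_flagged_nan(self):
        disc = np.array([[0.0], [1.0]])
        disc_lab = np.array([0, 1])
        with pytest.warns(UserWarning, match="IGP undefined"):
            res = ms.igp(np.array([[0.1]]), np.array([0]), disc, disc_lab)
        assert np.isnan(res.per_cluster[1])


class TestIGPPermutation:
    def _coherent_instance(self, seed=8):
        rng = np.random.default_rng(seed)
        centers = np.eye(4) * 4
        disc = np.vstack([rng.normal(centers[c], 1.0, size=(25, 4)) for c in range(4)])
        disc_lab = np.repeat(np.arange(4), 25)
        val = np.vstack([rng.normal(centers[c], 1.0, size=(15, 4)) for c in range(4)])
        pred = np.repeat(np.arange(4), 15)
        return val, pred, disc, disc_lab

    def test_coherent_clustering_significant(self):
        res = ms.igp(*self._coherent_instance())
        res = ms.igp_permutation_test(res, n_perm=500, seed=0)
        assert res.p_overall <= 0.05

    def test_p_bounded_below_by_estimator(self):
        res = ms.igp(*self._coherent_instance())
        res = ms.igp_permutation_test(res, n_perm=200, seed=1)
        assert res.p_overall >= 1 / 201

    def test_self_match_is_null_maximum(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 2))
        labels = rng.integers(0, 3, 40)
        res = ms.igp(X, labels, X, labels)
        res = ms.igp_permutation_test(res, n_perm=200, seed=2)
        assert res.overall == 1.0  # no permutation can exceed a perfect match

    def test_null_calibration_over_seeds(self):
        rng = np.random.default_rng(10)
        non_sig = 0
        n_seeds = 50
        for s in range(n_seeds):
            disc = rng.normal(size=(60, 3))
            disc_lab = rng.integers(0, 4, 60)
            val = rng.normal(size=(40, 3))
            pred = rng.integers(0, 4, 40)
            res = ms.igp(val, pred, disc, disc_lab)
            res = ms.igp_permutation_test(res, n_perm=100, seed=s)
            if res.p_overall > 0.05:
                non_sig += 1
        assert non_sig >= 0.9 * n_seeds

    def test_small_n_perm_rejected(self):
        res = ms.igp(*self._coherent_instance())
        with pytest.raises(ValueError):
            ms.igp_permutation_test(res, n_perm=50)


def test_hand_till_matches_binary_auc():
    """For two classes the Hand–Till average reduces to the ordinary AUC."""
    rng = np.random.default_rng(11)
    y = rng.integers(0, 2, 100)
    score = y + rng.normal(0, 1.2, 100)
    proba = 1 / (1 + np.exp(-score))
    P = np.column_stack([1 - proba, proba])
    from sklearn.metrics import roc_auc_score

    assert hand_till_auc(y, P, np.array([0, 1])) == pytest.approx(
        roc_auc_score(y, proba)
    )
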