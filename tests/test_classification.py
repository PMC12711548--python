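"""ReliefF ranking, the dense network, kappa, and cross-validation."""

import numpy as np
import pytest

from respconn.classification import (
    ClassifierSpec,
    DenseClassifier,
    cohens_kappa,
    cross_validate,
    relieff_rank,
    report_table,
    train_classifier,
)


def _blobs(rng, n_per_class=60, n_features=10, sep=4.0):
    """Three Gaussian blobs separated along the first feature axis pair."""
    X, y = [], []
    centers = [np.zeros(n_features) for _ in range(3)]
    centers[1][0] = sep
    centers[2][1] = sep
    for c, mu in enumerate(centers):
        X.append(mu + rng.standard_normal((n_per_class, n_features)))
        y += [("SB", "BH", "PB")[c]] * n_per_class
    return np.vstack(X), np.array(y)


class TestRelieff:
    def test_separating_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 30
        X = rng.standard_normal((3 * n, 20))
        y = np.repeat(["SB", "BH", "PB"], n)
        X[:, 7] = np.repeat([0.0, 5.0, 10.0], n) + 0.1 * rng.standard_normal(3 * n)
        sel, w = relieff_rank(X, y, n_select=5, seed=1)
        assert sel[0] == 7
        assert w[7] == w.max()

    def test_uninformative_features_have_near_zero_weights_reproducibly(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 8))
        y = np.repeat(["SB", "BH", "PB"], 20)
        sel1, w1 = relieff_rank(X, y, seed=3, n_select=8)
        sel2, w2 = relieff_rank(X, y, seed=3, n_select=8)
        assert np.array_equal(sel1, sel2)
        assert np.allclose(w1, w2)
        assert np.abs(w1).max() < 0.1

    def test_selects_requested_count(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((90, 120))
        y = np.repeat(["SB", "BH", "PB"], 30)
        sel, w = relieff_rank(X, y, n_select=30)
        assert len(sel) == 30
        assert w.shape == (120,)

    def test_small_class_rejected(self):
        X = np.random.rand(12, 4)
        y = np.array(["SB"] * 5 + ["BH"] * 5 + ["PB"] * 2)
        with pytest.raises(ValueError, match="fewer than"):
            relieff_rank(X, y, k_neighbors=10)


class TestDenseClassifier:
    def test_separable_blobs_reach_high_training_accuracy(self):
        rng = np.random.default_rng(3)
        X, y = _blobs(rng, n_per_class=40, n_features=30)
        model = train_classifier(X, y, seed=0)
        assert (model.predict(X) == y).mean() >= 0.99

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(4)
        X, y = _blobs(rng, n_per_class=20, n_features=30)
        model = train_classifier(X, y, seed=0)
        probs = model.predict_proba(X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.min() >= 0.0

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(5)
        X, y = _blobs(rng, n_per_class=20, n_features=30)
        m1 = train_classifier(X, y, seed=11)
        m2 = train_classifier(X, y, seed=11)
        assert np.array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_wrong_feature_count_rejected(self):
        with pytest.raises(ValueError, match="features"):
            train_classifier(np.zeros((10, 7)), np.array(["SB"] * 10))

    def test_too_many_labels_rejected(self):
        spec = ClassifierSpec(input_dim=4)
        X = np.zeros((8, 4))
        y = np.array(["a", "b", "c", "d"] * 2)
        with pytest.raises(ValueError, match="labels"):
            DenseClassifier(spec).fit(X, y)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(dropout=1.0)
        with pytest.raises(ValueError):
            ClassifierSpec(input_dim=0)


class TestCohensKappa:
    def test_perfect_diagonal_gives_one(self):
        assert cohens_kappa(np.diag([10, 10, 10])) == pytest.approx(1.0)

    def test_hand_computed_single_error_case(self):
        c = np.array([[9, 1, 0], [0, 10, 0], [0, 0, 10]])
        # p_o = 29/30; p_e = (10*9 + 10*11 + 10*10)/900 = 300/900
        expected = (29 / 30 - 300 / 900) / (1 - 300 / 900)
        assert cohens_kappa(c) == pytest.approx(expected, abs=1e-12)

    def test_uniform_confusion_gives_zero(self):
        assert cohens_kappa(np.full((3, 3), 7)) == pytest.approx(0.0)

    def test_invariant_to_count_scaling(self):
        rng = np.random.default_rng(6)
        c = rng.integers(1, 30, size=(3, 3))
        assert cohens_kappa(c) == pytest.approx(cohens_kappa(5 * c), abs=1e-12)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cohens_kappa(np.array([[5, 0], [0, 0]]))
        with pytest.raises(ValueError, match="zero total"):
            cohens_kappa(np.zeros((3, 3)))

    def test_matches_sklearn_on_prediction_vectors(self):
        from sklearn.metrics import cohen_kappa_score, confusion_matrix

        rng = np.random.default_rng(7)
        y_true = rng.choice(["SB", "BH", "PB"], 100)
        y_pred = np.where(rng.random(100) < 0.7, y_true, rng.choice(["SB", "BH", "PB"], 100))
        c = confusion_matrix(y_true, y_pred)
        assert cohens_kappa(c) == pytest.approx(cohen_kappa_score(y_true, y_pred), abs=1e-12)


class TestCrossValidate:
    def test_fold_sizes_balanced_within_one(self):
        rng = np.random.default_rng(8)
        X, y = _blobs(rng, n_per_class=25, n_features=6)
        from sklearn.model_selection import StratifiedKFold

        sizes = [len(te) for _, te in StratifiedKFold(10, shuffle=True, random_state=0).split(X, y)]
        assert max(sizes) - min(sizes) <= 3  # <=1 per class

    def test_separated_classes_classified_accurately(self):
        rng = np.random.default_rng(9)
        X, y = _blobs(rng, n_per_class=40, n_features=32, sep=8.0)
        report = cross_validate(X, y, folds=5, repeats=1, seed=0, n_select=30, k_neighbors=5)
        assert report.accuracy > 88.0
        assert report.kappa > 0.8

    def test_accuracy_recomputable_from_stored_confusions(self):
        rng = np.random.default_rng(10)
        X, y = _blobs(rng, n_per_class=30, n_features=35)
        report = cross_validate(X, y, folds=5, repeats=1, seed=1, n_select=30, k_neighbors=5)
        accs = [np.trace(c) / c.sum() for c in report.confusions]
        assert report.accuracy == pytest.approx(100.0 * np.mean(accs))

    def test_group_mode_keeps_subject_rows_together(self):
        rng = np.random.default_rng(11)
        n_sub = 30
        X = rng.standard_normal((3 * n_sub, 35))
        y = np.tile(["SB", "BH", "PB"], n_sub)
        groups = np.repeat(np.arange(n_sub), 3)
        from sklearn.model_selection import StratifiedGroupKFold

        for tr, te in StratifiedGroupKFold(5, shuffle=True, random_state=0).split(X, y, groups):
            assert not set(groups[tr]) & set(groups[te])
        report = cross_validate(
            X, y, folds=5, repeats=1, seed=2, n_select=30, k_neighbors=5, groups=groups
        )
        assert 0 <= report.accuracy <= 100

    def test_excessive_folds_rejected(self):
        rng = np.random.default_rng(12)
        X, y = _blobs(rng, n_per_class=5, n_features=4)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(X, y, folds=10, repeats=1)

    def test_report_table_layout(self):
        from respconn.classification import CvReport

        reports = {"alpha": CvReport(accuracy=85.1, kappa=0.77)}
        df = report_table(reports, {"alpha": (8.0, 13.0)})
        assert list(df.columns) == ["band", "frequency", "accuracy", "kappa"]
        assert df.loc[0, "frequency"] == "8-13 Hz"


class TestBandOrdering:
    def test_alpha_band_most_discriminative_under_default_coupling(self):
        """The default cohort carries its largest condition differences in
        alpha; classification accuracy should peak there."""
        from respconn.synthetic_data import default_coupling, simulate_plv_cohort

        feats, _ = simulate_plv_cohort(47, default_coupling(), est_noise_sd=0.03, seed=11)
        accs = {}
        for band in ("delta", "theta", "alpha", "beta"):
            X = np.vstack([feats[(c, band)] for c in ("SB", "BH", "PB")])
            y = np.repeat(["SB", "BH", "PB"], 47)
            accs[band] = cross_validate(X, y, folds=10, repeats=1, seed=0).accuracy
        assert accs["alpha"] == max(accs.values())
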