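import numpy as np
import pandas as pd
import pytest

from bodymaps.granularity import (
    chi2_from_counts,
    classifier_significance,
    confidence_scores,
    differentiation_score,
    fit_lda,
    granularity_metrics,
    representativeness_score,
    sobel_mediation,
    sobel_z,
)
from bodymaps.simulate import EMOTIONS


def _two_class_1d(rng, mu0, mu1, n=200):
    X = np.concatenate(
        [mu0 + rng.standard_normal(n), mu1 + rng.standard_normal(n)]
    ).reshape(-1, 1)
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestLda:
    def test_separated_classes_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X, y = _two_class_1d(rng, -10.0, 10.0)
        model = fit_lda(X, y)
        assert (model.predict(X) == y).all()

    def test_identical_class_distributions_posteriors_equal_priors(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((300, 2))
        y = np.array(["a", "b", "c"] * 100)
        model = fit_lda(X, y)
        post = model.posterior(rng.standard_normal((50, 2)))
        assert np.allclose(post.mean(axis=0), [1 / 3] * 3, atol=0.06)

    def test_posterior_half_at_midpoint(self):
        """1-D classes at 0 and 2 with unit variance and equal priors give
        posterior 0.5 at x = 1 (linear-discriminant symmetry point)."""
        rng = np.random.default_rng(2)
        n = 20000
        X = np.concatenate([rng.standard_normal(n), 2 + rng.standard_normal(n)])
        y = np.array(["a"] * n + ["b"] * n)
        model = fit_lda(X.reshape(-1, 1), y)
        post = model.posterior([[1.0]])
        assert post[0, 0] == pytest.approx(0.5, abs=0.02)

    def test_empirical_priors(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 2))
        y = np.array(["a"] * 75 + ["b"] * 25)
        model = fit_lda(X, y)
        assert model.priors == pytest.approx([0.75, 0.25])


class TestClassifierSignificance:
    def test_chi2_goodness_of_fit_counts_example(self):
        """661 correct of 2280 at 10% chance: (661-228)^2/228 +
        (1619-2052)^2/2052 = 913.7."""
        assert chi2_from_counts(661, 2280, 0.10) == pytest.approx(913.7, abs=0.05)

    def test_null_features_accuracy_near_chance(self):
        rng = np.random.default_rng(4)
        n_subj = 40
        X = rng.standard_normal((n_subj * 10, 3))
        labels = np.tile(EMOTIONS, n_subj)
        subjects = np.repeat([f"S{i}" for i in range(n_subj)], 10)
        out = classifier_significance(X, labels, subjects, n_splits=100, seed=0)
        assert out["accuracy"] == pytest.approx(0.10, abs=0.05)
        assert out["p_cv"] > 0.1

    def test_separated_classes_significant(self):
        rng = np.random.default_rng(5)
        n_subj = 30
        means = rng.standard_normal((10, 3)) * 4
        labels = np.tile(EMOTIONS, n_subj)
        X = means[np.tile(np.arange(10), n_subj)] + 0.5 * rng.standard_normal(
            (n_subj * 10, 3)
        )
        subjects = np.repeat([f"S{i}" for i in range(n_subj)], 10)
        out = classifier_significance(X, labels, subjects, n_splits=200, seed=1)
        assert out["p_cv"] <= 0.01
        assert out["confusion"].to_numpy().sum() == n_subj * 10

    def test_subject_wise_splits_keep_subject_together(self):
        # indirectly: determinism and successful run with 2 maps per subject
        rng = np.random.default_rng(6)
        n_subj = 30
        X = rng.standard_normal((n_subj * 10, 2))
        labels = np.tile(EMOTIONS, n_subj)
        subjects = np.repeat([f"S{i}" for i in range(n_subj)], 10)
        a = classifier_significance(X, labels, subjects, n_splits=20, seed=9)
        b = classifier_significance(X, labels, subjects, n_splits=20, seed=9)
        assert np.array_equal(a["cv_accuracies"], b["cv_accuracies"])


class TestConfidence:
    def test_uninformative_features_confidence_equals_prior(self):
        # every class sees the exact same observations, so the class
        # conditionals are identical and posteriors must equal the priors
        rng = np.random.default_rng(7)
        block = rng.standard_normal((20, 2))
        X = np.tile(block, (10, 1))
        labels = np.repeat(EMOTIONS, 20)
        subjects = np.tile([f"S{i}" for i in range(20)], 10)
        model = fit_lda(X, labels)
        conf = confidence_scores(model, X, labels, subjects)
        assert np.allclose(conf, 0.1, atol=1e-6)

    def test_perfect_separation_confidence_near_one(self):
        rng = np.random.default_rng(8)
        n_subj = 20
        means = np.eye(10) * 100
        labels = np.tile(EMOTIONS, n_subj)
        X = means[np.tile(np.arange(10), n_subj)] + 0.01 * rng.standard_normal(
            (n_subj * 10, 10)
        )
        subjects = np.repeat([f"S{i}" for i in range(n_subj)], 10)
        model = fit_lda(X, labels)
        conf = confidence_scores(model, X, labels, subjects)
        assert (conf > 1 - 1e-6).all()

    def test_locality_of_subject_scores(self):
        rng = np.random.default_rng(9)
        n_subj = 10
        X = rng.standard_normal((n_subj * 10, 3))
        labels = np.tile(EMOTIONS, n_subj)
        subjects = np.repeat([f"S{i}" for i in range(n_subj)], 10)
        model = fit_lda(X, labels)
        full = confidence_scores(model, X, labels, subjects)
        drop = np.ones(len(labels), dtype=bool)
        drop[0] = False  # remove one map of subject S0
        part = confidence_scores(model, X[drop], labels[drop], subjects[drop])
        changed = (full.drop("S0") - part.drop("S0")).abs().max()
        assert changed < 1e-12
        assert full["S0"] != part["S0"]


class TestCosineMetrics:
    def test_identical_vectors_zero_differentiation(self):
        V = np.tile([1.0, 2.0, 3.0], (10, 1))
        assert differentiation_score(V) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_vectors_unit_differentiation(self):
        assert differentiation_score(np.eye(4)) == pytest.approx(1.0)

    def test_hand_cosine_pair(self):
        """(1,0) vs (1,1): 1 - 1/sqrt(2) ~ 0.29289."""
        V = np.array([[1.0, 0.0], [1.0, 1.0]])
        assert differentiation_score(V) == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-10)

    def test_representativeness_of_group_mean_is_one(self):
        G = np.random.default_rng(0).standard_normal((10, 4))
        assert representativeness_score(G, G) == pytest.approx(1.0)

    def test_representativeness_orthogonal_is_zero(self):
        V = np.tile([1.0, 0.0], (10, 1))
        G = np.tile([0.0, 1.0], (10, 1))
        assert representativeness_score(V, G) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        V = rng.standard_normal((10, 3))
        G = rng.standard_normal((10, 3))
        a = representativeness_score(V, G)
        b = representativeness_score(3.7 * V, G)
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_vectors_skipped(self):
        V = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        d = differentiation_score(V)
        assert d == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-10)

    def test_metrics_invariant_to_orthogonal_rotation(self):
        """Cosine metrics in component space do not depend on whether the
        retained space was rotated (rotation is orthogonal)."""
        rng = np.random.default_rng(2)
        V = rng.standard_normal((10, 4))
        G = rng.standard_normal((10, 4))
        Q = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        assert differentiation_score(V) == pytest.approx(
            differentiation_score(V @ Q), abs=1e-10
        )
        assert representativeness_score(V, G) == pytest.approx(
            representativeness_score(V @ Q, G @ Q), abs=1e-10
        )


class TestConfidenceVariants:
    def test_cv_confidence_covers_all_subjects_and_is_leakage_free(self):
        from bodymaps.granularity import confidence_scores_cv

        rng = np.random.default_rng(21)
        n_subj = 20
        means = np.eye(10) * 5
        labels = np.tile(EMOTIONS, n_subj)
        X = means[np.tile(np.arange(10), n_subj)] + rng.standard_normal(
            (n_subj * 10, 10)
        )
        subjects = np.repeat([f"S{i}" for i in range(n_subj)], 10)
        cv = confidence_scores_cv(X, labels, subjects, n_folds=4, seed=0)
        assert set(cv.index) == set(subjects)
        # cross-validated confidence cannot exceed the optimistic full-fit one
        model = fit_lda(X, labels)
        full = confidence_scores(model, X, labels, subjects)
        assert cv.mean() <= full.mean() + 0.02


class TestLeaveOneOutRepresentativeness:
    def test_loo_lower_for_self_contributing_subjects(self):
        rng = np.random.default_rng(22)
        n_subj = 8
        idx = pd.MultiIndex.from_product(
            [[f"S{i}" for i in range(n_subj)], EMOTIONS],
            names=["subject", "emotion"],
        )
        scores = pd.DataFrame(rng.standard_normal((n_subj * 10, 3)), index=idx)
        incl = granularity_metrics(scores).table["representativeness"]
        loo = granularity_metrics(scores, leave_one_out=True).table[
            "representativeness"
        ]
        # removing one's own maps from the reference lowers typicality on
        # average (the self-term inflates the included-version cosines)
        assert loo.mean() < incl.mean()


class TestSobel:
    def test_hand_example(self):
        """a=0.5 (se .1), b=0.4 (se .1) -> z = 3.123, p ~ 0.0018."""
        z = sobel_z(0.5, 0.1, 0.4, 0.1)
        assert z == pytest.approx(3.123, abs=0.001)

    def test_zero_a_gives_null(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        m = rng.standard_normal(100)  # unrelated to x: a ~ 0
        y = m + 0.1 * rng.standard_normal(100)
        out = sobel_mediation(x, m, y)
        assert abs(out["z"]) < 2.5

    def test_full_mediation_detected(self):
        """Monte Carlo: x -> m -> y with path coefficients 0.5 at n = 500."""
        hits = 0
        for s in range(40):
            rng = np.random.default_rng(s)
            x = rng.standard_normal(500)
            m = 0.5 * x + rng.standard_normal(500)
            y = 0.5 * m + rng.standard_normal(500)
            hits += sobel_mediation(x, m, y)["p"] < 0.05
        assert hits >= 36

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            sobel_mediation(np.ones(20), np.arange(20.0), np.arange(20.0))


class TestGranularityMetricsTable:
    def test_confidence_bounded_by_priors_and_one(self):
        rng = np.random.default_rng(10)
        n_subj = 15
        idx = pd.MultiIndex.from_product(
            [[f"S{i}" for i in range(n_subj)], EMOTIONS],
            names=["subject", "emotion"],
        )
        scores = pd.DataFrame(rng.standard_normal((n_subj * 10, 4)), index=idx)
        model = fit_lda(
            scores.to_numpy(), idx.get_level_values("emotion").to_numpy()
        )
        table = granularity_metrics(scores, model=model).table
        assert (table["confidence"].mean() >= 0.1 - 1e-9)
        assert (table["confidence"] <= 1).all()
        assert table["differentiation"].between(0, 2).all()
        assert table["representativeness"].between(-1, 1).all()
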