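import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bodymaps.decomposition import (
    apply_sign_convention,
    bootstrap_loading_z,
    fit_pca,
    match_components,
    quartimax_criterion,
    quartimax_rotate,
    rotate_model,
    signflip_retention,
    tucker_congruence,
)


def _planted_data(rng, n=200, p=50, k=3, signal_sd=10.0):
    """Rank-k structure with strong components plus unit noise."""
    scores = rng.standard_normal((n, k)) * signal_sd
    loadings = np.linalg.qr(rng.standard_normal((p, k)))[0]
    return scores @ loadings.T + rng.standard_normal((n, p))


class TestFitPca:
    def test_eigenvalue_sum_equals_total_variance(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 12))
        model = fit_pca(X)
        total = np.var(X - X.mean(0), axis=0, ddof=1).sum()
        assert model.eigenvalues.sum() == pytest.approx(total, abs=1e-8)

    def test_rank_one_data_single_nonzero_eigenvalue(self):
        rng = np.random.default_rng(1)
        X = np.outer(rng.standard_normal(40), rng.standard_normal(8))
        model = fit_pca(X)
        assert model.eigenvalues[0] > 1e-8
        assert np.all(model.eigenvalues[1:] < 1e-10 * model.eigenvalues[0])

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(2)
        model = fit_pca(rng.standard_normal((80, 10)))
        G = model.scores.T @ model.scores
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off < 1e-8

    def test_zero_variance_variable_with_scaling_rejected(self):
        X = np.random.default_rng(3).standard_normal((30, 4))
        X[:, 2] = 5.0
        with pytest.raises(ValueError, match="zero-variance"):
            fit_pca(X, scale=True)

    def test_observation_order_invariance(self):
        rng = np.random.default_rng(4)
        X = _planted_data(rng, n=100, p=20, k=2)
        m1 = rotate_model(fit_pca(X, n_components=2))
        perm = rng.permutation(100)
        m2 = rotate_model(fit_pca(X[perm], n_components=2))
        assert np.allclose(np.abs(m1.loadings), np.abs(m2.loadings), atol=1e-8)


class TestSignflipRetention:
    def test_pure_noise_retains_zero(self):
        """Monte Carlo: sign flips preserve the law of iid noise, so no
        component should beat the envelope in most seeds."""
        zero = 0
        for s in range(50):
            X = np.random.default_rng(s).standard_normal((100, 50))
            ret = signflip_retention(X, n_perm=200, seed=s)
            zero += ret.n_retained == 0
        assert zero >= 45

    def test_planted_rank_three_recovered(self):
        """Monte Carlo: strong rank-3 structure retains exactly 3."""
        exact = 0
        for s in range(20):
            X = _planted_data(np.random.default_rng(100 + s), n=200, p=50, k=3)
            ret = signflip_retention(X, n_perm=200, seed=s)
            exact += ret.n_retained == 3
        assert exact >= 18

    def test_envelope_at_least_median(self):
        X = np.random.default_rng(9).standard_normal((50, 10))
        ret = signflip_retention(X, n_perm=200, seed=0)
        assert (ret.envelope >= ret.permutation_median).all()

    def test_too_few_permutations_rejected(self):
        X = np.random.default_rng(0).standard_normal((30, 5))
        with pytest.raises(ValueError):
            signflip_retention(X, n_perm=10)
        with pytest.warns(UserWarning):
            signflip_retention(X, n_perm=50, seed=0)


class TestQuartimax:
    def test_45_degree_analytic_rotation(self):
        """[[c, c], [c, -c]] with c = 1/sqrt(2) is a 45-degree rotation of
        the identity; quartimax must undo it."""
        c = 1 / np.sqrt(2)
        A = np.array([[c, c], [c, -c]])
        L, R = quartimax_rotate(A)
        assert np.allclose(np.abs(L), np.eye(2), atol=1e-6)
        assert np.allclose(R.T @ R, np.eye(2), atol=1e-10)

    def test_simple_structure_fixed_point(self):
        A = np.zeros((6, 2))
        A[:3, 0] = [0.9, 0.8, 0.85]
        A[3:, 1] = [0.7, 0.95, 0.8]
        L, _ = quartimax_rotate(A)
        assert np.allclose(np.abs(L), np.abs(A), atol=1e-6)

    def test_criterion_never_decreases(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((20, 4))
        L, _ = quartimax_rotate(A)
        assert quartimax_criterion(L) >= quartimax_criterion(A) - 1e-8

    def test_single_component_passthrough(self):
        A = np.random.default_rng(0).standard_normal((10, 1))
        L, R = quartimax_rotate(A)
        assert np.array_equal(L, A)
        assert R.shape == (1, 1)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_rotation_always_orthogonal(self, seed):
        A = np.random.default_rng(seed).standard_normal((12, 3))
        _, R = quartimax_rotate(A)
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-8)

    def test_matches_independent_gradient_projection_solver(self):
        """Cross-check the pairwise solver against the gradient-projection
        implementation in statsmodels on a generic loading matrix."""
        from statsmodels.multivariate.factor_rotation import rotate_factors

        A = np.random.default_rng(19).standard_normal((30, 4)) * [2.0, 1.5, 1.0, 0.5]
        L_pair, _ = quartimax_rotate(A)
        L_gpa, _ = rotate_factors(A, "quartimax")
        assert quartimax_criterion(L_pair) >= quartimax_criterion(L_gpa) - 1e-6


class TestSignConvention:
    def test_max_loading_positive_and_scores_consistent(self):
        rng = np.random.default_rng(11)
        X = _planted_data(rng, n=80, p=15, k=2)
        model = fit_pca(X, n_components=2)
        Xc = X - X.mean(0)
        flipped = apply_sign_convention(model)
        for k in range(2):
            i = np.argmax(np.abs(flipped.loadings[:, k]))
            assert flipped.loadings[i, k] > 0
        assert np.allclose(flipped.scores, Xc @ flipped.loadings, atol=1e-8)


class TestBootstrapLoadingZ:
    def test_degenerate_resample_recovers_reference(self):
        """Bootstrap 'samples' equal to the data reproduce the reference."""
        rng = np.random.default_rng(13)
        X = _planted_data(rng, n=60, p=10, k=2)
        ref = rotate_model(fit_pca(X, n_components=2))
        boot = rotate_model(fit_pca(X, n_components=2))
        perm, signs = match_components(ref.loadings, boot.loadings)
        aligned = boot.loadings[:, perm] * signs
        assert np.allclose(aligned, ref.loadings, atol=1e-8)

    def test_strong_structure_yields_large_z(self):
        """Monte Carlo: true nonzero loadings give |z| > 2."""
        rng = np.random.default_rng(17)
        n, k = 228, 2
        loadings = np.zeros((8, k))
        loadings[:4, 0] = 0.95
        loadings[4:, 1] = 0.95
        hits = 0
        runs = 5
        for r in range(runs):
            F = rng.standard_normal((n, k))
            X = F @ loadings.T + 0.3 * rng.standard_normal((n, 8))
            res = bootstrap_loading_z(X, K=k, n_boot=100, seed=r)
            ref = rotate_model(fit_pca(X, n_components=k))
            big = np.abs(res.z[np.abs(ref.loadings) > 0.2])
            hits += (big > 2).all()
        assert hits >= int(0.95 * runs)

    def test_zero_sd_cells_flagged_not_dropped(self):
        # constant-score degenerate data force sd == 0 cells
        X = np.tile(np.arange(10.0)[:, None], (1, 3))
        res = bootstrap_loading_z(X, K=1, n_boot=30, seed=0)
        assert res.undefined.dtype == bool
        assert np.isnan(res.z[res.undefined]).all() or not res.undefined.any()


class TestCongruenceMatching:
    def test_match_recovers_permutation_and_signs(self):
        rng = np.random.default_rng(23)
        ref = np.linalg.qr(rng.standard_normal((12, 3)))[0]
        perm_true = [2, 0, 1]
        signs_true = np.array([-1.0, 1.0, -1.0])
        cand = ref[:, perm_true] * signs_true
        perm, signs = match_components(ref, cand)
        aligned = cand[:, perm] * signs
        assert np.allclose(aligned, ref, atol=1e-12)

    def test_congruence_of_identical_columns_is_one(self):
        A = np.random.default_rng(2).standard_normal((9, 2))
        C = tucker_congruence(A, A)
        assert np.allclose(np.diag(C), 1.0)
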