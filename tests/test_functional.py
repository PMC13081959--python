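"""Basis systems, curve fitting, QC, and the f-rhoPCA eigenproblem."""

import numpy as np
import pytest
from scipy.integrate import quad

from rqpca.exceptions import AlignmentError, InvalidInputError, NotPSDError
from rqpca.functional import (
    f_rho_pca,
    f_rho_pca_discrete,
    fit_samples,
    gram_matrix,
    make_basis,
    qc_filter,
    score_samples,
    score_variance_ratio,
    sqrt_psd,
)
from rqpca.synth import FunctionalScenario, make_functional_dataset


class TestBasisAndGram:
    def test_monomial_basis_and_gram(self):
        basis = make_basis("monomial", 2, (0.0, 1.0))
        t = np.array([0.0, 0.5, 1.0])
        np.testing.assert_allclose(basis.evaluate(t),
                                   [[1, 0], [1, 0.5], [1, 1]])
        np.testing.assert_allclose(basis.gram, [[1, 0.5], [0.5, 1 / 3]])

    def test_fourier_basis_is_orthonormal(self):
        basis = make_basis("fourier", 3, (0.0, 2 * np.pi))
        np.testing.assert_allclose(basis.gram, np.eye(3), atol=1e-12)
        t = np.array([np.pi / 2])
        vals = basis.evaluate(t)[0]
        np.testing.assert_allclose(
            vals,
            [1 / np.sqrt(2 * np.pi), 1 / np.sqrt(np.pi), 0.0],
            atol=1e-12,
        )

    def test_bspline_gram_matches_quadrature_oracle(self):
        basis = make_basis("bspline", 5, (0.0, 14.0), order=4)
        G_oracle = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                G_oracle[i, j] = quad(
                    lambda t: basis.evaluate(np.array([t]))[0, i]
                    * basis.evaluate(np.array([t]))[0, j],
                    0.0, 14.0, limit=200,
                )[0]
        np.testing.assert_allclose(basis.gram, G_oracle, atol=1e-8)
        np.testing.assert_array_equal(basis.gram, basis.gram.T)

    def test_bspline_partition_of_unity(self):
        basis = make_basis("bspline", 6, (0.0, 1.0), order=4)
        t = np.linspace(0, 1, 37)
        np.testing.assert_allclose(basis.evaluate(t).sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_bspline_requires_enough_functions(self):
        with pytest.raises(InvalidInputError):
            make_basis("bspline", 3, (0.0, 1.0), order=4)

    def test_gram_positive_definite(self):
        for kind, D in [("bspline", 7), ("monomial", 4), ("fourier", 5)]:
            basis = make_basis(kind, D, (0.0, 2.0))
            assert np.linalg.eigvalsh(basis.gram)[0] > 0


class TestSqrtPsd:
    def test_diagonal(self):
        np.testing.assert_allclose(sqrt_psd(np.diag([4.0, 9.0])),
                                   np.diag([2.0, 3.0]))
        np.testing.assert_allclose(sqrt_psd(np.eye(3)), np.eye(3))

    def test_reconstruction(self, rng):
        A = rng.standard_normal((5, 5))
        S = A @ A.T + 0.1 * np.eye(5)
        R = sqrt_psd(S)
        np.testing.assert_allclose(R @ R, S, atol=1e-10)

    def test_substantially_negative_rejected(self):
        with pytest.raises(NotPSDError):
            sqrt_psd(np.diag([1.0, -0.5]))


class TestFitSamples:
    def test_exact_basis_function_recovered(self):
        basis = make_basis("bspline", 5, (0.0, 10.0))
        t = np.linspace(0, 10, 10)
        y = basis.evaluate(t)[:, 1]
        out = fit_samples([t], [y], basis)
        np.testing.assert_allclose(out.coefficients[0],
                                   [0, 1, 0, 0, 0], atol=1e-10)
        assert out.r_squared[0] == pytest.approx(1.0)

    def test_constant_recovered_via_partition_of_unity(self):
        basis = make_basis("bspline", 5, (0.0, 1.0))
        t = np.linspace(0, 1, 9)
        out = fit_samples([t], [np.full(9, 3.5)], basis)
        np.testing.assert_allclose(out.coefficients[0], 3.5, atol=1e-9)
        # TSS = 0 for a constant trajectory: R^2 defined as 0
        assert out.r_squared[0] == 0.0

    def test_pure_noise_has_low_r_squared(self, rng):
        basis = make_basis("bspline", 5, (0.0, 1.0))
        t = np.linspace(0, 1, 200)
        out = fit_samples([t], [rng.standard_normal(200)], basis)
        assert out.r_squared[0] < 0.2

    def test_too_few_points_flagged_not_fatal(self):
        basis = make_basis("bspline", 5, (0.0, 1.0))
        out = fit_samples(
            [np.array([0.1, 0.5, 0.9]), np.linspace(0, 1, 8)],
            [np.ones(3), np.linspace(0, 1, 8) ** 2],
            basis,
            sample_ids=["short", "ok"],
        )
        assert out.n == 1
        assert out.sample_ids == ["ok"]
        assert out.unfittable[0][0] == "short"

    def test_irregular_grids_allowed(self, rng):
        basis = make_basis("monomial", 2, (0.0, 1.0))
        t1, t2 = np.sort(rng.uniform(0, 1, 5)), np.sort(rng.uniform(0, 1, 9))
        out = fit_samples([t1, t2], [2 * t1 + 1, 2 * t2 + 1], basis)
        np.testing.assert_allclose(out.coefficients,
                                   [[1.0, 2.0], [1.0, 2.0]], atol=1e-9)


class TestQCFilter:
    def _sets(self, r2_target, r2_background):
        basis = make_basis("monomial", 2, (0.0, 1.0))
        t = np.linspace(0, 1, 6)
        mk = lambda n, grp: fit_samples([t] * n, [1 + t] * n, basis,
                                        group=grp)
        ft = mk(len(r2_target), "target")
        ft.r_squared = np.asarray(r2_target, float)
        fb = mk(len(r2_background), "background")
        fb.basis = ft.basis = basis
        fb.r_squared = np.asarray(r2_background, float)
        # share the exact basis object, as the pipeline does
        fb.basis = ft.basis
        return ft, fb

    def test_all_good_passes(self):
        ft, fb = self._sets([1.0] * 10, [1.0] * 10)
        _, _, report = qc_filter(ft, fb, r2_min=0.5, min_per_group=7)
        assert report.passed and not report.dropped

    def test_threshold_is_inclusive(self):
        ft, fb = self._sets([0.5, 0.49, 1.0, 1.0], [1.0] * 4)
        out_t, _, report = qc_filter(ft, fb, r2_min=0.5, min_per_group=2)
        assert out_t.n == 3  # 0.50 kept, 0.49 dropped
        assert any("0.49" in r for _, _, r in report.dropped)

    def test_group_size_rule(self):
        ft, fb = self._sets([1.0] * 6 + [0.2] * 4, [1.0] * 10)
        _, _, report = qc_filter(ft, fb, r2_min=0.5, min_per_group=7)
        assert not report.passed
        assert report.n_target_kept == 6


def _fit_dataset(ds):
    ft = fit_samples(ds.target_times, ds.target_values, ds.basis,
                     group="target")
    fb = fit_samples(ds.background_times, ds.background_values, ds.basis,
                     group="background")
    return ft, fb


class TestFRhoPCA:
    def test_orthonormal_basis_reduces_to_coefficient_rho_pca(self, rng):
        """With G = I the functional problem is exactly contrastive PCA on
        the (centered) coefficient covariances."""
        from rqpca.core import center_columns, generalized_eigensolve, sample_covariance
        from rqpca.functional import FunctionalSampleSet

        basis = make_basis("fourier", 4, (0.0, 1.0))
        A_X = rng.standard_normal((30, 4)) * [3.0, 1.0, 0.5, 0.2]
        A_Y = rng.standard_normal((40, 4))
        ft = FunctionalSampleSet(A_X, basis, np.ones(30), "target",
                                 [f"t{i}" for i in range(30)])
        fb = FunctionalSampleSet(A_Y, basis, np.ones(40), "background",
                                 [f"b{i}" for i in range(40)])
        efs = f_rho_pca(ft, fb, k=4, eps=0.0)
        dec = generalized_eigensolve(
            sample_covariance(center_columns(A_X)),
            sample_covariance(center_columns(A_Y)),
            k=4, eps=0.0,
        )
        np.testing.assert_allclose(efs.eigenvalues, dec.eigenvalues,
                                   rtol=1e-10)
        np.testing.assert_allclose(np.abs(efs.coefficient_vectors),
                                   np.abs(dec.eigenvectors), atol=1e-8)

    def test_target_equals_background_gives_unit_eigenvalues(self):
        ds = make_functional_dataset(FunctionalScenario(seed=2))
        ft, _ = _fit_dataset(ds)
        fb = fit_samples(ds.target_times, ds.target_values, ds.basis,
                         group="background")
        fb.basis = ft.basis = ds.basis
        efs = f_rho_pca(ft, fb, k=5, eps=0.0)
        np.testing.assert_allclose(efs.eigenvalues, 1.0, atol=1e-8)

    def test_reconstruction_relation(self):
        """Eigenfunction basis coefficients satisfy f = G^{-1/2} w."""
        ds = make_functional_dataset(FunctionalScenario(seed=4))
        ft, fb = _fit_dataset(ds)
        efs = f_rho_pca(ft, fb, k=3)
        G_half = sqrt_psd(ds.basis.gram)
        np.testing.assert_allclose(G_half @ efs.coefficient_vectors,
                                   efs.w_vectors, atol=1e-8)

    def test_whitened_background_orthonormality(self):
        ds = make_functional_dataset(FunctionalScenario(seed=6))
        ft, fb = _fit_dataset(ds)
        efs = f_rho_pca(ft, fb, k=5, eps=0.0)
        G_half = sqrt_psd(ds.basis.gram)
        A = fb.coefficients - fb.coefficients.mean(axis=0)
        C_Y = G_half @ A.T @ A @ G_half / (fb.n - 1)
        W = efs.w_vectors
        np.testing.assert_allclose(W.T @ C_Y @ W, np.eye(5), atol=1e-8)

    def test_recovers_planted_mode(self):
        ds = make_functional_dataset(FunctionalScenario(seed=11))
        ft, fb = _fit_dataset(ds)
        efs = f_rho_pca(ft, fb, k=1)
        grid = np.linspace(0, 14, 200)
        truth = ds.basis.evaluate(grid) @ ds.truth["v_star_coefficients"]
        corr = np.corrcoef(efs.evaluate(grid)[:, 0], truth)[0, 1]
        assert abs(corr) > 0.95
        assert efs.eigenvalues[0] > 3.0

    def test_eigenvalues_invariant_to_basis_spanning_same_space(self, rng):
        """Monomials of degree < 4 and cubic B-splines without interior
        knots span the same space, so the eigenvalues must agree."""
        b_mono = make_basis("monomial", 4, (0.0, 1.0))
        b_bern = make_basis("bspline", 4, (0.0, 1.0), order=4)
        t = np.linspace(0, 1, 25)
        curves_t = [np.polyval(rng.standard_normal(4), t) for _ in range(20)]
        curves_b = [np.polyval(rng.standard_normal(4) * 0.3, t)
                    for _ in range(25)]
        evs = []
        for basis in (b_mono, b_bern):
            ft = fit_samples([t] * 20, curves_t, basis, group="target")
            fb = fit_samples([t] * 25, curves_b, basis, group="background")
            evs.append(f_rho_pca(ft, fb, k=4, eps=0.0).eigenvalues)
        np.testing.assert_allclose(evs[0], evs[1], rtol=1e-6)

    def test_reduces_to_functional_pca_for_isotropic_background(self):
        """A background of pure L2-white smooth noise (large m) makes the
        top contrastive eigenfunction match the target's ordinary fPCA
        eigenfunction."""
        sc = FunctionalScenario(seed=9, n_background=2000, shared_sd=0.0,
                                background_sd=0.0)
        ds = make_functional_dataset(sc)
        ft, fb = _fit_dataset(ds)
        efs = f_rho_pca(ft, fb, k=1)
        # ordinary fPCA of the target: eigenproblem of G^{1/2} Sigma G^{1/2}
        G_half = sqrt_psd(ds.basis.gram)
        A = ft.coefficients - ft.coefficients.mean(axis=0)
        C = G_half @ A.T @ A @ G_half / (ft.n - 1)
        w = np.linalg.eigh((C + C.T) / 2)[1][:, -1]
        f_pca = np.linalg.inv(G_half) @ w
        grid = np.linspace(0, 14, 300)
        corr = np.corrcoef(efs.evaluate(grid)[:, 0],
                           ds.basis.evaluate(grid) @ f_pca)[0, 1]
        assert abs(corr) > 0.9

    def test_basis_mismatch_rejected(self):
        ds = make_functional_dataset(FunctionalScenario(seed=1))
        ft, fb = _fit_dataset(ds)
        fb.basis = make_basis("bspline", 5, (0.0, 14.0))
        with pytest.raises(AlignmentError):
            f_rho_pca(ft, fb)


class TestDiscreteRoute:
    def test_target_equals_background_unit_eigenvalues(self, rng):
        grid = np.linspace(0, 1, 12)
        X = rng.standard_normal((20, 12))
        out = f_rho_pca_discrete(X, X.copy(), grid, k=5, eps=0.0)
        np.testing.assert_allclose(out.eigenvalues[:5], 1.0, atol=1e-8)

    def test_linear_interpolation_between_grid_points(self, rng):
        grid = np.array([0.0, 1.0, 2.0])
        X = rng.standard_normal((10, 3))
        Y = rng.standard_normal((10, 3))
        out = f_rho_pca_discrete(X, Y, grid, k=1)
        v = out.values[:, 0]
        mid = out.evaluate(np.array([0.5]))[0, 0]
        assert mid == pytest.approx((v[0] + v[1]) / 2)

    def test_grid_length_mismatch_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            f_rho_pca_discrete(rng.standard_normal((5, 4)),
                               rng.standard_normal((5, 4)),
                               np.linspace(0, 1, 5))

    def test_agrees_with_basis_route_on_dense_curves(self):
        """Eigenfunctions from the discrete objective on densely sampled
        fitted curves match the basis-route eigenfunctions."""
        ds = make_functional_dataset(FunctionalScenario(seed=11))
        ft, fb = _fit_dataset(ds)
        efs = f_rho_pca(ft, fb, k=1)
        dense = np.linspace(0, 14, 120)
        Bt = ds.basis.evaluate(dense)
        out = f_rho_pca_discrete(ft.coefficients @ Bt.T,
                                 fb.coefficients @ Bt.T, dense, k=1)
        vg = out.values[:, 0] / np.linalg.norm(out.values[:, 0])
        vb = efs.evaluate(dense)[:, 0]
        vb = vb / np.linalg.norm(vb)
        if vg @ vb < 0:
            vg = -vg
        assert np.max(np.abs(vg - vb)) < 0.05


class TestScores:
    def test_self_projection_of_unit_norm_eigenfunction(self):
        ds = make_functional_dataset(FunctionalScenario(seed=5))
        ft, fb = _fit_dataset(ds)
        efs = f_rho_pca(ft, fb, k=2)
        from rqpca.functional import FunctionalSampleSet

        G = ds.basis.gram
        f1 = efs.coefficient_vectors[:, 0]
        f1 = f1 / np.sqrt(f1 @ G @ f1)  # unit L2 norm
        efs.coefficient_vectors = np.column_stack(
            [f1, efs.coefficient_vectors[:, 1]]
        )
        samples = FunctionalSampleSet(
            np.vstack([f1, np.zeros(5)]), ds.basis, np.ones(2), "target",
            ["a", "b"],
        )
        sc = score_samples(samples, efs, center=False)
        assert sc.scores[0, 0] == pytest.approx(1.0)
        assert sc.scores[1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_coefficient_formula_matches_quadrature(self):
        """theta = a' G f equals the trapezoid approximation of
        int X(t) v(t) dt on a 10^4-point grid."""
        ds = make_functional_dataset(FunctionalScenario(seed=8))
        ft, fb = _fit_dataset(ds)
        efs = f_rho_pca(ft, fb, k=2)
        sc = score_samples(ft, efs, center=False)
        grid = np.linspace(0, 14, 10_000)
        Bt = ds.basis.evaluate(grid)
        V = efs.evaluate(grid)
        for i in (0, 3, 17):
            x = Bt @ ft.coefficients[i]
            for kcomp in range(2):
                oracle = np.trapezoid(x * V[:, kcomp], grid)
                assert sc.scores[i, kcomp] == pytest.approx(oracle, abs=1e-4)

    def test_variance_ratio_examples(self):
        from rqpca.functional import ScoreSet

        a = ScoreSet(np.array([[-2.0], [0.0], [2.0]]), "target", list("abc"))
        b = ScoreSet(np.array([[-1.0], [0.0], [1.0]]), "background",
                     list("def"))
        assert score_variance_ratio(a, b, 0) == pytest.approx(4.0)
        assert score_variance_ratio(a, a, 0) == pytest.approx(1.0)

    def test_variance_ratio_equals_top_eigenvalue(self):
        """Scores computed on the fitting data itself reproduce the
        eigenvalue-as-variance-ratio identity at eps = 0."""
        ds = make_functional_dataset(FunctionalScenario(seed=13))
        ft, fb = _fit_dataset(ds)
        efs = f_rho_pca(ft, fb, k=2, eps=0.0)
        r = score_variance_ratio(score_samples(ft, efs),
                                 score_samples(fb, efs), 0)
        assert r == pytest.approx(efs.eigenvalues[0], rel=1e-6)
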