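"""Two-level functional PCA: moments, eigenanalysis, selection, BLUP scores."""

import numpy as np
import pytest

import sitfpca as sf
from sitfpca.mfpca import (
    MfpcaModel,
    estimate_covariances,
    estimate_mean_and_shift,
    eigendecompose_level,
    select_components,
)


class TestMeanAndShift:
    def test_constant_rows(self):
        X = np.full((6, 10), 7.0)
        mask = np.ones_like(X, dtype=bool)
        day_order = np.tile([1, 2], 3)
        mu, eta = estimate_mean_and_shift(X, mask, day_order)
        np.testing.assert_allclose(mu, 7.0)
        np.testing.assert_allclose(eta, 0.0, atol=1e-12)

    def test_day_symmetry(self):
        X = np.vstack([np.full((3, 5), 4.0), np.full((3, 5), 2.0)])
        mask = np.ones_like(X, dtype=bool)
        day_order = np.array([1] * 3 + [2] * 3)
        mu, eta = estimate_mean_and_shift(X, mask, day_order)
        np.testing.assert_allclose(mu, 3.0)
        np.testing.assert_allclose(eta[0], 1.0)
        np.testing.assert_allclose(eta[1], -1.0)

    def test_unobserved_grid_point_rejected(self):
        X = np.ones((3, 4))
        mask = np.ones_like(X, dtype=bool)
        mask[:, 2] = False
        with pytest.raises(ValueError, match="zero rows"):
            estimate_mean_and_shift(X, mask, np.array([1, 1, 1]))

    def test_mean_converges_to_truth(self):
        truth = sf.simple_curve_truth(B=8, noise_sd=1.0)
        data = sf.simulate_curves(truth, 500, 2, seed=21)
        mu, _ = estimate_mean_and_shift(
            data.curves, data.mask, np.tile([1, 2], 500)
        )
        # per-point s.e. ~ sqrt(total var / rows); allow 5 s.e.
        total_sd = np.sqrt(
            truth.level1_eigenvalues.sum() + truth.level2_eigenvalues.sum() + 1.0
        )
        assert np.max(np.abs(mu - truth.mean_fn)) < 5 * total_sd / np.sqrt(1000)


class TestCovariances:
    def _residuals(self, lambda1, lambda2, noise_sd, n=300, d=3, seed=0, B=8):
        truth = sf.simple_curve_truth(
            B=B, lambda1=lambda1, lambda2=lambda2, noise_sd=noise_sd
        )
        data = sf.simulate_curves(truth, n, d, seed=seed)
        resid = data.curves - truth.mean_fn
        return truth, data, resid

    def test_single_level1_component(self):
        truth, data, resid = self._residuals((2.0, 1e-8), (1e-8,), 0.0)
        cov = estimate_covariances(resid, data.mask, data.subjects, smooth="off")
        phi = truth.level1_eigenfunctions[0]
        target = 2.0 * np.outer(phi, phi)
        assert np.abs(cov.k_between - target).max() < 0.1 * 2.0
        assert np.abs(cov.k_within).max() < 0.1 * 2.0
        assert cov.sigma2 < 0.05

    def test_pure_noise(self):
        truth, data, resid = self._residuals((1e-8, 1e-9), (1e-8,), 1.0, seed=3)
        cov = estimate_covariances(resid, data.mask, data.subjects, smooth="off")
        off = cov.k_total - np.diag(np.diag(cov.k_total))
        assert np.abs(off).max() < 0.15
        assert cov.sigma2 == pytest.approx(1.0, abs=0.1)

    def test_deterministic_rows(self):
        resid = np.zeros((6, 10))
        mask = np.ones_like(resid, dtype=bool)
        subjects = np.repeat([1, 2, 3], 2)
        cov = estimate_covariances(resid, mask, subjects, smooth="off")
        np.testing.assert_allclose(cov.k_between, 0.0, atol=1e-12)
        np.testing.assert_allclose(cov.k_within, 0.0, atol=1e-12)
        assert cov.sigma2 == 0.0

    def test_additivity_by_construction(self):
        truth, data, resid = self._residuals((2.0, 0.5), (1.0,), 0.3, seed=5)
        cov = estimate_covariances(resid, data.mask, data.subjects, smooth="off")
        np.testing.assert_allclose(
            cov.k_between + cov.k_within, cov.k_total, atol=1e-10
        )

    def test_single_day_subjects_rejected(self):
        resid = np.random.default_rng(0).normal(size=(4, 6))
        mask = np.ones_like(resid, dtype=bool)
        with pytest.raises(ValueError, match="unidentifiable"):
            estimate_covariances(resid, mask, np.arange(4), smooth="off")


class TestEigendecompose:
    def test_rank_one_with_sign_convention(self):
        phi = sf.make_fourier_eigenbasis(1, 30)[0]
        phi_neg = -phi if phi[np.argmax(np.abs(phi))] > 0 else phi
        funcs, vals = eigendecompose_level(2.0 * np.outer(phi_neg, phi_neg))
        assert vals.shape == (1,)
        assert vals[0] == pytest.approx(2.0, rel=1e-10)
        assert funcs[0][np.argmax(np.abs(funcs[0]))] > 0
        assert abs(funcs[0] @ phi) == pytest.approx(1.0, abs=1e-10)

    def test_known_rank3_spectrum(self):
        basis = sf.make_fourier_eigenbasis(3, 40)
        lams = np.array([5.0, 2.0, 0.5])
        K = (basis.T * lams) @ basis
        funcs, vals = eigendecompose_level(K)
        np.testing.assert_allclose(vals[:3], lams, rtol=1e-8)
        for k in range(3):
            assert abs(funcs[k] @ basis[k]) == pytest.approx(1.0, abs=1e-8)

    def test_flat_spectrum(self):
        funcs, vals = eigendecompose_level(np.eye(4) * 3.0)
        np.testing.assert_allclose(vals, 3.0)
        np.testing.assert_allclose(funcs @ funcs.T, np.eye(4), atol=1e-10)

    def test_negative_eigenvalues_excluded(self):
        phi = sf.make_fourier_eigenbasis(2, 20)
        K = 2.0 * np.outer(phi[0], phi[0]) - 1.0 * np.outer(phi[1], phi[1])
        funcs, vals = eigendecompose_level(K)
        assert (vals > 0).all()
        assert vals.shape == (1,)

    def test_asymmetric_rejected(self):
        K = np.eye(5)
        K[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose_level(K)


class TestSelectComponents:
    def test_greedy_stops_at_threshold(self):
        # 5/10 then 9/10 >= 0.9 after the second component -> one per level
        assert select_components(np.array([5.0]), np.array([4.0, 1.0])) == (1, 1)

    def test_level_floor(self):
        # level-1 alone reaches 90%; the zero-spectrum level still keeps one
        assert select_components(np.array([9.0, 1.0]), np.array([0.0])) == (1, 1)

    def test_hand_traced_pooled_rule(self):
        # shares 40,30,20,10: greedy takes 40+30+20 = 90% and stops
        n1, n2 = select_components(np.array([4.0, 1.0]), np.array([3.0, 2.0]))
        assert (n1, n2) == (1, 2)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            select_components(np.zeros(2), np.zeros(3))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            select_components(np.array([-1.0]), np.array([1.0]))

    def test_reference_truth_spectra_select_two_and_six(self):
        truth = sf.reference_curve_truth()
        n1, n2 = select_components(truth.level1_eigenvalues, truth.level2_eigenvalues)
        assert (n1, n2) == (2, 6)


class TestScores:
    def test_projection_identity_full_observation(self, recovery_fit):
        """With sigma2 -> 0 BLUP equals least-squares projection of residuals."""
        truth, data, model = recovery_fit
        proj_model = MfpcaModel(
            T=model.T, mu=model.mu, eta=model.eta,
            phi1=model.phi1, lambda1=model.lambda1,
            phi2=model.phi2, lambda2=model.lambda2,
            sigma2=0.0, lambda1_full=model.lambda1_full, lambda2_full=model.lambda2_full,
        )
        s1, s2 = sf.estimate_scores(
            proj_model, data.curves, data.mask, data.subjects, data.days
        )
        # residual of one subject, projected directly
        rows = np.flatnonzero(data.subjects == 1)
        resid = data.curves[rows] - model.mu - model.eta[data.days[rows] - 1]
        # joint least squares via the explicitly stacked design
        d = rows.size
        N1, N2 = model.N1, model.N2
        big = np.zeros((d * model.T, N1 + d * N2))
        for jj in range(d):
            big[jj * model.T : (jj + 1) * model.T, :N1] = model.phi1.T
            big[jj * model.T : (jj + 1) * model.T, N1 + jj * N2 : N1 + (jj + 1) * N2] = model.phi2.T
        theta, *_ = np.linalg.lstsq(big, resid.ravel(), rcond=None)
        np.testing.assert_allclose(s1[0], theta[:N1], atol=1e-5)

    def test_blup_shrinks_towards_zero(self, recovery_fit):
        """With sigma2 > 0 the BLUP magnitude is below the raw projection's."""
        truth, data, model = recovery_fit
        noisy = MfpcaModel(
            T=model.T, mu=model.mu, eta=model.eta,
            phi1=model.phi1, lambda1=model.lambda1,
            phi2=model.phi2, lambda2=model.lambda2,
            sigma2=50.0, lambda1_full=model.lambda1_full, lambda2_full=model.lambda2_full,
        )
        sharp = MfpcaModel(
            T=model.T, mu=model.mu, eta=model.eta,
            phi1=model.phi1, lambda1=model.lambda1,
            phi2=model.phi2, lambda2=model.lambda2,
            sigma2=0.0, lambda1_full=model.lambda1_full, lambda2_full=model.lambda2_full,
        )
        s1_noisy, _ = sf.estimate_scores(noisy, data.curves, data.mask, data.subjects, data.days)
        s1_sharp, _ = sf.estimate_scores(sharp, data.curves, data.mask, data.subjects, data.days)
        assert np.abs(s1_noisy).mean() < np.abs(s1_sharp).mean()

    def test_empty_row_rejected(self, recovery_fit):
        truth, data, model = recovery_fit
        mask = data.mask.copy()
        mask[0] = False
        with pytest.raises(ValueError, match="zero observed"):
            sf.estimate_scores(model, data.curves, mask, data.subjects, data.days)


class TestFitAndReconstruct:
    def test_eigenfunction_recovery(self, recovery_fit):
        truth, data, model = recovery_fit
        assert model.sigma2 == pytest.approx(0.25, abs=0.05)
        for k in range(2):
            assert abs(truth.level1_eigenfunctions[k] @ model.phi1[k]) > 0.95
        for l in range(3):
            assert abs(truth.level2_eigenfunctions[l] @ model.phi2[l]) > 0.95

    def test_orthonormality_within_levels(self, recovery_fit):
        _, _, model = recovery_fit
        np.testing.assert_allclose(model.phi1 @ model.phi1.T, np.eye(model.N1), atol=1e-6)
        np.testing.assert_allclose(model.phi2 @ model.phi2.T, np.eye(model.N2), atol=1e-6)

    def test_stage1_constant_across_rows(self, recovery_fit):
        _, data, model = recovery_fit
        a = sf.reconstruct(model, 1, 1, stage=1)
        b = sf.reconstruct(model, 2, 3, stage=1)
        np.testing.assert_array_equal(a, b)

    def test_stage4_increment_in_level2_span(self, recovery_fit):
        _, data, model = recovery_fit
        inc = sf.reconstruct(model, 5, 2, stage=4) - sf.reconstruct(model, 5, 2, stage=3)
        proj = model.phi2.T @ (model.phi2 @ inc)
        np.testing.assert_allclose(inc, proj, atol=1e-8)

    def test_rss_monotone_over_stages(self, recovery_fit):
        _, data, model = recovery_fit
        rss = []
        for stage in (2, 3, 4):
            total = 0.0
            for r in range(40):
                fit = sf.reconstruct(model, data.subjects[r], data.days[r], stage=stage)
                total += float(((data.curves[r] - fit) ** 2).sum())
            rss.append(total)
        assert rss[2] <= rss[1] <= rss[0]

    def test_truth_basis_exact_reconstruction(self):
        """sigma=0, truth eigenfunctions as the model -> stage 4 is the data."""
        truth = sf.simple_curve_truth(B=8, noise_sd=0.0)
        data = sf.simulate_curves(truth, 10, 2, seed=17)
        model = MfpcaModel(
            T=truth.T, mu=truth.mean_fn, eta=truth.day_shifts,
            phi1=truth.level1_eigenfunctions, lambda1=truth.level1_eigenvalues,
            phi2=truth.level2_eigenfunctions, lambda2=truth.level2_eigenvalues,
            sigma2=0.0, lambda1_full=truth.level1_eigenvalues,
            lambda2_full=truth.level2_eigenvalues,
            subjects=np.unique(data.subjects), row_subjects=data.subjects,
            row_days=data.days, row_day_order=data.days,
        )
        model.scores1, model.scores2 = sf.estimate_scores(
            model, data.curves, data.mask, data.subjects, data.days
        )
        fit = sf.reconstruct(model, 3, 2, stage=4)
        r = np.flatnonzero((data.subjects == 3) & (data.days == 2))[0]
        np.testing.assert_allclose(fit, data.curves[r], atol=1e-6)

    def test_unknown_row_rejected(self, recovery_fit):
        _, _, model = recovery_fit
        with pytest.raises(KeyError):
            sf.reconstruct(model, 999, 1)


class TestVarianceSummary:
    def test_share_arithmetic(self):
        model = MfpcaModel(
            T=4, mu=np.zeros(4), eta=np.zeros((1, 4)),
            phi1=np.eye(4)[:2], lambda1=np.array([3.0, 1.0]),
            phi2=np.eye(4)[2:3], lambda2=np.array([4.0]),
            sigma2=0.0, lambda1_full=np.array([3.0, 1.0]), lambda2_full=np.array([4.0]),
        )
        assert model.rho == pytest.approx(0.5)
        table = sf.variance_summary(model)
        l1 = table[table["level"] == 1]
        np.testing.assert_allclose(l1["within_level_share"], [0.75, 0.25])

    def test_rho_one_when_level2_empty(self):
        model = MfpcaModel(
            T=4, mu=np.zeros(4), eta=np.zeros((1, 4)),
            phi1=np.eye(4)[:1], lambda1=np.array([3.0]),
            phi2=np.eye(4)[2:3], lambda2=np.array([0.0]),
            sigma2=0.0, lambda1_full=np.array([3.0]), lambda2_full=np.array([0.0]),
        )
        assert model.rho == 1.0

    def test_rho_recovery_on_reference_truth(self):
        truth = sf.reference_curve_truth()
        data = sf.simulate_curves(truth, 300, 4, seed=23)
        model = sf.fit_mfpca(data.curves, data.mask, data.subjects, data.days, smooth="on")
        true_rho = truth.level1_eigenvalues.sum() / (
            truth.level1_eigenvalues.sum() + truth.level2_eigenvalues.sum()
        )
        assert model.rho == pytest.approx(true_rho, abs=0.05)
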