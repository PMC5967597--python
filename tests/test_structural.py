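"""Ellipsoidal model components: radii, smoothing, gradients, heterogeneity,
and model fitting on samples with known structure."""

import numpy as np
import pytest

from metagrad.structural import (EllipsoidModel, EllipsoidalUptakeModel,
                                 GradientSample, UptakeProfile, fit_structural_model,
                                 gradients, heterogeneity, mahalanobis_radii,
                                 smooth_profile, summarize_gradients)


class TestMahalanobisRadii:
    def test_identity_covariance(self):
        m = EllipsoidModel(np.zeros(3), np.eye(3))
        assert mahalanobis_radii(np.array([3.0, 0.0, 0.0]), m) == pytest.approx(9.0)

    def test_center_is_zero(self):
        m = EllipsoidModel([1, 2, 3], np.diag([4.0, 2.0, 1.0]))
        assert mahalanobis_radii(np.array([1.0, 2.0, 3.0]), m) == pytest.approx(0.0)

    def test_anisotropic_analytic(self):
        m = EllipsoidModel(np.zeros(3), np.diag([4.0, 1.0, 1.0]))
        assert mahalanobis_radii(np.array([2.0, 0.0, 0.0]), m) == pytest.approx(1.0)

    def test_scaling_sigma_rescales_u(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 3))
        sigma = np.diag([2.0, 3.0, 1.5])
        u1 = mahalanobis_radii(pts, EllipsoidModel(np.zeros(3), sigma))
        u2 = mahalanobis_radii(pts, EllipsoidModel(np.zeros(3), 4.0 * sigma))
        np.testing.assert_allclose(u2, u1 / 4.0)

    def test_non_spd_sigma_rejected(self):
        with pytest.raises(ValueError):
            EllipsoidModel(np.zeros(3), np.diag([1.0, -1.0, 1.0]))

    def test_rigid_motion_invariance(self):
        # rotating/translating the data with theta transformed accordingly
        # leaves every radius (hence the u-ordering and step fit) unchanged
        from metagrad.phantom import rotation_matrix
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(100, 3)) * [8, 5, 3]
        mu = np.array([1.0, -2.0, 0.5])
        sigma = np.diag([64.0, 25.0, 9.0])
        r = rotation_matrix((30.0, -20.0, 55.0))
        t = np.array([10.0, -4.0, 7.0])
        u1 = mahalanobis_radii(pts, EllipsoidModel(mu, sigma))
        u2 = mahalanobis_radii(pts @ r.T + t, EllipsoidModel(r @ mu + t, r @ sigma @ r.T))
        np.testing.assert_allclose(u2, u1, rtol=1e-10)


class TestSmoothProfile:
    def test_constant_step_fit_reproduced(self):
        u = np.linspace(0, 2, 100)
        sp = smooth_profile(u, np.full(100, 4.2))
        assert np.abs(sp(u) - 4.2).max() < 1e-9
        assert np.abs(sp.derivative()(u)).max() < 1e-6

    def test_linear_step_fit_reproduced_with_slope(self):
        u = np.linspace(0, 3, 150)
        sp = smooth_profile(u, 10.0 - 2.0 * u)
        assert np.abs(sp(u) - (10 - 2 * u)).max() < 1e-6
        assert np.abs(sp.derivative()(u) + 2.0).max() < 1e-6

    def test_smooth_curve_recovery_within_one_percent_of_peak(self):
        # noiseless smooth decreasing profile sampled on a step fit
        u = np.sort(np.random.default_rng(1).uniform(0, 2, 600))
        f = 10.0 * np.exp(-u / 0.8)
        sp = smooth_profile(u, f)
        assert np.abs(sp(u) - f).max() < 0.1   # 1% of peak 10

    def test_duplicate_radii_collapsed(self):
        u = np.repeat(np.linspace(0, 1, 20), 3)
        y = np.repeat(np.linspace(5, 1, 20), 3)
        sp = smooth_profile(u, y)
        assert np.abs(sp(u) - y).max() < 1e-6

    def test_too_few_distinct_radii_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            smooth_profile([0.0, 0.0, 1.0, 1.0], [1.0, 1.0, 0.5, 0.5])


class TestGradients:
    def _profile(self, u, y, spline):
        order = np.argsort(u)
        return UptakeProfile(u=u[order], order=order, y=y[order], y_step=y[order],
                             mode_index=0, spline=spline, y_smooth=spline(u[order]),
                             residuals=np.zeros_like(u))

    def test_linear_profile_analytic_chain(self):
        # f~(u) = 10 - 2u: g = +2; g~ = 2 / max f~; gY = Y g~
        u = np.linspace(0, 2, 50)
        sp = smooth_profile(u, 10 - 2 * u)
        y = np.full(50, 5.0)
        prof = self._profile(u, y, sp)
        gs = gradients(prof)
        np.testing.assert_allclose(gs.g, 2.0, atol=1e-6)
        np.testing.assert_allclose(gs.g_norm, 2.0 / 10.0, atol=1e-7)
        np.testing.assert_allclose(gs.g_weighted, 5.0 * 0.2, atol=1e-6)

    def test_constant_profile_zero_gradients(self):
        u = np.linspace(0, 1, 30)
        sp = smooth_profile(u, np.full(30, 3.0))
        gs = gradients(self._profile(u, np.full(30, 3.0), sp))
        np.testing.assert_allclose(gs.g, 0.0, atol=1e-6)


class TestHeterogeneity:
    def test_perfect_fit_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert heterogeneity(y, y) == (0.0, 0.0)

    def test_derived_arithmetic(self):
        # RSS = 0.5; H0 = 0.5 / (15/4); H1 = 0.5 / 0.91667 (n-1 variance)
        y = np.array([2.0, 1.0, 3.0, 1.0])
        yhat = np.array([1.5, 1.5, 3.0, 1.0])
        h0, h1 = heterogeneity(y, yhat)
        assert h0 == pytest.approx(0.5 / (15.0 / 4.0))
        assert h1 == pytest.approx(0.5 / np.var(y, ddof=1))
        assert h1 == pytest.approx(0.54545454, rel=1e-6)

    def test_quadratic_residual_scaling(self):
        y = np.array([2.0, 1.0, 3.0, 1.0])
        yhat = np.array([1.5, 1.5, 3.0, 1.0])
        h0a, h1a = heterogeneity(y, yhat)
        h0b, h1b = heterogeneity(y, y + 2 * (yhat - y))
        assert h0b == pytest.approx(4 * h0a)
        assert h1b == pytest.approx(4 * h1a)

    def test_mean_normalized_option_divides_by_n(self):
        y = np.array([2.0, 1.0, 3.0, 1.0])
        yhat = np.array([1.5, 1.5, 3.0, 1.0])
        h0, _ = heterogeneity(y, yhat)
        h0m, _ = heterogeneity(y, yhat, mean_normalized=True)
        assert h0m == pytest.approx(h0 / 4.0)


class TestSummarizeGradients:
    def test_constant_sample(self):
        gs = GradientSample(*(np.full(5, 2.0),) * 3)
        s = summarize_gradients(gs)
        assert s.g_q25 == s.g_q95 == 2.0

    def test_linear_interpolation_quantiles(self):
        v = np.array([-1.0, 0.0, 1.0, 2.0])
        gs = GradientSample(v, v, v)
        s = summarize_gradients(gs)
        assert s.gn_q25 == pytest.approx(-0.25)
        assert s.gn_q95 == pytest.approx(1.85)

    def test_q25_never_exceeds_q95(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            v = rng.normal(size=rng.integers(2, 50))
            s = summarize_gradients(GradientSample(v, v, v))
            assert s.g_q25 <= s.g_q95


class TestFitDegenerateCases:
    def test_constant_uptake_returns_moment_init(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(60, 3)) * [10, 7, 5]
        res = EllipsoidalUptakeModel(coords, np.full(60, 2.0)).fit()
        assert res.h0 == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(res.h1)
        np.testing.assert_allclose(res.ellipsoid.mu, coords.mean(axis=0), atol=1e-9)

    def test_collinear_voxels_rejected(self):
        t = np.linspace(0, 1, 35)
        coords = np.c_[t, 2 * t, -t]
        with pytest.raises(ValueError, match="degenerate"):
            EllipsoidalUptakeModel(coords, np.ones(35)).fit()

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            EllipsoidalUptakeModel(np.random.default_rng(0).normal(size=(10, 3)), np.ones(10))

    def test_rss_invariant_under_sigma_rescaling(self):
        # u-ordering is unchanged by Sigma -> c Sigma, so the step-fit SSE is too
        from metagrad.shape_regression import unimodal_fit
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(80, 3)) * [10, 6, 4]
        y = np.exp(-np.sum(coords**2, axis=1) / 100) * 10
        for c in (1.0, 0.25, 9.0):
            m = EllipsoidModel(np.zeros(3), c * np.diag([100.0, 36.0, 16.0]))
            u = mahalanobis_radii(coords, m)
            o = np.argsort(u, kind="stable")
            _, _, sse = unimodal_fit(u[o], y[o])
            if c == 1.0:
                ref = sse
            else:
                assert sse == pytest.approx(ref, rel=1e-12)


class TestFitOnSyntheticSample:
    def test_recovers_profile_on_analytic_ellipsoid(self):
        # direct sample (no grid/pipeline): y an exact unimodal function of u_true
        rng = np.random.default_rng(6)
        coords = rng.uniform(-25, 25, size=(800, 3))
        sigma_true = np.diag([400.0, 225.0, 100.0])
        m_true = EllipsoidModel(np.array([1.0, -2.0, 0.5]), sigma_true)
        u = mahalanobis_radii(coords, m_true)
        y = np.where(u <= 0.5, 2 + 8 * u, 6 * np.exp(-(u - 0.5)))
        ellip, profile = fit_structural_model(coords, y, seed=0)
        rel = profile.rss / float(y @ y)
        assert rel < 1e-4
        np.testing.assert_allclose(ellip.mu, m_true.mu, atol=1.0)

    def test_low_decile_downweighting_option(self):
        # robustness option: halving the weight of the dimmest decile during
        # the theta search must leave recovery on clean data intact
        from metagrad.structural import FitConfig
        rng = np.random.default_rng(17)
        coords = rng.uniform(-25, 25, size=(600, 3))
        m_true = EllipsoidModel(np.zeros(3), np.diag([400.0, 225.0, 100.0]))
        u = mahalanobis_radii(coords, m_true)
        y = 8.0 * np.exp(-u)
        cfg = FitConfig(downweight_low_decile=True)
        res = EllipsoidalUptakeModel(coords, y, config=cfg).fit(seed=0)
        np.testing.assert_allclose(res.ellipsoid.mu, m_true.mu, atol=1.0)
        assert res.h0 < 1e-3

    def test_summary_renders(self, noiseless_monotone_fit):
        text = noiseless_monotone_fit.results.summary()
        assert "H0" in text and "mu (mm)" in text and "g.w" in text

    def test_profile_frame_alignment(self, noiseless_monotone_fit):
        res = noiseless_monotone_fit.results
        frame = res.profile_frame()
        assert len(frame) == res.nobs
        # original-order Y must match the model's input uptake
        np.testing.assert_allclose(frame["Y"].to_numpy(), res.model.y)
        np.testing.assert_allclose(frame["g.w"], frame["Y"] * frame["g.n"], atol=1e-12)
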