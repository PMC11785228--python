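"""Localization models M1-M5: simulators, closed forms, likelihoods, and
Bayesian parameter recovery."""

import numpy as np
import pytest
from scipy import stats

from centrospot import models as md
from centrospot.core_io import (
    ConfigError,
    NucleusGeometry,
    SpotSet,
    default_circle,
    rng_for,
)
from centrospot.models import (
    FitError,
    GeometryKindError,
    IntegrationConfig,
    MCMCConfig,
    RadialGaussianModel,
    closed_form_K,
    fit_m3,
    fit_m4_mcmc,
    fit_m5_mcmc,
    pairwise_distance_density,
    radial_loglik,
    simulate_m1,
    simulate_m2,
    simulate_m3,
    simulate_radially_shifted_gaussian,
)


def radii_spotset(radii, geometry, nucleus_id="r"):
    """Spot set with prescribed radial distances (spots on the +x axis)."""
    center = np.asarray(geometry.center)
    pts = center + np.column_stack([radii, np.zeros(len(radii))])
    return SpotSet(nucleus_id, pts, geometry)


class TestM1:
    def test_matches_csr_sampler_stream(self):
        from centrospot.simulators import sample_uniform_in_circle

        g = default_circle()
        a = simulate_m1(g, 46, rng_for(20, 0))
        b = sample_uniform_in_circle(g, 46, rng_for(20, 0))
        np.testing.assert_array_equal(a.points, b.points)

    def test_mask_with_hole_excludes_hole(self):
        yy, xx = np.mgrid[0:128, 0:128]
        r2 = (xx - 64) ** 2 + (yy - 64) ** 2
        mask = ((r2 <= 50**2) & (r2 >= 20**2)).astype(np.uint16)
        g = NucleusGeometry(kind="mask", center=(64, 64), mask=mask, label=1)
        ss = simulate_m1(g, 500, rng_for(20, 1))
        rr = np.hypot(*(ss.points - (64, 64)).T)
        assert (rr >= 19.0).all()

    def test_quadrant_uniformity(self):
        g = default_circle()
        pts = simulate_m1(g, 10_000, rng_for(20, 2)).points - g.center
        quad = (pts[:, 0] > 0).astype(int) * 2 + (pts[:, 1] > 0).astype(int)
        counts = np.bincount(quad, minlength=4)
        _, p = stats.chisquare(counts)
        assert p > 0.001


class TestM2:
    def test_requires_ellipse_geometry(self):
        with pytest.raises(GeometryKindError, match="extract_geometry_from_mask"):
            simulate_m2(default_circle(), 10, rng_for(21, 0))

    def test_circular_ellipse_is_isotropic(self):
        g = NucleusGeometry(kind="ellipse", center=(128, 128), axes=(92, 92))
        pts = simulate_m2(g, 20_000, rng_for(21, 1)).points - (128, 128)
        assert pts[:, 0].std() == pytest.approx(pts[:, 1].std(), rel=0.03)

    def test_axis_ratio_three_pre_truncation(self):
        # huge ellipse with sigma_scale shrinking the density: no truncation
        g = NucleusGeometry(kind="ellipse", center=(0, 0), axes=(600, 200))
        pts = simulate_m2(g, 20_000, rng_for(21, 2), sigma_scale=0.1).points
        ratio = pts[:, 0].std() / pts[:, 1].std()
        assert ratio == pytest.approx(3.0, rel=0.1)

    def test_degenerate_scale_collapses_to_center(self):
        g = NucleusGeometry(kind="ellipse", center=(128, 128), axes=(92, 92))
        pts = simulate_m2(g, 100, rng_for(21, 3), sigma_scale=1e-6).points
        assert np.abs(pts - (128, 128)).max() < 0.1

    def test_orientation_respected(self):
        th = np.pi / 4
        g = NucleusGeometry(kind="ellipse", center=(0, 0), axes=(600, 200),
                            orientation=th)
        pts = simulate_m2(g, 20_000, rng_for(21, 4), sigma_scale=0.1).points
        w, v = np.linalg.eigh(np.cov(pts.T))
        ang = np.arctan2(v[1, np.argmax(w)], v[0, np.argmax(w)]) % np.pi
        assert min(abs(ang - th), np.pi - abs(ang - th)) < 0.05


class TestClosedFormK:
    def test_anchor_values(self):
        m = RadialGaussianModel(r0=0.0, sigma=10.0, amplitude=2.0)
        assert closed_form_K(0.0, m) == 0.0
        assert closed_form_K(1e6, m) == pytest.approx(2.0)
        r_half = 10.0 * np.sqrt(2 * np.log(2))
        assert closed_form_K(r_half, m) == pytest.approx(1.0)

    def test_monotone_and_bounded(self):
        m = RadialGaussianModel(r0=0.0, sigma=7.0, amplitude=3.0)
        grid = np.linspace(0, 100, 400)
        K = closed_form_K(grid, m)
        assert (np.diff(K) >= 0).all()
        assert (K <= 3.0 + 1e-12).all()


class TestRadialLoglik:
    def test_single_point_at_mean(self):
        sigma = 4.0
        assert radial_loglik([30.0], 30.0, sigma) == pytest.approx(
            -0.5 * np.log(2 * np.pi * sigma**2)
        )

    def test_translation_invariance(self):
        r = np.array([10.0, 12.0, 15.0])
        assert radial_loglik(r, 11.0, 2.0) == pytest.approx(
            radial_loglik(r + 7.5, 18.5, 2.0)
        )

    def test_matches_naive_sum(self):
        rng = rng_for(22, 0)
        r = rng.uniform(5, 40, 25)
        r0, sigma = 20.0, 6.0
        naive = sum(
            -0.5 * np.log(2 * np.pi * sigma**2) - (x - r0) ** 2 / (2 * sigma**2)
            for x in r
        )
        assert radial_loglik(r, r0, sigma) == pytest.approx(naive, abs=1e-12)

    def test_sigma_domain(self):
        with pytest.raises(ValueError):
            radial_loglik([1.0], 0.0, -1.0)


class TestM3:
    def test_rayleigh_recovery(self):
        big = default_circle(radius=200.0)  # no boundary truncation
        sets = [simulate_m3(big, 50, 15.0, rng_for(23, i)) for i in range(200)]
        m = fit_m3(sets)
        assert m.sigma == pytest.approx(15.0, rel=0.02)
        assert m.r0 == 0.0

    def test_exact_cdf_zero_residual(self):
        g = default_circle(radius=500.0)
        sigma = 12.0
        u = (np.arange(1000) + 0.5) / 1000
        radii = sigma * np.sqrt(-2 * np.log(1 - u))  # Rayleigh quantiles
        m = fit_m3([radii_spotset(radii, g)])
        assert m.diagnostics["rmse"] < 1e-3
        assert m.sigma == pytest.approx(sigma, rel=0.01)

    def test_degenerate_radii_flagged(self):
        g = default_circle()
        with pytest.raises(FitError, match="degenerate"):
            fit_m3([radii_spotset(np.full(50, 10.0), g)])

    def test_underdetermined(self):
        g = default_circle()
        with pytest.raises(FitError, match="underdetermined"):
            fit_m3([radii_spotset(np.array([1.0, 2.0]), g)])

    def test_pairwise_target_also_fits(self):
        big = default_circle(radius=200.0)
        sets = [simulate_m3(big, 50, 15.0, rng_for(23, 500 + i)) for i in range(50)]
        m = fit_m3(sets, fit_target="pairwise")
        assert m.diagnostics["fit_target"] == "pairwise"
        assert m.sigma > 0


class TestRadiallyShiftedSimulator:
    def test_thin_ring(self):
        g = default_circle()
        ss = simulate_radially_shifted_gaussian(g, 200, 30.0, 1e-3, rng_for(24, 0))
        assert np.abs(ss.radii() - 30.0).max() < 0.01

    def test_moments(self):
        big = default_circle(radius=200.0)
        ss = simulate_radially_shifted_gaussian(big, 10_000, 30.0, 5.0, rng_for(24, 1))
        r = ss.radii()
        assert r.mean() == pytest.approx(30.0, abs=0.2)
        assert r.std() == pytest.approx(5.0, abs=0.2)

    def test_angles_uniform_rayleigh_test(self):
        import pingouin as pg

        big = default_circle(radius=200.0)
        ss = simulate_radially_shifted_gaussian(big, 10_000, 30.0, 5.0, rng_for(24, 2))
        d = ss.points - big.center
        angles = np.arctan2(d[:, 1], d[:, 0])
        _, p = pg.circ_rayleigh(angles)
        assert p > 0.001

    def test_infeasible_r0(self):
        with pytest.raises(ConfigError):
            simulate_radially_shifted_gaussian(default_circle(), 10, 200.0, 1.0,
                                               rng_for(24, 3))


class TestM4:
    def test_parameter_recovery_within_5pct(self, m4_fit):
        assert m4_fit.r0 == pytest.approx(30.0, rel=0.05)
        assert m4_fit.sigma == pytest.approx(5.0, rel=0.05)
        assert 0.005 < m4_fit.diagnostics["acceptance_fraction"] < 0.95

    def test_posterior_summary_shape(self, m4_fit):
        s = m4_fit.posterior_summary()
        assert s["r0"]["q2.5"] < m4_fit.r0 < s["r0"]["q97.5"]

    def test_tight_prior_pins_r0(self, rsg_sets):
        priors = {"mu_r0": 30.0, "tau_r0": 1e-9, "mu_sigma": 5.0, "tau_sigma": 2.5}
        m = fit_m4_mcmc(rsg_sets[:50], cfg=MCMCConfig(seed=6), priors=priors)
        assert m.r0 == pytest.approx(30.0, abs=0.1)

    def test_determinism(self, rsg_sets):
        cfg = MCMCConfig(n_iterations=500, burn_in=100, seed=9)
        a = fit_m4_mcmc(rsg_sets[:20], cfg=cfg)
        b = fit_m4_mcmc(rsg_sets[:20], cfg=cfg)
        np.testing.assert_array_equal(a.posterior_samples, b.posterior_samples)

    def test_flat_priors_track_mle(self):
        g = default_circle(radius=400.0)
        rng = rng_for(25, 0)
        radii = rng.normal(60.0, 8.0, 10_000)
        radii = radii[radii > 0]
        ss = radii_spotset(radii, g)
        # priors centered on the data scale but made effectively flat
        priors = {"mu_r0": float(radii.mean()), "tau_r0": 1e4,
                  "mu_sigma": float(radii.std()), "tau_sigma": 1e4}
        m = fit_m4_mcmc([ss], cfg=MCMCConfig(seed=8, proposal_scales=(0.2, 0.1)),
                        priors=priors)
        assert m.r0 == pytest.approx(radii.mean(), rel=0.02)
        assert m.sigma == pytest.approx(radii.std(), rel=0.02)


class TestPairwiseDensity:
    def test_normalization(self):
        for r0, sigma in ((30.0, 5.0), (30.0, 2.0), (15.0, 12.0)):
            dg, pdf = md._density_grid(r0, sigma, IntegrationConfig())
            assert np.trapezoid(pdf, dg) == pytest.approx(1.0, abs=1e-3)

    def test_finite_at_zero(self):
        assert np.isfinite(pairwise_distance_density(0.0, r0=30.0, sigma=5.0))

    def test_monte_carlo_oracle_supnorm(self, density_mc_errors):
        for setting, err in density_mc_errors.items():
            assert err < 0.02, f"density mismatch {err:.4f} at {setting}"

    def test_sigma_to_zero_ring_law(self):
        r0, sigma = 30.0, 0.03  # sigma = 1e-3 r0
        d = np.linspace(0.5, 2 * r0 - 2.0, 150)
        pdf = pairwise_distance_density(d, r0=r0, sigma=sigma)
        ring = (2.0 / np.pi) / np.sqrt(4 * r0**2 - d**2)
        np.testing.assert_allclose(pdf, ring, rtol=0.02)
        # essentially no mass beyond the ring diameter
        tail = pairwise_distance_density(np.array([2 * r0 + 1.0]), r0=r0, sigma=sigma)
        assert tail[0] < 1e-6

    def test_printed_kernel_normalized_and_supported(self):
        # the compressed 1/(2 r1 r2) kernel is exposed for reference; it omits
        # the d/sqrt(1-u^2) Jacobian factor, so only its normalization and
        # support are contract-checked (the Jacobian form is the oracle-backed
        # default)
        dg, pdf = md._density_grid(30.0, 5.0, IntegrationConfig(method="printed"))
        assert np.trapezoid(pdf, dg) == pytest.approx(1.0, abs=1e-3)
        assert (pdf >= 0).all()


class TestM5:
    def test_parameter_recovery_within_10pct(self, m5_fit):
        assert m5_fit.r0 == pytest.approx(30.0, rel=0.10)
        assert m5_fit.sigma == pytest.approx(5.0, rel=0.10)

    def test_m4_m5_agreement(self, m4_fit, m5_fit):
        assert m5_fit.r0 == pytest.approx(m4_fit.r0, rel=0.10)
        assert m5_fit.sigma == pytest.approx(m4_fit.sigma, rel=0.10)

    def test_determinism(self, rsg_sets):
        cfg = MCMCConfig(n_iterations=120, burn_in=20,
                         proposal_scales=(0.05, 0.025), seed=14)
        a = fit_m5_mcmc(rsg_sets[:10], cfg=cfg)
        b = fit_m5_mcmc(rsg_sets[:10], cfg=cfg)
        np.testing.assert_array_equal(a.posterior_samples, b.posterior_samples)


def test_recovery_bias_shrinks_with_sample_size():
    """M4 posterior error decreases as pooled radii grow (50 -> 500 -> 5000)."""
    g = default_circle(radius=200.0)
    errors = []
    for n in (50, 500, 5000):
        rng = rng_for(26, n)
        radii = rng.normal(30.0, 5.0, int(n * 1.1))
        radii = radii[radii > 0][:n]
        m = fit_m4_mcmc([radii_spotset(radii, g)],
                        cfg=MCMCConfig(seed=n, proposal_scales=(0.5, 0.25)))
        errors.append(abs(m.r0 - 30.0) + abs(m.sigma - 5.0))
    assert errors[2] < errors[0]
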