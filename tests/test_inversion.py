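"""LM inversion: cost function, determinism, degenerate inputs, recovery."""

import math

import numpy as np
import pytest

from srrkit.inversion import FitConfig, chi_squared, lm_fit
from srrkit.montecarlo import SimulationConfig, simulate_srr_image
from srrkit.optics import OpticalProperties
from srrkit.pipeline import RadialCurve, RadialWindow, radial_bin

from conftest import PIXEL_SCALE, fast_cfg

PS = PIXEL_SCALE


def make_curve(values, d_rho=PS):
    values = np.asarray(values, float)
    rho = (np.arange(values.size) + 0.5) * d_rho
    return RadialCurve(rho, values, d_rho, np.ones(values.size, int))


def window_over(curve, i0, i1):
    return RadialWindow(float(curve.rho[i0]), float(curve.rho[i1]),
                        i1 - i0 + 1, i0, i1)


class TestChiSquared:
    def test_identical_curves_cost_zero(self):
        c = make_curve(np.linspace(3.0, 0.1, 30))
        w = window_over(c, 2, 25)
        assert chi_squared(c, c, w) == 0.0

    def test_uniform_decade_offset_costs_one(self):
        base = np.linspace(3.0, 0.1, 30)
        mc = make_curve(10.0 * base)
        exp = make_curve(base)
        w = window_over(mc, 2, 25)
        assert chi_squared(mc, exp, w) == pytest.approx(1.0, rel=1e-12)

    def test_one_of_four_bins_off_by_a_decade(self):
        base = np.array([1.0, 1.0, 1.0, 1.0])
        mc_vals = base.copy()
        mc_vals[2] = 10.0
        mc = make_curve(mc_vals)
        exp = make_curve(base)
        w = window_over(mc, 0, 3)
        assert chi_squared(mc, exp, w) == pytest.approx(0.25, rel=1e-12)

    def test_nonpositive_bins_reduce_p_with_warning(self):
        mc_vals = np.ones(6)
        mc_vals[3] = 0.0
        mc = make_curve(mc_vals)
        exp = make_curve(np.full(6, 10.0))
        w = window_over(mc, 0, 5)
        with pytest.warns(UserWarning):
            chi2 = chi_squared(mc, exp, w)
        assert chi2 == pytest.approx(1.0)

    def test_empty_window_raises(self):
        mc = make_curve(np.zeros(6))
        exp = make_curve(np.ones(6))
        w = window_over(mc, 0, 5)
        with pytest.raises(ValueError):
            chi_squared(mc, exp, w)


@pytest.fixture(scope="module")
def noiseless_target(medium_beam, geometry):
    """An MC-generated curve at known properties, plus its binning."""
    props = OpticalProperties(mu_a=0.02, mu_s_prime=2.0)
    img, _ = simulate_srr_image(props, geometry, medium_beam,
                                SimulationConfig(n_photons=400_000, seed=101,
                                                 kill_radius=30.0))
    curve = radial_bin(img.values, medium_beam.origin, PS, PS)
    return props, curve


class TestLmFit:
    def test_closed_loop_recovery(self, noiseless_target, medium_beam,
                                  geometry):
        """Forward-modeled data refit with an independent seed: few-percent
        coefficient recovery."""
        props, curve = noiseless_target
        cfg = FitConfig(n_photons_per_iter=100_000, seed=55)
        fit = lm_fit(curve, medium_beam, geometry, cfg)
        assert fit.converged
        assert fit.mu_a_hat == pytest.approx(props.mu_a, rel=0.10)
        assert fit.mu_s_prime_hat == pytest.approx(props.mu_s_prime, rel=0.03)

    def test_fit_is_deterministic_for_fixed_seed(self, noiseless_target,
                                                 medium_beam, geometry):
        props, curve = noiseless_target
        cfg = FitConfig(n_photons_per_iter=50_000, seed=20,
                        max_iterations=6, max_refinements=0)
        fit1 = lm_fit(curve, medium_beam, geometry, cfg)
        fit2 = lm_fit(curve, medium_beam, geometry, cfg)
        assert fit1.mu_a_hat == fit2.mu_a_hat
        assert fit1.mu_s_prime_hat == fit2.mu_s_prime_hat
        assert fit1.chi2_final == fit2.chi2_final

    def test_accepted_steps_never_increase_the_objective(self,
                                                         noiseless_target,
                                                         medium_beam,
                                                         geometry):
        props, curve = noiseless_target
        cfg = FitConfig(n_photons_per_iter=50_000, seed=3)
        fit = lm_fit(curve, medium_beam, geometry, cfg)
        for entry in fit.trace[1:]:
            if entry.get("accepted"):
                assert entry["chi2"] <= entry["chi2_before"] + 1e-15

    def test_flat_curve_returns_nonconverged_without_crashing(self,
                                                              medium_beam,
                                                              geometry):
        flat = make_curve(np.full(150, 2.0))
        cfg = FitConfig(n_photons_per_iter=20_000, seed=9, max_iterations=8)
        fit = lm_fit(flat, medium_beam, geometry, cfg)
        assert not fit.converged
        assert math.isfinite(fit.mu_a_hat) or math.isnan(fit.mu_a_hat)

    def test_rejects_unusable_curve_gracefully(self, medium_beam, geometry):
        empty = make_curve(np.zeros(50))
        fit = lm_fit(empty, medium_beam, geometry,
                     FitConfig(n_photons_per_iter=10_000, seed=1))
        assert not fit.converged
        assert "window" in fit.message or "bins" in fit.message
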