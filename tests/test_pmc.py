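"""Perturbation-MC rescaling and derivative assembly."""

import numpy as np
import pytest

from srrkit.montecarlo import PathStatistics, simulate_srr_image
from srrkit.optics import OpticalProperties
from srrkit.pipeline import radial_bin
from srrkit.pmc import (PerturbationSpec, jacobian_columns, rescale_factors,
                        rescale_reflectance)

from conftest import PIXEL_SCALE, fast_cfg


def single_record(j, length, weight=1.0):
    return PathStatistics(np.array([5]), np.array([5]), np.array([weight]),
                          np.array([j]), np.array([length]), n_launched=1)


class TestRescaleFactors:
    def test_identity_perturbation_is_exact(self, small_beam, geometry,
                                            turbid_props):
        img, stats = simulate_srr_image(turbid_props, geometry, small_beam,
                                        fast_cfg(n_photons=5_000))
        out = rescale_reflectance(stats, turbid_props, turbid_props,
                                  small_beam.shape, PIXEL_SCALE,
                                  small_beam.origin)
        np.testing.assert_array_equal(out.values, img.values)

    def test_scattering_factor_hand_value(self):
        # j=2 collisions, L=10 mm, mu_s 1.0 -> 1.1: (1.1)^2 * exp(-0.1*10)
        stats = single_record(j=2, length=10.0)
        props = OpticalProperties(mu_a=0.01, mu_s_prime=0.5, g=0.5)  # mu_s=1
        pert = props.with_(mu_s_prime=0.55)                          # mu_s=1.1
        factor = rescale_factors(stats, props, pert)[0]
        assert factor == pytest.approx(1.21 * np.exp(-1.0), rel=1e-12)
        assert factor == pytest.approx(0.44513, abs=5e-6)

    def test_absorption_factor_hand_value(self):
        # mu_a 0.01 -> 0.02, L=10 mm: exp(-0.1)
        stats = single_record(j=3, length=10.0)
        props = OpticalProperties(mu_a=0.01, mu_s_prime=1.0)
        pert = props.with_(mu_a=0.02)
        assert rescale_factors(stats, props, pert)[0] == pytest.approx(
            np.exp(-0.1), rel=1e-12)
        assert rescale_factors(stats, props, pert)[0] == pytest.approx(
            0.90484, abs=5e-6)

    @pytest.mark.parametrize("field", ["g", "n"])
    def test_unsupported_parameters_rejected(self, field):
        stats = single_record(1, 1.0)
        props = OpticalProperties(mu_a=0.01, mu_s_prime=1.0)
        pert = props.with_(**{field: getattr(props, field) + 0.05})
        with pytest.raises(ValueError):
            rescale_factors(stats, props, pert)

    def test_large_perturbation_warns(self):
        # a long path re-weighted to much weaker absorption blows the
        # factor past the validity limit
        stats = single_record(j=0, length=100.0)
        props = OpticalProperties(mu_a=0.1, mu_s_prime=1.0)
        pert = props.with_(mu_a=0.01)  # factor exp(+9) ~ 8100
        with pytest.warns(UserWarning):
            rescale_reflectance(stats, props, pert, (11, 11), PIXEL_SCALE,
                                (5, 5))


class TestJacobian:
    def test_identity_spec_gives_zero_derivative(self, small_beam, geometry,
                                                 turbid_props):
        _, stats = simulate_srr_image(turbid_props, geometry, small_beam,
                                      fast_cfg(n_photons=5_000))
        # a vanishing numerator: rescale to the same properties
        derivs = jacobian_columns(stats, turbid_props, [], small_beam.shape,
                                  PIXEL_SCALE, small_beam.origin, PIXEL_SCALE)
        assert derivs == {}

    def test_absorption_derivative_is_nonpositive(self, small_beam, geometry,
                                                  turbid_props):
        _, stats = simulate_srr_image(turbid_props, geometry, small_beam,
                                      fast_cfg(n_photons=20_000))
        derivs = jacobian_columns(stats, turbid_props,
                                  [PerturbationSpec("mu_a", 0.05)],
                                  small_beam.shape, PIXEL_SCALE,
                                  small_beam.origin, PIXEL_SCALE)
        d = derivs["mu_a"]
        assert np.all(d[np.isfinite(d)] <= 0.0)

    def test_rescale_then_bin_equals_bin_then_rescale(self, small_beam,
                                                      geometry, turbid_props):
        """Binning is linear in the weights, so the order cannot matter."""
        _, stats = simulate_srr_image(turbid_props, geometry, small_beam,
                                      fast_cfg(n_photons=10_000))
        pert = turbid_props.with_(mu_a=0.012)
        img = rescale_reflectance(stats, turbid_props, pert, small_beam.shape,
                                  PIXEL_SCALE, small_beam.origin)
        curve_a = radial_bin(img.values, small_beam.origin, PIXEL_SCALE,
                             PIXEL_SCALE)
        factors = rescale_factors(stats, turbid_props, pert)
        inside = ((stats.row >= 0) & (stats.row < small_beam.shape[0])
                  & (stats.col >= 0) & (stats.col < small_beam.shape[1]))
        from srrkit.montecarlo import bin_exits_to_image
        img_b = bin_exits_to_image(stats.row, stats.col,
                                   stats.weight * factors, small_beam.shape,
                                   PIXEL_SCALE, small_beam.origin,
                                   stats.n_launched)
        curve_b = radial_bin(img_b.values, small_beam.origin, PIXEL_SCALE,
                             PIXEL_SCALE)
        np.testing.assert_array_equal(curve_a.values, curve_b.values)

    def test_pmc_curve_matches_fresh_simulation(self, medium_beam, geometry):
        """Rescaled curve vs a common-seed re-simulation at p', 3 sigma/bin."""
        props = OpticalProperties(mu_a=0.01, mu_s_prime=2.0)
        delta = 0.08
        pert = props.with_(mu_s_prime=props.mu_s_prime * (1 + delta))
        n = 200_000
        _, stats = simulate_srr_image(props, geometry, medium_beam,
                                      fast_cfg(n_photons=n, seed=31))
        pmc_img = rescale_reflectance(stats, props, pert, medium_beam.shape,
                                      PIXEL_SCALE, medium_beam.origin)
        fresh_img, _ = simulate_srr_image(pert, geometry, medium_beam,
                                          fast_cfg(n_photons=n, seed=31))
        # per-bin weight sums and their variances from the photon records
        d_rho = 0.25
        n_bins = 16

        def bin_sums(st, factors=None):
            w = st.weight if factors is None else st.weight * factors
            rho = np.hypot((st.row - medium_beam.origin[0]) * PIXEL_SCALE,
                           (st.col - medium_beam.origin[1]) * PIXEL_SCALE)
            idx = np.floor(rho / d_rho).astype(int)
            keep = idx < n_bins
            return (np.bincount(idx[keep], weights=w[keep],
                                minlength=n_bins),
                    np.bincount(idx[keep], weights=w[keep] ** 2,
                                minlength=n_bins))

        from srrkit.pmc import rescale_factors
        fresh_img2, fresh_stats = simulate_srr_image(
            pert, geometry, medium_beam, fast_cfg(n_photons=n, seed=31))
        s_pmc, v_pmc = bin_sums(stats, rescale_factors(stats, props, pert))
        s_new, v_new = bin_sums(fresh_stats)
        sel = slice(2, 15)
        se = np.sqrt(v_pmc + v_new)
        assert np.all(np.abs(s_pmc - s_new)[sel] <= 3 * se[sel])
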