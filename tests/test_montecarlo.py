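"""Forward Monte Carlo: conservation, determinism, symmetry, oracles."""

import math

import numpy as np
import pytest

from srrkit.montecarlo import (BeamProfile, SimulationConfig,
                               convolve_with_beam, diffusion_reflectance,
                               simulate_pencil_image, simulate_srr_image)
from srrkit.optics import OpticalProperties, SampleGeometry
from srrkit.pipeline import radial_bin

from conftest import PIXEL_SCALE, fast_cfg


def budget_sum(stats) -> float:
    return sum(stats.energy_budget.values())


class TestEnergyAccounting:
    def test_budget_closes_to_unity(self, small_beam, geometry, turbid_props):
        _, stats = simulate_srr_image(turbid_props, geometry, small_beam,
                                      fast_cfg())
        assert budget_sum(stats) == pytest.approx(1.0, abs=1e-6)

    def test_budget_closes_with_roulette_and_kill(self, small_beam):
        props = OpticalProperties(mu_a=0.3, mu_s_prime=1.0, g=0.5, n=1.4)
        geom = SampleGeometry(thickness_d=5.0)
        cfg = SimulationConfig(n_photons=20_000, seed=3, kill_radius=4.0,
                               roulette_threshold=1e-2, roulette_survival=0.2)
        _, stats = simulate_srr_image(props, geom, small_beam, cfg)
        assert budget_sum(stats) == pytest.approx(1.0, abs=1e-6)
        assert stats.energy_budget["lateral"] > 0

    def test_matched_halfspace_returns_everything(self, small_beam):
        # no absorption, matched index, effectively semi-infinite slab:
        # the random walk returns to the surface with probability one
        props = OpticalProperties(mu_a=0.0, mu_s_prime=1.0, g=0.0, n=1.0)
        geom = SampleGeometry(thickness_d=1e4)
        cfg = SimulationConfig(n_photons=20_000, seed=5,
                               max_path_events=10_000_000)
        _, stats = simulate_srr_image(props, geom, small_beam, cfg)
        lost = (stats.energy_budget["detected_bottom"]
                + stats.energy_budget["truncated"])
        assert stats.energy_budget["detected_top"] == pytest.approx(
            1.0, abs=max(2e-3, 3 * math.sqrt(lost / cfg.n_photons) + lost))

    def test_pure_absorber_reflects_nothing(self, small_beam, geometry):
        # mu_s ~ 0: photons go straight down and never turn back
        props = OpticalProperties(mu_a=1.0, mu_s_prime=1e-9, g=0.0, n=1.0)
        _, stats = simulate_srr_image(props, geometry, small_beam,
                                      fast_cfg(n_photons=5_000))
        assert stats.energy_budget["detected_top"] == 0.0
        assert len(stats) == 0


class TestDeterminismAndValidation:
    def test_fixed_seed_reproduces_bit_exactly(self, small_beam, geometry,
                                               turbid_props):
        img1, st1 = simulate_srr_image(turbid_props, geometry, small_beam,
                                       fast_cfg(n_photons=10_000))
        img2, st2 = simulate_srr_image(turbid_props, geometry, small_beam,
                                       fast_cfg(n_photons=10_000))
        np.testing.assert_array_equal(img1.values, img2.values)
        np.testing.assert_array_equal(st1.weight, st2.weight)
        np.testing.assert_array_equal(st1.path_length, st2.path_length)

    def test_zero_weight_beam_rejected(self):
        with pytest.raises(ValueError):
            BeamProfile(np.zeros((9, 9)), PIXEL_SCALE, (4, 4))

    def test_total_reflectance_bounded_by_launched_energy(self, small_beam,
                                                          geometry):
        props = OpticalProperties(mu_a=0.001, mu_s_prime=1.5)
        img, _ = simulate_srr_image(props, geometry, small_beam,
                                    fast_cfg(n_photons=10_000))
        assert img.total_reflectance <= 1.0 + 1e-12


class TestPencilBeam:
    def test_origin_pixel_holds_the_maximum(self, small_beam, geometry):
        props = OpticalProperties(mu_a=0.1, mu_s_prime=2.0)
        img, _ = simulate_pencil_image(props, geometry,
                                       fast_cfg(n_photons=30_000),
                                       small_beam.shape, PIXEL_SCALE,
                                       small_beam.origin)
        r, c = np.unravel_index(np.argmax(img.values), img.values.shape)
        assert (r, c) == small_beam.origin

    def test_normal_incidence_is_radially_symmetric(self, geometry):
        # quadrant sums of the pencil image agree within 4 sigma
        props = OpticalProperties(mu_a=0.01, mu_s_prime=1.5)
        img, _ = simulate_pencil_image(props, geometry,
                                       fast_cfg(n_photons=100_000, seed=11),
                                       (129, 129), PIXEL_SCALE, (64, 64),
                                       incidence_angle_deg=0.0)
        v = img.values
        o = 64
        quadrants = [v[:o, :o].sum(), v[:o, o + 1:].sum(),
                     v[o + 1:, :o].sum(), v[o + 1:, o + 1:].sum()]
        total = sum(quadrants)
        for q in quadrants:
            # binomial-ish count comparison: each quadrant ~ total/4;
            # sigma in image-value units = sqrt(counts)/(pixel_area * n)
            sigma = math.sqrt((total / 4) / (PIXEL_SCALE**2 * 100_000))
            assert q == pytest.approx(total / 4, abs=4 * sigma + 1e-12)


class TestBeamConvolution:
    def test_delta_kernel_is_identity(self, small_beam, geometry,
                                      turbid_props):
        img, _ = simulate_pencil_image(turbid_props, geometry,
                                       fast_cfg(n_photons=5_000),
                                       small_beam.shape, PIXEL_SCALE,
                                       small_beam.origin)
        delta = np.zeros(small_beam.shape)
        delta[small_beam.origin] = 1.0
        kernel = BeamProfile(delta, PIXEL_SCALE, small_beam.origin)
        out = convolve_with_beam(img, kernel)
        np.testing.assert_allclose(out.values, img.values, atol=1e-12)

    def test_two_delta_kernel_is_average_of_shifts(self, small_beam, geometry,
                                                   turbid_props):
        img, _ = simulate_pencil_image(turbid_props, geometry,
                                       fast_cfg(n_photons=5_000),
                                       small_beam.shape, PIXEL_SCALE,
                                       small_beam.origin)
        k = 5
        two = np.zeros(small_beam.shape)
        two[small_beam.origin] = 1.0
        two[small_beam.origin[0], small_beam.origin[1] + k] = 1.0
        kernel = BeamProfile(two, PIXEL_SCALE, small_beam.origin)
        out = convolve_with_beam(img, kernel)
        shifted = np.zeros_like(img.values)
        shifted[:, k:] = img.values[:, :-k]
        np.testing.assert_allclose(out.values, 0.5 * (img.values + shifted),
                                   atol=1e-9)

    def test_grid_mismatch_rejected(self, small_beam, geometry, turbid_props):
        img, _ = simulate_pencil_image(turbid_props, geometry,
                                       fast_cfg(n_photons=1_000),
                                       (65, 65), PIXEL_SCALE, (32, 32))
        with pytest.raises(ValueError):
            convolve_with_beam(img, small_beam)


class TestDiffusionOracle:
    def test_monotone_decay_and_asymptotic_slope(self):
        props = OpticalProperties(mu_a=0.01, mu_s_prime=1.0, g=0.8, n=1.0)
        rho = np.linspace(2.0, 40.0, 200)
        r = diffusion_reflectance(props, rho)
        assert np.all(np.diff(r) < 0)
        mu_eff = math.sqrt(3 * 0.01 * 1.01)
        # log-slope at large rho approaches -mu_eff (after removing 1/rho^2)
        slope = np.gradient(np.log(r * rho**2), rho)
        assert slope[-1] == pytest.approx(-mu_eff, rel=0.05)

    def test_more_absorption_means_less_reflectance(self):
        rho = np.linspace(0.5, 15.0, 50)
        lo = diffusion_reflectance(
            OpticalProperties(mu_a=0.01, mu_s_prime=1.0), rho)
        hi = diffusion_reflectance(
            OpticalProperties(mu_a=0.02, mu_s_prime=1.0), rho)
        assert np.all(hi < lo)

    def test_matches_independent_transcription(self):
        """Cross-check against a from-scratch dipole implementation."""
        from scipy.integrate import quad

        def independent_dipole(mu_a, mu_sp, n_rel, rho):
            mu_t = mu_a + mu_sp
            d = 1.0 / (3.0 * mu_t)
            mu_eff = math.sqrt(mu_a / d)
            z0 = 1.0 / mu_t

            def fres(theta):
                ci = math.cos(theta)
                s2 = (n_rel * math.sin(theta)) ** 2
                if s2 >= 1.0:
                    return 1.0
                ct = math.sqrt(1.0 - s2)
                rs = (n_rel * ci - ct) / (n_rel * ci + ct)
                rp = (n_rel * ct - ci) / (n_rel * ct + ci)
                return 0.5 * (rs * rs + rp * rp)

            r_phi = quad(lambda t: 2 * math.sin(t) * math.cos(t) * fres(t),
                         0, math.pi / 2)[0]
            r_j = quad(lambda t: 3 * math.sin(t) * math.cos(t) ** 2 * fres(t),
                       0, math.pi / 2)[0]
            zb = 2 * d * (1 + r_j) / (1 - r_phi)
            z1 = z0 + 2 * zb
            r1 = math.hypot(rho, z0)
            r2 = math.hypot(rho, z1)
            phi = (math.exp(-mu_eff * r1) / r1
                   - math.exp(-mu_eff * r2) / r2) / (4 * math.pi * d)
            jz = (z0 * (mu_eff + 1 / r1) * math.exp(-mu_eff * r1) / r1**2
                  + z1 * (mu_eff + 1 / r2) * math.exp(-mu_eff * r2) / r2**2
                  ) / (4 * math.pi)
            return (1 - r_phi) / 4 * phi + (1 - r_j) / 2 * jz

        rng = np.random.default_rng(42)
        for _ in range(10):
            mu_a = float(rng.uniform(0.001, 0.05))
            mu_sp = float(rng.uniform(0.5, 3.0))
            n_rel = float(rng.uniform(1.0, 1.5))
            rho = float(rng.uniform(1.0, 10.0))
            props = OpticalProperties(mu_a=mu_a, mu_s_prime=mu_sp, n=n_rel)
            assert diffusion_reflectance(props, rho) == pytest.approx(
                independent_dipole(mu_a, mu_sp, n_rel, rho), rel=1e-9)

    def test_warns_outside_diffusive_regime(self):
        props = OpticalProperties(mu_a=0.5, mu_s_prime=1.0)
        with pytest.warns(UserWarning):
            diffusion_reflectance(props, 1.0)
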