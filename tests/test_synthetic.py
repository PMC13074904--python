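"""Synthetic instrument: beam profiles, camera rendering, scenario output."""

import numpy as np
import pytest

from srrkit.pipeline import (FULL_SCALE, detect_bloom, normalize_frame,
                             patch_exposure_series, radial_bin)
from srrkit.synthetic import (CameraModel, SyntheticScenario, auto_exposure,
                              default_flat_field, make_beam_profile,
                              render_exposure_triplet, render_frame,
                              _bloom_spill)

PS = 0.0361


class TestBeamProfile:
    def test_normalized_to_unit_sum(self):
        beam = make_beam_profile(grid_shape=(129, 129))
        assert beam.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_pure_core_concentrates_energy(self):
        beam = make_beam_profile(grid_shape=(129, 129), halo_amplitude=0.0)
        yy = (np.arange(129) - 64) * PS
        rho = np.hypot(yy[:, None], yy[None, :])
        inside = beam.weights[rho <= 2 * 0.27].sum()
        assert inside >= 0.99

    def test_radial_profile_decays_beyond_core(self):
        beam = make_beam_profile(grid_shape=(129, 129))
        curve = radial_bin(beam.weights, beam.origin, PS, 2 * PS)
        vals = curve.values[np.isfinite(curve.values)]
        tail = vals[curve.rho[np.isfinite(curve.values)] > 0.4]
        assert np.all(np.diff(tail) <= 1e-15)

    def test_oblique_core_is_elongated_along_x(self):
        beam = make_beam_profile(grid_shape=(129, 129))
        yy = (np.arange(129) - 64) * PS
        var_x = (beam.weights * yy[None, :] ** 2).sum()
        var_y = (beam.weights * yy[:, None] ** 2).sum()
        assert var_x > 1.05 * var_y


class TestRenderFrame:
    def test_linearity_in_exposure(self):
        cam = CameraModel(read_noise_sd=0.0, dark_offset=0.0)
        truth = np.full((33, 33), 0.2)  # well below saturation at 10x
        a = render_frame(truth, 5.0, 2.0, cam, seed=1)
        b = render_frame(truth, 50.0, 2.0, cam, seed=2)
        ratio = b.counts.mean() / a.counts.mean()
        assert ratio == pytest.approx(10.0, rel=0.02)

    def test_seed_reproducibility(self):
        cam = CameraModel()
        truth = np.random.default_rng(0).random((33, 33))
        f1 = render_frame(truth, 10.0, 2.0, cam, seed=5)
        f2 = render_frame(truth, 10.0, 2.0, cam, seed=5)
        np.testing.assert_array_equal(f1.counts, f2.counts)

    def test_noiseless_render_is_exact_expectation(self):
        cam = CameraModel(read_noise_sd=0.0, dark_offset=7.0)
        truth = np.full((17, 17), 3.0)
        f = render_frame(truth, 4.0, 2.0, cam, seed=0, noise=False)
        np.testing.assert_allclose(f.counts,
                                   3.0 * cam.gain * 4.0 * 2.0 + 7.0)

    def test_saturated_region_blooms_and_is_detected(self):
        cam = CameraModel(read_noise_sd=2.0, dark_offset=100.0)
        truth = np.zeros((65, 65))
        truth[30:35, 30:35] = 1.0
        t_sat = 5 * FULL_SCALE / (cam.gain * 2.0)  # drive the core 5x over
        frame = render_frame(truth, t_sat, 2.0, cam, seed=8)
        spilled = (frame.counts >= FULL_SCALE - 1)
        assert spilled.sum() > 5 * 5  # streaks beyond the driven square
        mask = detect_bloom(frame)
        assert mask[spilled].mean() >= 0.95


class TestBloomSpill:
    def test_charge_conserved_away_from_edges(self):
        charge = np.full((64, 8), 100.0)
        charge[30:34, 3] = 3e5
        out = _bloom_spill(charge, FULL_SCALE, 0.5)
        assert out.sum() == pytest.approx(charge.sum(), rel=1e-9)
        assert out.max() <= FULL_SCALE

    def test_overflow_beyond_column_capacity_is_clipped_at_edges(self):
        charge = np.full((16, 4), 0.0)
        charge[8, 1] = 16 * FULL_SCALE * 2.0
        out = _bloom_spill(charge, FULL_SCALE, 0.5)
        np.testing.assert_allclose(out[:, 1], FULL_SCALE)


class TestAutoExposure:
    def test_doubling_gain_halves_integration_time(self):
        truth = np.full((9, 9), 1.7)
        t1 = auto_exposure(truth, CameraModel(gain=1000.0), 2.0)
        t2 = auto_exposure(truth, CameraModel(gain=2000.0), 2.0)
        assert t1 == pytest.approx(2 * t2, rel=1e-12)

    def test_rendered_peak_hits_the_target(self):
        cam = CameraModel(read_noise_sd=0.0, dark_offset=0.0)
        rng = np.random.default_rng(2)
        truth = rng.random((33, 33)) * 5.0
        t = auto_exposure(truth, cam, 2.0)
        frame = render_frame(truth, t, 2.0, cam, seed=3, noise=False)
        assert frame.counts.max() == pytest.approx(30_000, rel=1e-9)

    def test_target_above_full_well_warns(self):
        with pytest.warns(UserWarning):
            auto_exposure(np.ones((4, 4)), CameraModel(), 2.0,
                          target_max=70_000)


class TestTripletClosure:
    def test_noise_free_pipeline_reproduces_truth(self):
        """Render -> patch -> normalize closes on the input field."""
        yy, xx = np.mgrid[0:129, 0:129]
        rho = np.hypot(yy - 64, xx - 64) * PS
        truth = 50.0 * 10.0 ** (-2.0 * rho)   # ~4.6 decades across the grid
        cam = CameraModel(read_noise_sd=0.0, dark_offset=50.0)
        rng = np.random.default_rng(11)
        flat = default_flat_field((129, 129))
        frames = render_exposure_triplet(truth, cam, 2.0, rng,
                                         flat_field=flat, noise=False)
        subtracted = [f.replace_counts(f.counts - cam.dark_offset,
                                       dark_subtracted=True) for f in frames]
        patched = patch_exposure_series(subtracted, (64, 64), PS, flat=flat)
        # normalized units still carry the camera gain; divide it out
        curve = radial_bin(patched.values / cam.gain, (64, 64), PS, PS)
        truth_curve = radial_bin(truth / (PS * PS), (64, 64), PS, PS)
        lo = truth_curve.values >= truth.max() / (PS * PS) * 1e-4
        good = np.isfinite(curve.values) & lo
        rel = np.abs(curve.values[good] - truth_curve.values[good]) \
            / truth_curve.values[good]
        assert np.max(rel) <= 1e-3

    def test_noisy_triplet_recovers_profile_over_four_decades(self):
        yy, xx = np.mgrid[0:129, 0:129]
        rho = np.hypot(yy - 64, xx - 64) * PS
        truth = 10.0 ** (-2.0 * rho)
        cam = CameraModel(read_noise_sd=3.0, dark_offset=100.0)
        rng = np.random.default_rng(21)
        frames = render_exposure_triplet(truth, cam, 2.0, rng, noise=True)
        subtracted = [f.replace_counts(f.counts.astype(float)
                                       - cam.dark_offset,
                                       dark_subtracted=True) for f in frames]
        patched = patch_exposure_series(subtracted, (64, 64), PS)
        curve = radial_bin(patched.values / cam.gain, (64, 64), PS, PS)
        truth_curve = radial_bin(truth / (PS * PS), (64, 64), PS, PS)
        t1 = frames[0].t_int
        # bins whose expected 100x counts clear 100: shot noise under ~10%
        expected_counts = truth_curve.values * (PS * PS) * cam.gain \
            * t1 * 100 * 2.0
        sel = (np.isfinite(curve.values) & (expected_counts >= 100)
               & (truth_curve.values >= truth.max() / (PS * PS) * 1e-4))
        rel = np.abs(curve.values[sel] - truth_curve.values[sel]) \
            / truth_curve.values[sel]
        assert np.max(rel) <= 0.05


class TestScenarioGeneration:
    def test_round_trips_and_reproducibility(self, tmp_path):
        from srrkit import io as srrio
        from srrkit.synthetic import generate_scenario

        scenario = SyntheticScenario(
            samples={"demo": (0.05, 1.5)}, wavelengths=(660.0,),
            grid_half=32, n_photons=5_000, seed=99)
        m1 = generate_scenario(scenario, tmp_path / "a")
        m2 = generate_scenario(scenario, tmp_path / "b")
        assert m1["samples"] == {k: v for k, v in m2["samples"].items()}
        f1 = srrio.load_camera_frame(tmp_path / "a/demo_660nm/frame_10x.tiff")
        f2 = srrio.load_camera_frame(tmp_path / "b/demo_660nm/frame_10x.tiff")
        np.testing.assert_array_equal(f1.counts, f2.counts)
        assert f1.t_int == f2.t_int and f1.exposure_tag == "10x"
        truth, meta = srrio.load_reflectance_image(
            tmp_path / "a/demo_660nm/truth.tiff")
        assert meta["n_launched"] == 5_000
        assert truth.shape == (65, 65)
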