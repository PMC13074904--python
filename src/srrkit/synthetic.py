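"""Synthetic SRR instrument: beam profiles and 16-bit camera frame rendering.

This module emulates the measurement chain of the imaging system — an
oblique focused beam with a faint instrument-response halo, a cooled 16-bit
CCD with shot noise, read noise, dark offset, saturation and columnar
blooming, a monitor photodiode with slow drift, and the 1x/10x/100x
exposure-triplet protocol — so the entire processing and inversion pipeline
can be exercised and validated without hardware.  True camera constants of
any particular instrument are not published; the defaults here are chosen to
reproduce the operating regime (auto-exposure to a 30,000-count peak on a
16-bit sensor).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .montecarlo import BeamProfile, SimulationConfig, simulate_srr_image
from .optics import OpticalProperties, SampleGeometry
from .pipeline import FULL_SCALE, CameraFrame

__all__ = [
    "CameraModel",
    "SyntheticScenario",
    "make_beam_profile",
    "render_frame",
    "auto_exposure",
    "generate_scenario",
]

#: instrument pixel scale, mm per pixel
PIXEL_SCALE = 0.0361
#: nominal focused beam radius, mm
BEAM_RADIUS = 0.27
#: beam incidence angle from the surface normal, degrees
INCIDENCE_ANGLE_DEG = 21.0
#: auto-exposure peak target, counts
AUTO_EXPOSURE_TARGET = 30_000


@dataclass(frozen=True)
class CameraModel:
    """Response model of the synthetic CCD.

    ``gain`` converts reflectance-rate units (mm^-2 * ms * V) to counts.
    Blooming spills the charge in excess of ``full_well`` along the readout
    axis; ``bloom_spill_fraction`` of the excess travels toward higher row
    indices, the rest toward lower ones.
    """

    gain: float = 1000.0
    read_noise_sd: float = 5.0
    dark_offset: float = 100.0
    full_well: int = FULL_SCALE
    bloom_axis: str = "col"
    bloom_spill_fraction: float = 0.5
    psf_width: float = 0.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError("gain must be > 0")
        if not (0.0 <= self.bloom_spill_fraction < 1.0):
            raise ValueError("bloom_spill_fraction must lie in [0, 1)")
        if self.bloom_axis not in ("row", "col"):
            raise ValueError("bloom_axis must be 'row' or 'col'")


@dataclass
class SyntheticScenario:
    """A reproducible synthetic measurement campaign.

    ``samples`` maps a sample id to its true optical properties (mu_a and
    mu_s' in mm^-1); one wavelength per entry keeps desk-scale runs small,
    and multi-wavelength campaigns simply list more entries.
    """

    samples: dict
    wavelengths: tuple = (660.0,)
    camera: CameraModel = field(default_factory=CameraModel)
    grid_half: int = 128
    pixel_scale: float = PIXEL_SCALE
    n_photons: int = 200_000
    seed: int = 0
    pd_voltage: float = 2.0
    thickness: float = 55.5
    kill_radius: float = 30.0


# --------------------------------------------------------------------------
# Beam profile
# --------------------------------------------------------------------------

def make_beam_profile(rho_r: float = BEAM_RADIUS,
                      grid_shape: tuple[int, int] = (257, 257),
                      pixel_scale: float = PIXEL_SCALE,
                      origin: tuple[int, int] | None = None,
                      incidence_angle_deg: float = INCIDENCE_ANGLE_DEG,
                      halo_amplitude: float = 1e-3,
                      halo_exponent: float = 3.5,
                      speckle_contrast: float = 0.0,
                      speckle_scale_px: float = 1.5,
                      seed: int = 0) -> BeamProfile:
    """Synthetic incident beam: oblique near-top-hat core plus a faint halo.

    The core is a super-Gaussian of radius ``rho_r``, elongated along the
    incidence plane (+x) by 1/cos of the incidence angle; the halo is a
    power-law tail standing in for the instrument response (point spread
    contributions), spanning several decades as a measured, exposure-patched
    profile does.  The profile is normalized to unit sum.

    ``speckle_contrast`` overlays multiplicative granular structure
    (correlation length ``speckle_scale_px`` pixels, deterministic in
    ``seed``): a profile measured off a granular diffuse reflector is not
    smooth, and that shared fine structure is what makes reflectance fits
    sensitive to the alignment between the measured image and the model.
    The default is a smooth profile.
    """
    if not rho_r > 0:
        raise ValueError("rho_r must be > 0")
    if origin is None:
        origin = (grid_shape[0] // 2, grid_shape[1] // 2)
    yy = (np.arange(grid_shape[0]) - origin[0]) * pixel_scale
    xx = (np.arange(grid_shape[1]) - origin[1]) * pixel_scale
    stretch = 1.0 / math.cos(math.radians(incidence_angle_deg))
    r_ell = np.hypot(yy[:, None], xx[None, :] / stretch)
    core = np.exp(-((r_ell / rho_r) ** 8))
    halo = halo_amplitude * (1.0 + (r_ell / rho_r) ** 2) ** (-halo_exponent / 2.0)
    weights = core + halo
    if speckle_contrast > 0:
        rng = np.random.default_rng(seed)
        field = ndimage.gaussian_filter(
            rng.standard_normal(grid_shape), speckle_scale_px)
        field /= field.std()
        weights = weights * np.clip(1.0 + speckle_contrast * field, 0.05,
                                    None)
    weights /= weights.sum()
    return BeamProfile(weights, pixel_scale, origin, incidence_angle_deg, rho_r)


# --------------------------------------------------------------------------
# Camera rendering
# --------------------------------------------------------------------------

def _bloom_spill(charge: np.ndarray, full_well: float,
                 down_fraction: float) -> np.ndarray:
    """Redistribute charge above the full well along columns (sandpile model).

    Each over-full column's excess is split into a down-travelling and an
    up-travelling packet which top up neighbouring pixels to the full well,
    marching away from the saturated run; charge pushed past the frame edge
    is lost (as on a real sensor).  Charge is conserved elsewhere.
    """
    out = charge.copy()
    over_cols = np.nonzero((out > full_well).any(axis=0))[0]
    for c in over_cols:
        col = out[:, c]
        over = np.nonzero(col > full_well)[0]
        excess = float((col[over] - full_well).sum())
        col[over] = full_well
        lo, hi = int(over.min()), int(over.max())
        down = excess * down_fraction
        up = excess - down
        i = hi + 1
        while down > 0 and i < col.size:
            room = full_well - col[i]
            fill = min(room, down)
            col[i] += fill
            down -= fill
            i += 1
        i = lo - 1
        while up > 0 and i >= 0:
            room = full_well - col[i]
            fill = min(room, up)
            col[i] += fill
            up -= fill
            i -= 1
        out[:, c] = col
    return out


def render_frame(truth: np.ndarray, t_int: float, pd_voltage: float,
                 cam: CameraModel, seed: int,
                 flat_field: np.ndarray | None = None,
                 wavelength: float | None = None,
                 noise: bool = True,
                 exposure_tag: str | None = None) -> CameraFrame:
    """Render a camera frame from a true reflectance field (mm^-2 scale).

    Expected photo-charge is ``truth * gain * t_int * pd_voltage``,
    optionally multiplied by a flat-field map and blurred by a Gaussian PSF.
    With ``noise`` the charge is Poisson-sampled, read noise and the dark
    offset are added, blooming spills saturated charge along the readout
    axis, and the result is clipped and quantized to integers.  With
    ``noise=False`` the noiseless, unquantized expectation is returned
    (useful for closure checks); saturation and bloom still apply.
    """
    truth = np.asarray(truth, dtype=float)
    if np.any(truth < 0):
        raise ValueError("truth field must be non-negative")
    expected = truth * cam.gain * t_int * pd_voltage
    if cam.psf_width > 0:
        # psf_width is in mm; the grid is assumed at the instrument pixel scale
        expected = ndimage.gaussian_filter(expected, cam.psf_width / PIXEL_SCALE)
    if flat_field is not None:
        expected = expected * np.asarray(flat_field, dtype=float)
    rng = np.random.default_rng(seed)
    if noise:
        charge = rng.poisson(expected).astype(float)
        charge += cam.dark_offset
        charge += rng.normal(0.0, cam.read_noise_sd, charge.shape)
        charge = np.clip(charge, 0.0, None)
    else:
        charge = expected + cam.dark_offset
    if cam.bloom_axis == "row":
        charge = _bloom_spill(charge.T, cam.full_well,
                              cam.bloom_spill_fraction).T
    else:
        charge = _bloom_spill(charge, cam.full_well, cam.bloom_spill_fraction)
    charge = np.clip(charge, 0.0, cam.full_well)
    counts = np.rint(charge).astype(np.uint16) if noise else charge
    return CameraFrame(counts, t_int, pd_voltage, wavelength,
                       dark_subtracted=False, exposure_tag=exposure_tag)


def auto_exposure(truth: np.ndarray, cam: CameraModel, pd_voltage: float,
                  target_max: float = AUTO_EXPOSURE_TARGET) -> float:
    """Integration time (ms) putting the expected peak at ``target_max`` counts."""
    truth = np.asarray(truth, dtype=float)
    peak = float(truth.max())
    if not peak > 0:
        raise ValueError("truth field has no positive values")
    if target_max > cam.full_well:
        warnings.warn("auto-exposure target exceeds the full well",
                      stacklevel=2)
    return target_max / (peak * cam.gain * pd_voltage)


# --------------------------------------------------------------------------
# Scenario generation
# --------------------------------------------------------------------------

def _pd_voltage_draw(base: float, rng: np.random.Generator) -> float:
    """Mean monitor voltage over an acquisition with ~1% slow drift."""
    phase = rng.uniform(0.0, 2.0 * math.pi)
    t = np.linspace(0.0, 1.0, 64)
    trace = base * (1.0 + 0.01 * np.sin(2.0 * math.pi * t + phase))
    return float(trace.mean())


def simulate_truth(props: OpticalProperties, scenario: SyntheticScenario,
                   beam: BeamProfile, seed: int):
    """Forward-model reflectance truth for one sample of a scenario."""
    geom = SampleGeometry(thickness_d=scenario.thickness)
    cfg = SimulationConfig(n_photons=scenario.n_photons, seed=seed,
                           kill_radius=scenario.kill_radius)
    image, stats = simulate_srr_image(props, geom, beam, cfg)
    return image, stats


def render_exposure_triplet(truth_values: np.ndarray, cam: CameraModel,
                            pd_voltage: float, rng: np.random.Generator,
                            flat_field: np.ndarray | None = None,
                            wavelength: float | None = None,
                            noise: bool = True) -> list[CameraFrame]:
    """Auto-exposed 1x plus 10x and 100x frames of one truth field."""
    t1 = auto_exposure(truth_values, cam, pd_voltage)
    frames = []
    for mult, tag in ((1, "1x"), (10, "10x"), (100, "100x")):
        volts = _pd_voltage_draw(pd_voltage, rng) if noise else pd_voltage
        frames.append(render_frame(
            truth_values, t1 * mult, volts, cam,
            seed=int(rng.integers(0, 2**31 - 1)), flat_field=flat_field,
            wavelength=wavelength, noise=noise, exposure_tag=tag))
    return frames


def default_flat_field(shape: tuple[int, int], amplitude: float = 0.05,
                       ) -> np.ndarray:
    """Smooth mean-one gain map with the stated border-to-center variation."""
    yy = np.linspace(-1.0, 1.0, shape[0])
    xx = np.linspace(-1.0, 1.0, shape[1])
    bowl = 1.0 - amplitude * 0.5 * (yy[:, None] ** 2 + xx[None, :] ** 2)
    return bowl / bowl.mean()


def generate_scenario(scenario: SyntheticScenario, out_dir) -> dict:
    """Render a full synthetic campaign to disk.

    For every (sample, wavelength): the Monte Carlo truth image, an
    auto-exposed 1x/10x/100x frame triplet with darks, the flat-field map,
    the beam profile, and a ground-truth JSON.  Returns the manifest.
    All randomness derives from ``scenario.seed``.
    """
    from . import io as srrio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = 2 * scenario.grid_half + 1
    origin = (scenario.grid_half, scenario.grid_half)
    beam = make_beam_profile(grid_shape=(n, n), pixel_scale=scenario.pixel_scale,
                             origin=origin)
    flat = default_flat_field((n, n))
    srrio.save_reflectance_image(out / "beam_profile.tiff",
                                 beam.weights, scenario.pixel_scale, origin,
                                 meta={"kind": "beam_profile",
                                       "incidence_angle_deg": beam.incidence_angle_deg,
                                       "beam_radius_mm": beam.beam_radius})
    np.savetxt(out / "flat_field.csv", flat, delimiter=",")
    manifest = {"seed": scenario.seed, "pixel_scale_mm": scenario.pixel_scale,
                "origin": list(origin), "samples": {}}
    rng = np.random.default_rng(scenario.seed)
    for sample_id, (mu_a, mu_sp) in scenario.samples.items():
        for wl in scenario.wavelengths:
            props = OpticalProperties(mu_a=mu_a, mu_s_prime=mu_sp,
                                      wavelength=wl)
            sim_seed = int(rng.integers(0, 2**31 - 1))
            truth_img, _ = simulate_truth(props, scenario, beam, sim_seed)
            frames = render_exposure_triplet(
                truth_img.values, scenario.camera, scenario.pd_voltage, rng,
                flat_field=flat, wavelength=wl)
            tag_dir = out / f"{sample_id}_{int(wl)}nm"
            tag_dir.mkdir(exist_ok=True)
            srrio.save_reflectance_image(
                tag_dir / "truth.tiff", truth_img.values,
                scenario.pixel_scale, origin,
                meta={"n_launched": truth_img.n_launched, "seed": sim_seed})
            for frame in frames:
                srrio.save_camera_frame(
                    tag_dir / f"frame_{frame.exposure_tag}.tiff", frame)
            dark = np.rint(np.clip(
                scenario.camera.dark_offset
                + rng.normal(0.0, scenario.camera.read_noise_sd, (n, n)),
                0, FULL_SCALE)).astype(np.uint16)
            srrio.save_camera_frame(
                tag_dir / "frame_dark.tiff",
                CameraFrame(dark, frames[0].t_int, scenario.pd_voltage, wl,
                            exposure_tag="dark"))
            manifest["samples"][f"{sample_id}_{int(wl)}nm"] = {
                "sample_id": sample_id, "wavelength_nm": wl,
                "mu_a": mu_a, "mu_s_prime": mu_sp,
                "g": props.g, "n": props.n, "seed": sim_seed,
            }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
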