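"""Photon-transport Monte Carlo for a homogeneous turbid slab.

The forward model produces the 2D surface-exit reflectance image observed by
a spatially resolved reflectance (SRR) imaging system: photons are launched
at the sample surface — either from a measured/synthetic 2D beam profile or
as a pencil beam — refracted by Snell's law for the oblique incidence,
propagated with free paths drawn from the scattering coefficient mu_s,
deflected by Henyey-Greenstein sampling, and subjected to unpolarized
Fresnel reflect/refract decisions at the top interface.  A photon that
refracts out through the top surface deposits its weight at the surface
pixel where it exits; no solid angle of detection is applied.

Absorption is handled as a terminal weight factor ``exp(-mu_a * L)`` over the
total path length L, with free paths drawn from mu_s alone.  This choice is
equivalent in expectation to albedo weighting per collision, reduces
variance, and makes the stored per-photon sufficient statistics
(collision count j, path length L) an exact basis for perturbation Monte
Carlo rescaling (see :mod:`srrkit.pmc`).

A diffusion-dipole closed form (extrapolated boundary, index-mismatch
boundary coefficients computed from Fresnel integrals) is provided as an
independent oracle for the diffusive regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numba import njit
from scipy import integrate, signal

from .optics import OpticalProperties, SampleGeometry, snell_refract

__all__ = [
    "BeamProfile",
    "ReflectanceImage",
    "PathStatistics",
    "SimulationConfig",
    "simulate_srr_image",
    "simulate_pencil_image",
    "convolve_with_beam",
    "diffusion_reflectance",
    "bin_exits_to_image",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class BeamProfile:
    """2D launch distribution of the incident beam on the sample surface.

    ``weights`` are arbitrary non-negative units (they are normalized
    internally); ``origin`` is the (row, col) pixel of beam incidence, which
    is also the origin used for radial binning.  ``incidence_angle_deg`` is
    measured from the surface normal in air; the incidence plane is fixed
    along the +x (column) axis of the grid.
    """

    weights: np.ndarray
    pixel_scale: float
    origin: tuple[int, int]
    incidence_angle_deg: float = 21.0
    beam_radius: float = 0.27

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("beam weights must be a 2D array")
        if np.any(self.weights < 0):
            raise ValueError("beam weights must be non-negative")
        if not np.any(self.weights > 0):
            raise ValueError("beam profile has zero total weight")
        r, c = self.origin
        if not (0 <= r < self.weights.shape[0] and 0 <= c < self.weights.shape[1]):
            raise ValueError("beam origin lies outside the grid")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape


@dataclass
class ReflectanceImage:
    """Surface-exit density in mm^-2 per launched photon on a pixel grid."""

    values: np.ndarray
    pixel_scale: float
    origin: tuple[int, int]
    n_launched: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("reflectance values must be a 2D array")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be > 0")

    @property
    def total_reflectance(self) -> float:
        """Integral of the image: fraction of launched weight seen on the grid."""
        return float(self.values.sum() * self.pixel_scale**2)


@dataclass
class PathStatistics:
    """Per detected photon: exit pixel, weight, collision count j, path length L.

    These are the sufficient statistics for perturbation-MC rescaling under
    the absorption-as-terminal-weight transport scheme.  ``row``/``col`` may
    lie outside the image grid for photons exiting beyond it; such photons
    count toward the energy budget but not toward the binned image.

    ``energy_budget`` decomposes the launched unit weight per photon into
    detected (top), transmitted (bottom), absorbed, net roulette kill and
    truncation, and closes to 1 up to floating rounding.
    """

    row: np.ndarray
    col: np.ndarray
    weight: np.ndarray
    n_collisions: np.ndarray
    path_length: np.ndarray
    n_launched: int
    energy_budget: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.weight.size


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo run controls.

    ``roulette_threshold``/``roulette_survival`` govern the unbiased Russian
    roulette applied once the running attenuation weight drops below the
    threshold; ``max_path_events`` caps the number of propagation events per
    photon (relevant only for non-absorbing, index-matched corner cases).
    ``kill_radius`` terminates photons that stray laterally beyond the given
    radius in mm (0 disables it); the sample vessel wall provides a physical
    counterpart, and any truncation is shared identically by every curve a
    fit compares, so it cancels in the inversion.
    """

    n_photons: int = 100_000
    seed: int = 0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    max_path_events: int = 1_000_000
    kill_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not (0.0 < self.roulette_survival < 1.0):
            raise ValueError("roulette_survival must lie in (0, 1)")
        if self.roulette_threshold < 0:
            raise ValueError("roulette_threshold must be >= 0")


# --------------------------------------------------------------------------
# Compiled transport kernel
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _fresnel_internal(n_rel: float, cos_i: float) -> float:
    """Unpolarized Fresnel reflectance, medium (index n_rel) -> air (1)."""
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = n_rel * n_rel * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True, inline="always")
def _xs128p(s0: np.uint64, s1: np.uint64):
    """One xorshift128+ step: returns (new_s0, new_s1, uint64 output)."""
    x = s0
    y = s1
    x = np.uint64(x ^ np.uint64(x << np.uint64(23)))
    new_s1 = np.uint64(x ^ y ^ np.uint64(x >> np.uint64(17)) ^ np.uint64(y >> np.uint64(26)))
    return y, new_s1, np.uint64(new_s1 + y)


@njit(cache=True, fastmath=True, inline="always")
def _splitmix64(state: np.uint64) -> np.uint64:
    state = np.uint64(state + np.uint64(0x9E3779B97F4A7C15))
    z = state
    z = np.uint64((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9))
    z = np.uint64((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB))
    return np.uint64(z ^ (z >> np.uint64(31)))


@njit(cache=True, fastmath=True)
def _transport(seed, x0, y0, ux0, uy0, uz0, mu_s, mu_a, n_rel, g, thickness,
               roulette_threshold, roulette_survival, max_events, kill_radius):
    """Sequential photon transport; deterministic for a fixed seed.

    Returns exit coordinates/weights/collision counts/path lengths of photons
    refracting out through the top surface, plus the energy budget
    ``(detected_top, detected_bottom, absorbed, roulette_net, truncated,
    lateral)``.  The running attenuated weight ``boost * exp(-mu_a * L)`` is
    never evaluated per collision: the roulette trigger is expressed as a
    path-length threshold and absorption bookkeeping is settled once per
    photon at termination.  Uniform variates come from an inline
    xorshift128+ generator; the azimuth of each deflection is drawn by
    Marsaglia's polar method, avoiding sin/cos calls.  Every photon gets its
    own counter-based stream (SplitMix64 of seed and photon index), so a
    perturbed parameter that alters one photon's event sequence cannot
    desynchronize the others — the property that makes common random
    numbers effective across parameter values.
    """
    inv53 = 1.0 / 9007199254740992.0
    seed64 = np.uint64(seed)
    n = x0.size
    exit_x = np.empty(n)
    exit_y = np.empty(n)
    exit_w = np.empty(n)
    exit_j = np.empty(n, dtype=np.int64)
    exit_len = np.empty(n)
    n_exit = 0
    detected_top = 0.0
    detected_bottom = 0.0
    absorbed = 0.0
    roulette_net = 0.0
    truncated = 0.0
    lateral = 0.0

    log_thresh = math.log(roulette_threshold) if roulette_threshold > 0.0 else -1e30
    log_boost_step = -math.log(roulette_survival)
    kill_r2 = kill_radius * kill_radius if kill_radius > 0.0 else 1e30

    for i in range(n):
        # per-photon stream: counter-based seeding
        s0 = _splitmix64(np.uint64(seed64 ^ np.uint64(np.uint64(i + 1) * np.uint64(0x9E3779B97F4A7C15))))
        s1 = _splitmix64(s0)
        x = x0[i]
        y = y0[i]
        z = 0.0
        ux = ux0
        uy = uy0
        uz = uz0
        boost = 1.0
        gains = 0.0
        path_len = 0.0
        # roulette fires when mu_a * L - log(boost) > -log(threshold)
        roulette_len = -log_thresh / mu_a if mu_a > 0.0 else 1e30
        j = 0
        events = 0
        terminal = -1  # 0 top, 1 bottom, 2 roulette kill, 3 truncated, 4 lateral

        while True:
            events += 1
            if events > max_events:
                terminal = 3
                break
            if mu_s > 0.0:
                s0, s1, rv = _xs128p(s0, s1)
                u = (rv >> np.uint64(11)) * inv53
                while u <= 0.0:
                    s0, s1, rv = _xs128p(s0, s1)
                    u = (rv >> np.uint64(11)) * inv53
                step = -math.log(u) / mu_s
            else:
                step = 1e30
            if uz < 0.0:
                d_bound = -z / uz
            elif uz > 0.0:
                d_bound = (thickness - z) / uz
            else:
                d_bound = 1e30

            if step < d_bound:
                # collision inside the medium
                x += step * ux
                y += step * uy
                z += step * uz
                path_len += step
                j += 1
                if x * x + y * y > kill_r2:
                    terminal = 4
                    break
                # HG deflection + uniform azimuth
                s0, s1, rv = _xs128p(s0, s1)
                uu = (rv >> np.uint64(11)) * inv53
                if g != 0.0:
                    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * uu)
                    cos_t = (1.0 + g * g - frac * frac) / (2.0 * g)
                    if cos_t > 1.0:
                        cos_t = 1.0
                    elif cos_t < -1.0:
                        cos_t = -1.0
                else:
                    cos_t = 2.0 * uu - 1.0
                sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
                # Marsaglia polar draw of (cos_p, sin_p)
                while True:
                    s0, s1, rv = _xs128p(s0, s1)
                    v1 = 2.0 * ((rv >> np.uint64(11)) * inv53) - 1.0
                    s0, s1, rv = _xs128p(s0, s1)
                    v2 = 2.0 * ((rv >> np.uint64(11)) * inv53) - 1.0
                    ssum = v1 * v1 + v2 * v2
                    if 0.0 < ssum < 1.0:
                        break
                cos_p = (v1 * v1 - v2 * v2) / ssum
                sin_p = 2.0 * v1 * v2 / ssum
                if abs(uz) > 0.99999:
                    ux = sin_t * cos_p
                    uy = sin_t * sin_p
                    uz = cos_t * (1.0 if uz >= 0.0 else -1.0)
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    nux = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
                    nuy = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
                    nuz = -sin_t * cos_p * den + uz * cos_t
                    norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                    ux = nux / norm
                    uy = nuy / norm
                    uz = nuz / norm
                # Russian roulette once the attenuated weight is below threshold
                if path_len > roulette_len:
                    w_now = boost * math.exp(-mu_a * path_len)
                    s0, s1, rv = _xs128p(s0, s1)
                    if (rv >> np.uint64(11)) * inv53 < roulette_survival:
                        boost /= roulette_survival
                        gains += w_now * (1.0 / roulette_survival - 1.0)
                        roulette_len += log_boost_step / mu_a
                    else:
                        terminal = 2
                        break
            else:
                # boundary crossing
                x += d_bound * ux
                y += d_bound * uy
                path_len += d_bound
                if uz > 0.0:
                    # bottom boundary: matched-index escape, counted and discarded
                    terminal = 1
                    break
                z = 0.0
                cos_i = -uz
                if n_rel == 1.0:
                    refl = 0.0
                else:
                    refl = _fresnel_internal(n_rel, cos_i)
                s0, s1, rv = _xs128p(s0, s1)
                if (rv >> np.uint64(11)) * inv53 >= refl:
                    terminal = 0
                    break
                uz = -uz

        w_term = boost * math.exp(-mu_a * path_len)
        absorbed += 1.0 + gains - w_term
        roulette_net -= gains
        if terminal == 0:
            detected_top += w_term
            exit_x[n_exit] = x
            exit_y[n_exit] = y
            exit_w[n_exit] = w_term
            exit_j[n_exit] = j
            exit_len[n_exit] = path_len
            n_exit += 1
        elif terminal == 1:
            detected_bottom += w_term
        elif terminal == 2:
            roulette_net += w_term
        elif terminal == 3:
            truncated += w_term
        else:
            lateral += w_term

    return (exit_x[:n_exit], exit_y[:n_exit], exit_w[:n_exit],
            exit_j[:n_exit], exit_len[:n_exit],
            detected_top, detected_bottom, absorbed, roulette_net, truncated,
            lateral)


# --------------------------------------------------------------------------
# Launch helpers and public API
# --------------------------------------------------------------------------

def _derive_seeds(seed: int) -> tuple[np.random.Generator, int]:
    """One generator for launch sampling + one 31-bit seed for the kernel."""
    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    return rng, kernel_seed


def _validate_props(props: OpticalProperties) -> None:
    if props.mu_s < 0 or not math.isfinite(props.mu_s):
        raise ValueError("non-physical scattering coefficient")


def _launch_direction(incidence_angle_deg: float, n_medium: float) -> tuple[float, float, float]:
    theta_i = math.radians(incidence_angle_deg)
    theta_t, tir = snell_refract(theta_i, 1.0, n_medium)
    if tir:  # cannot happen going into the denser medium, guard anyway
        raise ValueError("incident beam is totally reflected")
    return math.sin(theta_t), 0.0, math.cos(theta_t)


def bin_exits_to_image(rows, cols, weights, shape, pixel_scale, origin,
                       n_launched) -> ReflectanceImage:
    """Accumulate per-photon exit weights into a normalized ReflectanceImage."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    weights = np.asarray(weights, dtype=float)
    inside = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    lin = rows[inside] * shape[1] + cols[inside]
    img = np.bincount(lin, weights=weights[inside], minlength=shape[0] * shape[1])
    img = img.reshape(shape) / (n_launched * pixel_scale**2)
    return ReflectanceImage(img, pixel_scale, origin, n_launched)


def _run(props: OpticalProperties, geom: SampleGeometry, cfg: SimulationConfig,
         x0: np.ndarray, y0: np.ndarray, incidence_angle_deg: float,
         shape: tuple[int, int], pixel_scale: float, origin: tuple[int, int],
         kernel_seed: int) -> tuple[ReflectanceImage, PathStatistics]:
    _validate_props(props)
    ux0, uy0, uz0 = _launch_direction(incidence_angle_deg, props.n)
    out = _transport(kernel_seed, x0, y0, ux0, uy0, uz0,
                     props.mu_s, props.mu_a, props.n, props.g,
                     geom.thickness_d, cfg.roulette_threshold,
                     cfg.roulette_survival, cfg.max_path_events,
                     cfg.kill_radius)
    (ex, ey, ew, ej, el, det_top, det_bot, absorbed, roulette_net, truncated,
     lateral) = out
    # pixel-center convention: pixel (r, c) spans centers at offsets*pixel_scale
    rows = origin[0] + np.floor(ey / pixel_scale + 0.5).astype(np.int64)
    cols = origin[1] + np.floor(ex / pixel_scale + 0.5).astype(np.int64)
    budget = {
        "detected_top": det_top / cfg.n_photons,
        "detected_bottom": det_bot / cfg.n_photons,
        "absorbed": absorbed / cfg.n_photons,
        "roulette_net": roulette_net / cfg.n_photons,
        "truncated": truncated / cfg.n_photons,
        "lateral": lateral / cfg.n_photons,
    }
    stats = PathStatistics(rows, cols, ew, ej, el, cfg.n_photons, budget)
    image = bin_exits_to_image(rows, cols, ew, shape, pixel_scale, origin,
                               cfg.n_photons)
    return image, stats


def simulate_srr_image(props: OpticalProperties, geom: SampleGeometry,
                       beam: BeamProfile, cfg: SimulationConfig,
                       ) -> tuple[ReflectanceImage, PathStatistics]:
    """Simulate the SRR surface-exit image with the integrated beam profile.

    Launch positions are drawn from the beam-profile pixel weights, jittered
    uniformly within the selected pixel; the launch direction is the Snell
    refraction of the oblique incidence angle.  The detector grid coincides
    with the beam grid.  A fixed ``cfg.seed`` reproduces the image bit-exactly.
    """
    rng, kernel_seed = _derive_seeds(cfg.seed)
    h, w = beam.shape
    p = beam.weights.ravel() / beam.weights.sum()
    idx = rng.choice(h * w, size=cfg.n_photons, p=p)
    rr, cc = np.divmod(idx, w)
    # jitter within the pixel; positions in mm relative to the origin pixel center
    x0 = (cc - beam.origin[1] + rng.uniform(-0.5, 0.5, cfg.n_photons)) * beam.pixel_scale
    y0 = (rr - beam.origin[0] + rng.uniform(-0.5, 0.5, cfg.n_photons)) * beam.pixel_scale
    return _run(props, geom, cfg, x0, y0, beam.incidence_angle_deg,
                beam.shape, beam.pixel_scale, beam.origin, kernel_seed)


def simulate_pencil_image(props: OpticalProperties, geom: SampleGeometry,
                          cfg: SimulationConfig, shape: tuple[int, int],
                          pixel_scale: float, origin: tuple[int, int],
                          incidence_angle_deg: float = 21.0,
                          ) -> tuple[ReflectanceImage, PathStatistics]:
    """Pencil-beam variant: all photons enter at the origin pixel center."""
    _, kernel_seed = _derive_seeds(cfg.seed)
    x0 = np.zeros(cfg.n_photons)
    y0 = np.zeros(cfg.n_photons)
    return _run(props, geom, cfg, x0, y0, incidence_angle_deg,
                shape, pixel_scale, origin, kernel_seed)


def convolve_with_beam(pencil_image: ReflectanceImage,
                       beam: BeamProfile) -> ReflectanceImage:
    """Convolve a pencil-beam image with a (normalized) beam profile.

    Equivalent in expectation to simulating with the integrated beam profile;
    the result is cropped to the original grid with the origin preserved.
    """
    if pencil_image.values.shape != beam.shape:
        raise ValueError("pencil image and beam profile grids do not match")
    if abs(pencil_image.pixel_scale - beam.pixel_scale) > 1e-12:
        raise ValueError("pencil image and beam profile pixel scales differ")
    kernel = beam.weights / beam.weights.sum()
    full = signal.fftconvolve(pencil_image.values, kernel, mode="full")
    r0, c0 = beam.origin
    h, w = pencil_image.values.shape
    cropped = full[r0:r0 + h, c0:c0 + w]
    cropped = np.clip(cropped, 0.0, None)  # FFT can leave tiny negatives
    return ReflectanceImage(cropped, pencil_image.pixel_scale,
                            pencil_image.origin, pencil_image.n_launched)


# --------------------------------------------------------------------------
# Diffusion-dipole oracle
# --------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _boundary_coefficients(n_rel: float) -> tuple[float, float, float]:
    """Fresnel moments for the extrapolated-boundary diffusion solution.

    R_phi and R_j are the fluence- and flux-weighted angular integrals of the
    internal Fresnel reflectance; A is the internal-reflection parameter for
    the extrapolated boundary distance z_b = 2 A D.
    """
    from .optics import fresnel_unpolarized

    def refl(theta: float) -> float:
        return fresnel_unpolarized(n_rel, 1.0, math.cos(theta))

    r_phi = integrate.quad(lambda t: 2.0 * math.sin(t) * math.cos(t) * refl(t),
                           0.0, math.pi / 2)[0]
    r_j = integrate.quad(lambda t: 3.0 * math.sin(t) * math.cos(t) ** 2 * refl(t),
                         0.0, math.pi / 2)[0]
    a_param = (1.0 + r_j) / (1.0 - r_phi)
    return r_phi, r_j, a_param


def diffusion_reflectance(props: OpticalProperties, rho) -> np.ndarray:
    """Diffusion-dipole spatially resolved reflectance of a semi-infinite medium.

    Pencil-beam closed form with an isotropic source at depth
    ``z0 = 1/(mu_a + mu_s')``, an image source mirrored about the
    extrapolated boundary at ``z_b = 2 A D``, and detection expressed as the
    partial-current combination of surface fluence and flux with
    index-mismatch coefficients from Fresnel integrals.  Valid in the
    diffusive regime (mu_a << mu_s', rho * mu_s' >~ 2); a warning is issued
    outside it.  Units: mm^-2 per incident photon.
    """
    import warnings

    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be > 0")
    if props.mu_a > 0.1 * props.mu_s_prime:
        warnings.warn("diffusion oracle used outside the diffusive regime "
                      "(mu_a > 0.1 mu_s')", stacklevel=2)
    mu_t = props.mu_a + props.mu_s_prime
    d_coef = 1.0 / (3.0 * mu_t)
    mu_eff = math.sqrt(3.0 * props.mu_a * mu_t)
    z0 = 1.0 / mu_t
    r_phi, r_j, a_param = _boundary_coefficients(props.n)
    zb = 2.0 * a_param * d_coef
    z1 = z0 + 2.0 * zb  # image source depth
    r1 = np.sqrt(rho * rho + z0 * z0)
    r2 = np.sqrt(rho * rho + z1 * z1)
    phi = (np.exp(-mu_eff * r1) / r1 - np.exp(-mu_eff * r2) / r2) / (4.0 * math.pi * d_coef)
    flux = (z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1**2
            + z1 * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2**2) / (4.0 * math.pi)
    c_phi = 0.25 * (1.0 - r_phi)
    c_j = 0.5 * (1.0 - r_j)
    return (c_phi * phi + c_j * flux)[()]
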