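"""Perturbation Monte Carlo (pMC) rescaling and Jacobian assembly.

A stored simulation's detected photons carry the sufficient statistics
(collision count j, total path length L, detection weight).  Because the
forward model samples free paths from mu_s alone and applies absorption as a
terminal factor exp(-mu_a * L), a simulation run at properties
(mu_a, mu_s) can be reweighted exactly to perturbed properties
(mu_a_hat, mu_s_hat) per photon:

    factor = (mu_s_hat / mu_s)^j
             * exp(-(mu_s_hat - mu_s) * L)
             * exp(-(mu_a_hat - mu_a) * L)

The first two terms are the scattering likelihood ratio of the recorded path
(collision density and free-path exponentials), the last is the absorption
correction.  Perturbations of g or n change the angular likelihood and the
boundary physics and are not supported.

Derivatives of the radially binned reflectance with respect to mu_a and
mu_s' follow by finite differences of the rescaled curve against the
unperturbed one, divided by the absolute step p * delta_p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .montecarlo import PathStatistics, ReflectanceImage, bin_exits_to_image
from .optics import OpticalProperties

__all__ = [
    "PerturbationSpec",
    "rescale_factors",
    "rescale_reflectance",
    "jacobian_columns",
]

#: pMC weight factors above this trigger a validity warning.
FACTOR_WARN_LIMIT = 1e3


@dataclass(frozen=True)
class PerturbationSpec:
    """A relative perturbation of one optical coefficient.

    ``parameter`` is ``"mu_a"`` or ``"mu_s_prime"``; ``delta_p`` is the
    relative step (default 0.05), so the perturbed value is p * (1 + delta_p).
    """

    parameter: str
    delta_p: float = 0.05

    def __post_init__(self) -> None:
        if self.parameter not in ("mu_a", "mu_s_prime"):
            raise ValueError(f"unsupported perturbation parameter {self.parameter!r}")
        if not self.delta_p > 0:
            raise ValueError("delta_p must be > 0")

    def apply(self, props: OpticalProperties) -> OpticalProperties:
        value = getattr(props, self.parameter) * (1.0 + self.delta_p)
        return props.with_(**{self.parameter: value})


def rescale_factors(stats: PathStatistics, props: OpticalProperties,
                    perturbed: OpticalProperties) -> np.ndarray:
    """Per-photon pMC weight factors taking ``props`` to ``perturbed``.

    A mu_s' perturbation at fixed g is realized as a mu_s perturbation with
    mu_s_hat = mu_s_prime_hat / (1 - g).  Raises for perturbations of g or n.
    """
    if perturbed.g != props.g:
        raise ValueError("perturbation of the anisotropy g is not supported")
    if perturbed.n != props.n:
        raise ValueError("perturbation of the refractive index n is not supported")
    if perturbed.mu_a == props.mu_a and perturbed.mu_s_prime == props.mu_s_prime:
        return np.ones_like(stats.weight)
    mu_s = props.mu_s
    mu_s_hat = perturbed.mu_s
    ratio = mu_s_hat / mu_s
    log_factor = (stats.n_collisions * np.log(ratio)
                  - (mu_s_hat - mu_s) * stats.path_length
                  - (perturbed.mu_a - props.mu_a) * stats.path_length)
    return np.exp(log_factor)


def rescale_reflectance(stats: PathStatistics, props: OpticalProperties,
                        perturbed: OpticalProperties, shape: tuple[int, int],
                        pixel_scale: float, origin: tuple[int, int],
                        ) -> ReflectanceImage:
    """Rebin a stored simulation at perturbed optical properties.

    With ``perturbed == props`` the original image is reproduced bit-exactly
    (all factors are exactly 1).  Large perturbations degrade the pMC
    estimator; factors above :data:`FACTOR_WARN_LIMIT` raise a warning.
    """
    factors = rescale_factors(stats, props, perturbed)
    if np.any(factors > FACTOR_WARN_LIMIT):
        warnings.warn(
            "pMC weight factor exceeds %g; the perturbation is too large for "
            "a reliable rescaling" % FACTOR_WARN_LIMIT, stacklevel=2)
    return bin_exits_to_image(stats.row, stats.col, stats.weight * factors,
                              shape, pixel_scale, origin, stats.n_launched)


def jacobian_columns(stats: PathStatistics, props: OpticalProperties,
                     specs, shape: tuple[int, int], pixel_scale: float,
                     origin: tuple[int, int], d_rho: float,
                     window=None) -> dict[str, np.ndarray]:
    """Finite-difference derivatives of the radial reflectance curve.

    For each :class:`PerturbationSpec` the stored paths are rescaled to
    p' = p (1 + delta_p), radially binned, and differenced against the
    unperturbed curve:

        dR/dp = (R(p') - R(p)) / (p * delta_p)

    Returns a mapping parameter name -> derivative array over the window's
    bins (or the full curve when ``window`` is None).  Binning is linear in
    the photon weights, so rescale-then-bin equals bin-then-rescale exactly.
    """
    from .pipeline import radial_bin

    base_img = bin_exits_to_image(stats.row, stats.col, stats.weight, shape,
                                  pixel_scale, origin, stats.n_launched)
    base = radial_bin(base_img.values, origin, pixel_scale, d_rho)
    out: dict[str, np.ndarray] = {}
    for spec in specs:
        perturbed = spec.apply(props)
        img = rescale_reflectance(stats, props, perturbed, shape, pixel_scale,
                                  origin)
        curve = radial_bin(img.values, origin, pixel_scale, d_rho)
        p_value = getattr(props, spec.parameter)
        deriv = (curve.values - base.values) / (p_value * spec.delta_p)
        if window is not None:
            deriv = deriv[window.slice_for(base)]
        out[spec.parameter] = deriv
    return out
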