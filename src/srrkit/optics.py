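"""Elementary single-photon physics shared by all modules.

Conventions used throughout the package:

* ``mu_a``, ``mu_s``, ``mu_s_prime`` are in mm^-1 and relate through the
  anisotropy factor ``g`` as ``mu_s_prime = mu_s * (1 - g)``.
* Scattering deflections follow the Henyey-Greenstein (HG) phase function,
  sampled by its closed-form inverse CDF; azimuth is uniform on [0, 2*pi).
* Boundary crossings use unpolarized Fresnel reflectance (mean of the s- and
  p-polarized coefficients) and Snell refraction.  Light is assumed
  unpolarized at the sample.
* Angles handed to :func:`snell_refract` are in radians, measured from the
  surface normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "OpticalProperties",
    "SampleGeometry",
    "RefractionResult",
    "sample_hg_cosine",
    "hg_pdf",
    "hg_cdf",
    "fresnel_unpolarized",
    "snell_refract",
    "normalize_direction",
]

_UNIT_TOL = 1e-12


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of a homogeneous turbid medium at one wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient in mm^-1 (>= 0).
    mu_s_prime : float
        Reduced scattering coefficient in mm^-1 (> 0).
    g : float
        Anisotropy factor, |g| < 1.  Default 0.8, the value used for the
        polymer-microsphere phantoms this package emulates.
    n : float
        Refractive index of the medium (>= 1).  Default 1.33 (water).
    wavelength : float or None
        Wavelength in nm, carried as metadata only.
    """

    mu_a: float
    mu_s_prime: float
    g: float = 0.8
    n: float = 1.33
    wavelength: float | None = None

    def __post_init__(self) -> None:
        if not (self.mu_a >= 0.0):
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if not (self.mu_s_prime > 0.0):
            raise ValueError(f"mu_s_prime must be > 0, got {self.mu_s_prime}")
        if not (abs(self.g) < 1.0):
            raise ValueError(f"anisotropy must satisfy |g| < 1, got {self.g}")
        if not (self.n >= 1.0):
            raise ValueError(f"refractive index must be >= 1, got {self.n}")
        if not math.isfinite(self.mu_s):
            raise ValueError("derived mu_s = mu_s_prime/(1-g) is not finite")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_s = mu_s_prime / (1 - g), mm^-1."""
        return self.mu_s_prime / (1.0 - self.g)

    def with_(self, **changes) -> "OpticalProperties":
        """Return a copy with the given fields replaced."""
        kwargs = dict(
            mu_a=self.mu_a, mu_s_prime=self.mu_s_prime, g=self.g, n=self.n,
            wavelength=self.wavelength,
        )
        kwargs.update(changes)
        return OpticalProperties(**kwargs)


@dataclass(frozen=True)
class SampleGeometry:
    """Slab geometry: thickness in mm and the refractive index above the surface."""

    thickness_d: float = 55.5
    n_above: float = 1.0

    def __post_init__(self) -> None:
        if not (self.thickness_d > 0.0):
            raise ValueError(f"thickness_d must be > 0, got {self.thickness_d}")
        if not (self.n_above >= 1.0):
            raise ValueError(f"n_above must be >= 1, got {self.n_above}")


class RefractionResult(NamedTuple):
    """Outcome of a Snell refraction: transmitted angle (radians) and TIR flag."""

    theta_t: float
    tir: bool


def normalize_direction(u) -> np.ndarray:
    """Return ``u`` scaled to unit length; raises if the norm is ~0."""
    u = np.asarray(u, dtype=float)
    norm = float(np.linalg.norm(u))
    if norm < _UNIT_TOL:
        raise ValueError("cannot normalize a near-zero direction vector")
    return u / norm


def sample_hg_cosine(g: float, u):
    """Sample the HG deflection cosine from uniform variates ``u`` in [0, 1).

    Uses the closed-form inverse CDF.  For g = 0 this reduces to the isotropic
    ``cos(theta) = 2 u - 1``.  Accepts scalars or arrays.
    """
    if not abs(g) < 1.0:
        raise ValueError(f"anisotropy must satisfy |g| < 1, got {g}")
    u = np.asarray(u, dtype=float)
    if g == 0.0:
        cos_t = 2.0 * u - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        cos_t = (1.0 + g * g - frac * frac) / (2.0 * g)
    return np.clip(cos_t, -1.0, 1.0)[()]


def hg_pdf(g: float, cos_theta):
    """HG probability density of the deflection cosine."""
    if not abs(g) < 1.0:
        raise ValueError(f"anisotropy must satisfy |g| < 1, got {g}")
    x = np.asarray(cos_theta, dtype=float)
    return (0.5 * (1.0 - g * g) / (1.0 + g * g - 2.0 * g * x) ** 1.5)[()]


def hg_cdf(g: float, cos_theta):
    """HG cumulative distribution of the deflection cosine on [-1, 1]."""
    if not abs(g) < 1.0:
        raise ValueError(f"anisotropy must satisfy |g| < 1, got {g}")
    x = np.asarray(cos_theta, dtype=float)
    if g == 0.0:
        return (0.5 * (x + 1.0))[()]
    pref = (1.0 - g * g) / (2.0 * g)
    return (pref * (1.0 / np.sqrt(1.0 + g * g - 2.0 * g * x) - 1.0 / (1.0 + g)))[()]


def fresnel_unpolarized(n_i: float, n_t: float, cos_theta_i: float) -> float:
    """Unpolarized Fresnel reflection probability at a planar interface.

    Mean of the s- and p-polarized reflectances.  Returns 1.0 beyond the
    critical angle when going from the denser into the rarer medium.

    Parameters
    ----------
    n_i, n_t : float
        Refractive indices of the incidence and transmission media (>= 1).
    cos_theta_i : float
        Cosine of the incidence angle, in (0, 1].
    """
    if n_i < 1.0 or n_t < 1.0:
        raise ValueError("refractive indices must be >= 1")
    if not (0.0 < cos_theta_i <= 1.0):
        raise ValueError(f"cos_theta_i must lie in (0, 1], got {cos_theta_i}")
    if n_i == n_t:
        return 0.0
    sin_i2 = 1.0 - cos_theta_i * cos_theta_i
    sin_t2 = (n_i / n_t) ** 2 * sin_i2
    if sin_t2 >= 1.0:  # total internal reflection
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n_i * cos_theta_i - n_t * cos_t) / (n_i * cos_theta_i + n_t * cos_t)
    rp = (n_i * cos_t - n_t * cos_theta_i) / (n_i * cos_t + n_t * cos_theta_i)
    return 0.5 * (rs * rs + rp * rp)


def snell_refract(theta_i: float, n_i: float, n_t: float) -> RefractionResult:
    """Refract an angle across an interface by Snell's law.

    Parameters
    ----------
    theta_i : float
        Incidence angle from the normal, radians, in [0, pi/2).
    n_i, n_t : float
        Refractive indices of the incidence and transmission media.

    Returns
    -------
    RefractionResult
        ``(theta_t, tir)``.  ``theta_t`` is NaN when total internal
        reflection occurs (``tir`` True).
    """
    if not (0.0 <= theta_i < math.pi / 2):
        raise ValueError(f"theta_i must lie in [0, pi/2), got {theta_i}")
    sin_t = n_i * math.sin(theta_i) / n_t
    if sin_t > 1.0:
        return RefractionResult(math.nan, True)
    return RefractionResult(math.asin(sin_t), False)
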