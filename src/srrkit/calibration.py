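"""Scaling-coefficient calibration against a reference sample.

A simulated reflectance curve is in mm^-2 per launched photon; an
experimental one is in counts/(V ms mm^2).  On a reference sample whose
optical properties are known independently, the per-bin ratio

    k(rho) = R_MC(rho) / R_exp(rho)

has units V ms and collapses every unmodeled instrument factor (source
power, sensor sensitivity, specular entry loss, collection efficiency) into
one number.  Its arithmetic mean over the fit window, k_bar, converts any
experimental image of the same wavelength to the per-photon scale:
R_exp_sc = k_bar * R_exp.  Applying the scalar k_bar (a "DC shift") is the
default; the rho-resolved profile can be applied behind a flag but couples
the reference sample's noise into every bin and is non-default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pipeline import ExperimentalReflectanceImage, RadialCurve, RadialWindow

__all__ = [
    "ScalingCoefficient",
    "scaling_profile",
    "scaling_coefficient",
    "apply_scaling",
    "calibrate",
]


@dataclass
class ScalingCoefficient:
    """Calibration result: k(rho) over the window and its average k_bar (V ms)."""

    k_profile: np.ndarray
    k_bar: float
    window: RadialWindow
    wavelength: float | None = None
    reference_sample_id: str | None = None

    def __post_init__(self) -> None:
        self.k_profile = np.asarray(self.k_profile, dtype=float)
        if not self.k_bar > 0:
            raise ValueError("k_bar must be > 0")


def scaling_profile(r_mc: RadialCurve, r_exp: RadialCurve,
                    window: RadialWindow) -> np.ndarray:
    """Per-bin scaling profile k(rho) = R_MC / R_exp over the window.

    Bins where the experimental curve is zero, negative or missing are
    excluded (NaN) with a warning.
    """
    if abs(r_mc.d_rho - r_exp.d_rho) > 1e-12:
        raise ValueError("curves do not share the same binning")
    sl = window.slice_for(r_exp)
    mc = r_mc.values[sl]
    exp = r_exp.values[sl]
    bad = ~(np.isfinite(exp) & (exp > 0) & np.isfinite(mc))
    if bad.any():
        warnings.warn(f"{int(bad.sum())} bins excluded from the scaling "
                      "profile (non-positive or missing reflectance)",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(bad, np.nan, mc / exp)
    return k


def scaling_coefficient(k_profile: np.ndarray,
                        window: RadialWindow | None = None) -> float:
    """Arithmetic mean of the contributing k(rho) bins (k_bar)."""
    k = np.asarray(k_profile, dtype=float)
    finite = np.isfinite(k)
    if finite.sum() < 2:
        raise ValueError("scaling profile has fewer than two contributing bins")
    return float(k[finite].mean())


def apply_scaling(data, k_bar: float):
    """Scale an experimental image or curve onto the per-photon (mm^-2) scale."""
    if isinstance(data, RadialCurve):
        return data.scaled(k_bar)
    if isinstance(data, ExperimentalReflectanceImage):
        return ExperimentalReflectanceImage(data.values * k_bar,
                                            data.pixel_scale, data.origin,
                                            data.wavelength, dict(data.meta))
    raise TypeError("expected a RadialCurve or ExperimentalReflectanceImage")


def calibrate(r_mc: RadialCurve, r_exp: RadialCurve, window: RadialWindow,
              wavelength: float | None = None,
              reference_sample_id: str | None = None) -> ScalingCoefficient:
    """Convenience wrapper: profile + average in one step."""
    profile = scaling_profile(r_mc, r_exp, window)
    k_bar = scaling_coefficient(profile, window)
    return ScalingCoefficient(profile, k_bar, window, wavelength,
                              reference_sample_id)
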