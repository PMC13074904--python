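"""Camera-image processing: flat-field, normalization, bloom handling,
exposure patching, radial binning and fit-window selection.

The experimental side of the SRR workflow turns raw 16-bit camera frames
into a radially binned reflectance curve in units of counts/(V ms mm^2):

1. flat-field correction (division by a mean-one gain map),
2. bloom detection and radial-average backfill on over-exposed frames,
3. stitching of a 1x/10x/100x integration-time series, per radial annulus,
   preferring the longest usable exposure for maximal SNR,
4. normalization by integration time, monitor-photodiode voltage and pixel
   area,
5. radial binning about the beam-incidence origin pixel, and
6. selection of the radial fit window [rho_0, rho_m]: from just outside the
   beam radius to the radius of thousandfold attenuation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage

__all__ = [
    "CameraFrame",
    "ExperimentalReflectanceImage",
    "RadialCurve",
    "RadialWindow",
    "flatfield_correct",
    "normalize_frame",
    "detect_bloom",
    "backfill_with_radial_average",
    "patch_exposure_series",
    "radial_bin",
    "fit_window",
    "shift_curve",
]

FULL_SCALE = 65535
#: default saturation threshold as a fraction of full scale
SAT_FRACTION = 0.95
#: pixels this bright that touch a saturated pixel in the same column are bloom
GROW_FRACTION = 0.8


@dataclass
class CameraFrame:
    """A single camera acquisition plus the metadata needed to normalize it."""

    counts: np.ndarray
    t_int: float
    pd_voltage: float
    wavelength: float | None = None
    dark_subtracted: bool = False
    exposure_tag: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D array")
        if not self.t_int > 0:
            raise ValueError("integration time must be > 0")
        if not self.pd_voltage > 0:
            raise ValueError("photodiode voltage must be > 0")
        if self.counts.size and float(self.counts.max()) > FULL_SCALE:
            raise ValueError("counts exceed the 16-bit full scale")
        if not self.dark_subtracted and self.counts.size and float(self.counts.min()) < 0:
            raise ValueError("raw counts must be non-negative")

    def replace_counts(self, counts, *, dark_subtracted=None) -> "CameraFrame":
        return CameraFrame(counts, self.t_int, self.pd_voltage, self.wavelength,
                           self.dark_subtracted if dark_subtracted is None else dark_subtracted,
                           self.exposure_tag)


@dataclass
class ExperimentalReflectanceImage:
    """Normalized 2D reflectance in counts V^-1 ms^-1 mm^-2."""

    values: np.ndarray
    pixel_scale: float
    origin: tuple[int, int]
    wavelength: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be > 0")


@dataclass
class RadialCurve:
    """Radially binned reflectance: bin centers, means, width, pixel counts.

    ``variance``, when present, is the estimated variance of each bin mean
    (within-annulus pixel scatter divided by the pixel count).
    """

    rho: np.ndarray
    values: np.ndarray
    d_rho: float
    counts_per_bin: np.ndarray
    variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.counts_per_bin = np.asarray(self.counts_per_bin)
        if self.rho.ndim != 1 or self.rho.shape != self.values.shape:
            raise ValueError("rho and values must be matching 1D arrays")
        if not self.d_rho > 0:
            raise ValueError("d_rho must be > 0")
        if self.variance is not None:
            self.variance = np.asarray(self.variance, dtype=float)

    def scaled(self, factor: float) -> "RadialCurve":
        var = None if self.variance is None else self.variance * factor**2
        return RadialCurve(self.rho, self.values * factor, self.d_rho,
                           self.counts_per_bin, var)


@dataclass(frozen=True)
class RadialWindow:
    """Radial fit window [rho_0, rho_m] with P contributing bins (inclusive)."""

    rho_0: float
    rho_m: float
    P: int
    i0: int
    i1: int

    def __post_init__(self) -> None:
        if not self.rho_0 < self.rho_m:
            raise ValueError("rho_0 must be < rho_m")
        if self.P < 2:
            raise ValueError("a window needs at least two bins")

    def slice_for(self, curve: RadialCurve) -> slice:
        """Index slice of this window on a curve with the same binning."""
        if abs(curve.rho[self.i0] - self.rho_0) > 0.5 * curve.d_rho:
            raise ValueError("window does not match the curve binning")
        return slice(self.i0, self.i1 + 1)


# --------------------------------------------------------------------------
# Frame-level operations
# --------------------------------------------------------------------------

def flatfield_correct(frame: CameraFrame, flat: np.ndarray) -> CameraFrame:
    """Divide the frame pixelwise by a mean-one gain map."""
    flat = np.asarray(flat, dtype=float)
    if flat.shape != frame.counts.shape:
        raise ValueError("flat-field shape does not match the frame")
    if np.any(flat <= 0):
        raise ValueError("flat-field must be strictly positive")
    corrected = frame.counts.astype(float) / flat
    # division can push bright pixels past full scale; the frame stays valid
    out = CameraFrame.__new__(CameraFrame)
    out.counts = corrected
    out.t_int = frame.t_int
    out.pd_voltage = frame.pd_voltage
    out.wavelength = frame.wavelength
    out.dark_subtracted = frame.dark_subtracted
    out.exposure_tag = frame.exposure_tag
    return out


def normalize_frame(frame: CameraFrame, pixel_scale: float,
                    origin: tuple[int, int]) -> ExperimentalReflectanceImage:
    """Normalize counts by integration time, photodiode voltage and pixel area.

    The frame must already be dark-subtracted (and normally flat-fielded).
    """
    if not frame.dark_subtracted:
        raise ValueError("frame must be dark-subtracted before normalization")
    pixel_area = pixel_scale * pixel_scale
    values = frame.counts.astype(float) / (frame.t_int * frame.pd_voltage * pixel_area)
    return ExperimentalReflectanceImage(values, pixel_scale, origin,
                                        frame.wavelength)


def detect_bloom(frame: CameraFrame, sat_fraction: float = SAT_FRACTION,
                 grow_fraction: float = GROW_FRACTION,
                 axis: int = 0, dilate: int = 1) -> np.ndarray:
    """Mask saturated pixels and the charge-bleed streaks they feed.

    Seeds are pixels at or above ``sat_fraction`` of full scale.  CCD bloom
    bleeds charge along the readout axis (columns by default, ``axis=0``),
    so any contiguous same-column run of pixels above ``grow_fraction`` of
    full scale that touches a seed is masked with it.  The mask is then
    extended by ``dilate`` pixels along the axis at each run end: the last
    pixel a bleed reaches is only partially filled and can sit below any
    brightness threshold while still carrying spilled charge.
    """
    counts = np.asarray(frame.counts, dtype=float)
    if axis == 1:
        counts = counts.T
    seeds = counts >= sat_fraction * FULL_SCALE
    if not seeds.any():
        mask = np.zeros_like(seeds)
        return mask.T if axis == 1 else mask
    above = counts >= grow_fraction * FULL_SCALE
    # contiguous True-runs per column share a cumsum(~above) value
    run_id = np.cumsum(~above, axis=0)
    cols = np.broadcast_to(np.arange(counts.shape[1]), counts.shape)
    keys = run_id.astype(np.int64) * counts.shape[1] + cols
    seed_keys = np.unique(keys[seeds])
    mask = above & np.isin(keys, seed_keys)
    for _ in range(dilate):
        grown = mask.copy()
        grown[1:] |= mask[:-1]
        grown[:-1] |= mask[1:]
        mask = grown
    return mask.T if axis == 1 else mask


@lru_cache(maxsize=16)
def _annulus_index(shape: tuple[int, int], origin: tuple[int, int],
                   pixel_scale: float, d_rho: float) -> tuple[np.ndarray, int]:
    """Per-pixel radial bin index about the origin pixel center."""
    rr = (np.arange(shape[0]) - origin[0]) * pixel_scale
    cc = (np.arange(shape[1]) - origin[1]) * pixel_scale
    rho = np.hypot(rr[:, None], cc[None, :])
    idx = np.floor(rho / d_rho).astype(np.int64)
    return idx, int(idx.max()) + 1


def backfill_with_radial_average(values: np.ndarray, mask: np.ndarray,
                                 origin: tuple[int, int], pixel_scale: float,
                                 d_rho: float, method: str = "interp",
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Replace masked pixels using the radial average at their rho position.

    ``method="interp"`` (default) evaluates the radial profile of the
    unmasked pixels at each masked pixel's own radius (log-linear between
    annulus means when the profile is positive): on a steeply decaying
    image the plain annulus mean is biased by the within-annulus radial
    spread.  ``method="mean"`` assigns the bare annulus mean.

    Returns ``(filled, unfilled_mask)``; pixels in annuli with no unmasked
    member cannot be filled and stay flagged in ``unfilled_mask``.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask shape does not match the image")
    if method not in ("interp", "mean"):
        raise ValueError("method must be 'interp' or 'mean'")
    if not mask.any():
        return values.copy(), np.zeros_like(mask)
    idx, n_bins = _annulus_index(values.shape, tuple(origin), pixel_scale, d_rho)
    good = ~mask
    sums = np.bincount(idx[good], weights=values[good], minlength=n_bins)
    cnts = np.bincount(idx[good], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    filled = values.copy()
    bad_annulus = ~np.isfinite(means[idx[mask]])
    if method == "mean":
        fill_vals = means[idx[mask]]
    else:
        rr = (np.arange(values.shape[0]) - origin[0]) * pixel_scale
        cc = (np.arange(values.shape[1]) - origin[1]) * pixel_scale
        rho_all = np.hypot(rr[:, None], cc[None, :])
        rho_pix = rho_all[mask]
        # node abscissae: the measured mean radius of each annulus's
        # unmasked pixels (thin discrete annuli are not centered on the
        # nominal bin center)
        rho_sums = np.bincount(idx[good], weights=rho_all[good],
                               minlength=n_bins)
        nodes = np.isfinite(means) & (cnts > 0)
        node_rho = rho_sums[nodes] / cnts[nodes]
        node_val = means[nodes]
        if node_val.size and np.all(node_val > 0):
            fill_vals = 10.0 ** np.interp(rho_pix, node_rho,
                                          np.log10(node_val))
        elif node_val.size:
            fill_vals = np.interp(rho_pix, node_rho, node_val)
        else:
            fill_vals = np.full(rho_pix.size, np.nan)
        # pixels in annuli with no unmasked member stay flagged even though
        # interpolation could bridge them
        fill_vals = np.where(bad_annulus, np.nan, fill_vals)
    filled[mask] = fill_vals
    unfilled = np.zeros_like(mask)
    unfilled[mask] = ~np.isfinite(fill_vals)
    filled[mask & unfilled] = values[mask & unfilled]
    return filled, unfilled


def patch_exposure_series(frames, origin: tuple[int, int], pixel_scale: float,
                          flat: np.ndarray | None = None,
                          d_rho: float | None = None,
                          sat_fraction: float = SAT_FRACTION,
                          sat_headroom: float = 0.9,
                          min_counts: float = 50.0,
                          ) -> ExperimentalReflectanceImage:
    """Stitch a 1x/10x/100x exposure series into one normalized image.

    Each frame is flat-fielded, bloom-masked and backfilled, then normalized.
    Per radial annulus the stitched image takes its pixels from the longest
    exposure predicted not to saturate anywhere in that annulus.  The
    prediction scales the shortest (auto-exposed, unsaturated) frame by the
    exposure ratio ``(t_k V_k)/(t_0 V_0)``: judging saturation from the
    measured longer frame itself would admit annuli whose bright side is
    already clipped and bloom-masked, and backfilling those from the dim
    side biases the annulus low (the surface image of an oblique beam is not
    azimuthally uniform).  ``sat_headroom`` leaves margin for shot noise on
    top of the prediction.  Annuli where the chosen exposure averages below
    ``min_counts`` raw counts are kept but flagged as low-SNR in ``meta``.
    """
    frames = sorted(frames, key=lambda f: f.t_int)
    if not frames:
        raise ValueError("no frames supplied")
    shapes = {f.counts.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError("frames have inconsistent geometry")
    wavelengths = {f.wavelength for f in frames}
    if len(wavelengths) != 1:
        raise ValueError("frames are from different wavelengths")
    shape = frames[0].counts.shape
    if d_rho is None:
        d_rho = pixel_scale
    idx, n_bins = _annulus_index(shape, tuple(origin), pixel_scale, d_rho)
    flat_idx = idx.ravel()
    n_pix = np.bincount(flat_idx, minlength=n_bins)

    # annulus maxima of the reference (shortest) frame, for the prediction
    ref = frames[0]
    ref_raw = np.asarray(ref.counts, dtype=float).ravel()
    ref_max = np.full(n_bins, 0.0)
    np.maximum.at(ref_max, flat_idx, ref_raw)
    sat_level = sat_headroom * sat_fraction * FULL_SCALE

    normalized = []
    eligible = []
    mean_raw = []
    for k, f in enumerate(frames):
        raw = np.asarray(f.counts, dtype=float)
        mask = detect_bloom(f, sat_fraction=sat_fraction)
        ff = flatfield_correct(f, flat) if flat is not None else f
        filled, unfilled = backfill_with_radial_average(
            ff.counts.astype(float), mask, origin, pixel_scale, d_rho)
        norm = normalize_frame(ff.replace_counts(filled), pixel_scale, origin)
        normalized.append(norm.values)

        good = (~mask).ravel()
        n_good = np.bincount(flat_idx[good], minlength=n_bins)
        sum_raw = np.bincount(flat_idx[good], weights=raw.ravel()[good],
                              minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_raw.append(np.where(n_good > 0, sum_raw / np.maximum(n_good, 1), 0.0))
        scale = (f.t_int * f.pd_voltage) / (ref.t_int * ref.pd_voltage)
        predicted_max = ref_max * scale
        eligible.append((predicted_max <= sat_level) & (n_good > 0)
                        if k > 0 else np.ones(n_bins, dtype=bool))

    eligible = np.asarray(eligible)          # (n_frames, n_bins)
    # longest eligible exposure per annulus; the shortest frame is the fallback
    choice = np.zeros(n_bins, dtype=int)
    for k in range(len(frames)):
        choice[eligible[k]] = k
    out = np.zeros(shape, dtype=float)
    for k, norm in enumerate(normalized):
        sel = choice[idx] == k
        out[sel] = norm[sel]
    chosen_mean_raw = np.choose(choice, mean_raw)
    low_snr = (chosen_mean_raw < min_counts) & (n_pix > 0)
    meta = {
        "annulus_source": choice,
        "annulus_t_int": np.array([frames[k].t_int for k in choice]),
        "annulus_low_snr": low_snr,
        "d_rho": d_rho,
    }
    return ExperimentalReflectanceImage(out, pixel_scale, tuple(origin),
                                        frames[0].wavelength, meta)


# --------------------------------------------------------------------------
# Radial binning and the fit window
# --------------------------------------------------------------------------

def radial_bin(values: np.ndarray, origin: tuple[int, int], pixel_scale: float,
               d_rho: float, max_rho: float | None = None) -> RadialCurve:
    """Radially bin a 2D image about the origin pixel center.

    Bin i collects pixels whose center distance lies in [i*d_rho, (i+1)*d_rho);
    the bin value is the mean of the collected pixels (empty bins are NaN).
    The mean-times-count identity makes binning exactly conservative:
    sum_i R_i * n_i == sum of all binned pixels.
    """
    if not d_rho > 0:
        raise ValueError("d_rho must be > 0")
    values = np.asarray(values, dtype=float)
    idx, n_bins = _annulus_index(values.shape, tuple(origin), pixel_scale, d_rho)
    if max_rho is not None:
        n_bins = min(n_bins, int(np.ceil(max_rho / d_rho)))
    keep = idx < n_bins
    sums = np.bincount(idx[keep], weights=values[keep], minlength=n_bins)
    sumsq = np.bincount(idx[keep], weights=values[keep] ** 2,
                        minlength=n_bins)
    cnts = np.bincount(idx[keep], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        # variance of the bin mean from the within-annulus pixel scatter
        sample_var = (sumsq / np.maximum(cnts, 1) - means**2) \
            * cnts / np.maximum(cnts - 1, 1)
        var_mean = np.where(cnts > 1,
                            np.maximum(sample_var, 0.0) / np.maximum(cnts, 1),
                            np.nan)
    rho = (np.arange(n_bins) + 0.5) * d_rho
    return RadialCurve(rho, means, d_rho, cnts, var_mean)


def _running_median(values: np.ndarray, size: int) -> np.ndarray:
    """Median smoothing that tolerates NaNs (propagated as missing)."""
    filled = np.where(np.isfinite(values), values, np.nan)
    out = np.full_like(filled, np.nan)
    half = size // 2
    n = filled.size
    for i in range(n):
        seg = filled[max(0, i - half):min(n, i + half + 1)]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            out[i] = np.median(seg)
    return out


def fit_window(curve: RadialCurve, rho_r: float,
               attenuation: float = 1e3, smooth_bins: int = 5) -> RadialWindow:
    """Select the radial fit window [rho_0, rho_m].

    rho_0 is the first bin center at or beyond rho_r + d_rho (just outside
    the focused beam).  rho_m is the first bin at which the median-smoothed
    curve has fallen by ``attenuation`` (default one thousandfold) relative
    to rho_0; radially binned reflectance grows too noisy beyond that.  If
    the curve never reaches the attenuation the window is truncated at the
    last valid bin with a warning.
    """
    smoothed = _running_median(curve.values, smooth_bins)
    valid = np.isfinite(smoothed)
    start = curve.rho >= rho_r + curve.d_rho
    candidates = np.nonzero(start & valid)[0]
    if candidates.size == 0:
        raise ValueError("no valid bins beyond the beam radius")
    i0 = int(candidates[0])
    r0 = smoothed[i0]
    if not r0 > 0:
        raise ValueError("reflectance at rho_0 is not positive")
    below = np.nonzero(valid & (np.arange(curve.rho.size) > i0)
                       & (smoothed <= r0 / attenuation))[0]
    if below.size:
        i1 = int(below[0])
    else:
        i1 = int(np.nonzero(valid)[0][-1])
        warnings.warn(
            "curve never reaches the %.0fx attenuation bound; window "
            "truncated at the last valid bin" % attenuation, stacklevel=2)
    if i1 <= i0:
        raise ValueError("degenerate fit window")
    return RadialWindow(float(curve.rho[i0]), float(curve.rho[i1]),
                        i1 - i0 + 1, i0, i1)


def shift_curve(curve: RadialCurve, shift_bins: int) -> RadialCurve:
    """Re-index a curve by an integer number of bins (origin-shift emulation).

    ``shift_bins = s`` assigns bin i the value previously at i + s, which is
    what an origin misplaced by s bins produces; the vacated tail is NaN.
    """
    if shift_bins == 0:
        var = None if curve.variance is None else curve.variance.copy()
        return RadialCurve(curve.rho, curve.values.copy(), curve.d_rho,
                           curve.counts_per_bin.copy(), var)
    vals = np.full_like(curve.values, np.nan)
    cnts = np.zeros_like(curve.counts_per_bin)
    var = None if curve.variance is None else np.full_like(curve.variance,
                                                           np.nan)
    if shift_bins > 0:
        vals[:-shift_bins] = curve.values[shift_bins:]
        cnts[:-shift_bins] = curve.counts_per_bin[shift_bins:]
        if var is not None:
            var[:-shift_bins] = curve.variance[shift_bins:]
    else:
        vals[-shift_bins:] = curve.values[:shift_bins]
        cnts[-shift_bins:] = curve.counts_per_bin[:shift_bins]
        if var is not None:
            var[-shift_bins:] = curve.variance[:shift_bins]
    return RadialCurve(curve.rho, vals, curve.d_rho, cnts, var)
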