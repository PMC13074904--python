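"""File formats: TIFF images with JSON sidecars, CSV curves, JSON results.

Conventions
-----------
* Camera frames: 16-bit (or float, if processed) grayscale TIFF plus a JSON
  sidecar ``<name>.json`` carrying ``t_int_ms``, ``pd_voltage_V``,
  ``wavelength_nm``, ``exposure_tag`` and ``dark_subtracted``.
* Reflectance images: 32-bit float TIFF plus a sidecar with ``pixel_scale_mm``,
  ``origin`` and free-form metadata (``n_launched``, seeds, ...).
* Radial curves: CSV with header ``rho_mm,R,n_pixels``.
* Path statistics: NumPy ``.npz`` with documented column order
  (row, col, weight, n_collisions, path_length).
* Masks: 8-bit TIFF (0/255).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .montecarlo import PathStatistics, ReflectanceImage
from .pipeline import CameraFrame, RadialCurve, RadialWindow

__all__ = [
    "save_camera_frame", "load_camera_frame",
    "save_reflectance_image", "load_reflectance_image",
    "save_radial_curve", "load_radial_curve",
    "save_path_statistics", "load_path_statistics",
    "save_mask", "load_mask",
    "save_json", "load_json",
    "SidecarError",
]


class SidecarError(RuntimeError):
    """A required metadata sidecar is missing or malformed."""


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def _read_sidecar(path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SidecarError(f"missing metadata sidecar {sidecar}")
    try:
        with open(sidecar) as fh:
            return json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise SidecarError(f"malformed metadata sidecar {sidecar}: {exc}") from exc


def save_camera_frame(path, frame: CameraFrame) -> None:
    counts = frame.counts
    if counts.dtype.kind in "ui":
        data = counts.astype(np.uint16)
    else:
        data = counts.astype(np.float32)
    tifffile.imwrite(str(path), data)
    meta = {
        "t_int_ms": frame.t_int,
        "pd_voltage_V": frame.pd_voltage,
        "wavelength_nm": frame.wavelength,
        "exposure_tag": frame.exposure_tag,
        "dark_subtracted": frame.dark_subtracted,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_camera_frame(path) -> CameraFrame:
    meta = _read_sidecar(path)
    try:
        return CameraFrame(
            tifffile.imread(str(path)),
            t_int=float(meta["t_int_ms"]),
            pd_voltage=float(meta["pd_voltage_V"]),
            wavelength=meta.get("wavelength_nm"),
            dark_subtracted=bool(meta.get("dark_subtracted", False)),
            exposure_tag=meta.get("exposure_tag"),
        )
    except KeyError as exc:
        raise SidecarError(f"sidecar for {path} lacks required key {exc}") from exc


def save_reflectance_image(path, values, pixel_scale: float, origin,
                           meta: dict | None = None) -> None:
    tifffile.imwrite(str(path), np.asarray(values, dtype=np.float32))
    sidecar = {"pixel_scale_mm": pixel_scale, "origin": list(origin)}
    sidecar.update(meta or {})
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_reflectance_image(path) -> tuple[np.ndarray, dict]:
    meta = _read_sidecar(path)
    values = tifffile.imread(str(path)).astype(float)
    if "pixel_scale_mm" not in meta or "origin" not in meta:
        raise SidecarError(f"sidecar for {path} lacks pixel_scale_mm/origin")
    return values, meta


def save_radial_curve(path, curve: RadialCurve) -> None:
    pd.DataFrame({"rho_mm": curve.rho, "R": curve.values,
                  "n_pixels": curve.counts_per_bin}).to_csv(path, index=False)


def load_radial_curve(path) -> RadialCurve:
    df = pd.read_csv(path)
    for col in ("rho_mm", "R", "n_pixels"):
        if col not in df.columns:
            raise SidecarError(f"radial curve {path} lacks column {col!r}")
    rho = df["rho_mm"].to_numpy(float)
    if rho.size < 2:
        raise SidecarError(f"radial curve {path} has fewer than two bins")
    d_rho = float(np.median(np.diff(rho)))
    return RadialCurve(rho, df["R"].to_numpy(float), d_rho,
                       df["n_pixels"].to_numpy())


def save_path_statistics(path, stats: PathStatistics) -> None:
    np.savez_compressed(
        path, row=stats.row, col=stats.col, weight=stats.weight,
        n_collisions=stats.n_collisions, path_length=stats.path_length,
        n_launched=np.int64(stats.n_launched),
        budget_keys=np.array(sorted(stats.energy_budget)),
        budget_values=np.array([stats.energy_budget[k]
                                for k in sorted(stats.energy_budget)]))


def load_path_statistics(path) -> PathStatistics:
    with np.load(path, allow_pickle=False) as data:
        budget = dict(zip([str(k) for k in data["budget_keys"]],
                          data["budget_values"].tolist()))
        return PathStatistics(data["row"], data["col"], data["weight"],
                              data["n_collisions"], data["path_length"],
                              int(data["n_launched"]), budget)


def save_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


def load_mask(path) -> np.ndarray:
    return tifffile.imread(str(path)) > 0


def save_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, RadialWindow):
        return {"rho_0": obj.rho_0, "rho_m": obj.rho_m, "P": obj.P,
                "i0": obj.i0, "i1": obj.i1}
    raise TypeError(f"cannot serialize {type(obj)!r}")
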