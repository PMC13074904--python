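"""Synthetic instrument: render a 1x/10x/100x exposure triplet of a known
reflectance field, stitch it, and verify the recovered dynamic range.

Run:  python examples/02_synthetic_camera.py   (~10 s)
"""

import numpy as np

from srrkit.pipeline import patch_exposure_series, radial_bin
from srrkit.synthetic import (CameraModel, default_flat_field,
                              render_exposure_triplet)

PS = 0.0361  # mm per pixel

# A steeply decaying truth field spanning >4 decades across the grid.
yy, xx = np.mgrid[0:129, 0:129]
rho = np.hypot(yy - 64, xx - 64) * PS
truth = 10.0 ** (-2.0 * rho)

cam = CameraModel()        # 16-bit CCD: shot noise, read noise, bloom
rng = np.random.default_rng(0)
frames = render_exposure_triplet(truth, cam, pd_voltage=2.0, rng=rng)
print("integration times [ms]:", [round(f.t_int, 3) for f in frames])
print("peak counts:", [int(f.counts.max()) for f in frames],
      "(1x auto-exposed to ~30,000; longer exposures saturate and bloom)")

subtracted = [f.replace_counts(f.counts.astype(float) - cam.dark_offset,
                               dark_subtracted=True) for f in frames]
patched = patch_exposure_series(subtracted, (64, 64), PS)
curve = radial_bin(patched.values / cam.gain, (64, 64), PS, PS)
truth_curve = radial_bin(truth / PS**2, (64, 64), PS, PS)

print("\nrho [mm]   recovered/truth   exposure used")
src = patched.meta["annulus_source"]
for i in (5, 20, 40, 60, 80):
    ratio = curve.values[i] / truth_curve.values[i]
    print(f"{curve.rho[i]:7.2f}   {ratio:15.3f}   "
          f"{['1x', '10x', '100x'][src[i]]}")
print("\nRatios near 1 across ~4 decades show the stitching recovering the "
      "full dynamic range: the core from the short exposure, the faint tail "
      "from the 100x frame with its bloom masked and backfilled.")
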