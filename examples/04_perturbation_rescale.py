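"""Perturbation Monte Carlo: reweight a stored simulation to new optical
properties and assemble reflectance derivatives without re-simulating.

Run:  python examples/04_perturbation_rescale.py   (~30 s)
"""

import numpy as np

from srrkit import (OpticalProperties, PerturbationSpec, SampleGeometry,
                    SimulationConfig, jacobian_columns, make_beam_profile,
                    radial_bin, rescale_reflectance, simulate_srr_image)

props = OpticalProperties(mu_a=0.01, mu_s_prime=2.0)
beam = make_beam_profile(grid_shape=(257, 257))
cfg = SimulationConfig(n_photons=200_000, seed=5, kill_radius=30.0)
_, stats = simulate_srr_image(props, SampleGeometry(), beam, cfg)
print(f"stored {len(stats)} detected photons "
      "(exit pixel, weight, collisions, path length)")

# Reweight those same paths to 5% more scattering.
pert = props.with_(mu_s_prime=2.1)
img = rescale_reflectance(stats, props, pert, beam.shape, beam.pixel_scale,
                          beam.origin)
base = rescale_reflectance(stats, props, props, beam.shape, beam.pixel_scale,
                           beam.origin)
c0 = radial_bin(base.values, beam.origin, beam.pixel_scale, 0.25, max_rho=4.0)
c1 = radial_bin(img.values, beam.origin, beam.pixel_scale, 0.25, max_rho=4.0)
print("\nrho [mm]   R(mu_s'=2.0)   R(mu_s'=2.1)   ratio")
for i in (2, 5, 9, 13):
    print(f"{c0.rho[i]:7.2f}   {c0.values[i]:.4e}    {c1.values[i]:.4e}"
          f"    {c1.values[i] / c0.values[i]:.3f}")

derivs = jacobian_columns(stats, props,
                          [PerturbationSpec("mu_a"),
                           PerturbationSpec("mu_s_prime")],
                          beam.shape, beam.pixel_scale, beam.origin, 0.25)
d_mua = derivs["mu_a"][2:14]
d_musp = derivs["mu_s_prime"][2:14]
print(f"\ndR/dmu_a over 0.5-3.5 mm: all non-positive? "
      f"{bool(np.all(d_mua[np.isfinite(d_mua)] <= 0))}")
print(f"dR/dmu_s' changes sign with radius (steeper tail, brighter core): "
      f"min {np.nanmin(d_musp):.3e}, max {np.nanmax(d_musp):.3e}")
print("\nMore scattering brightens the near field and dims the tail; more "
      "absorption only removes light. These derivatives, obtained from one "
      "stored photon set, drive the Levenberg-Marquardt Jacobian.")
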