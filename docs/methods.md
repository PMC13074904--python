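# Methods

`srrkit` implements the computational core of a spatially resolved
reflectance (SRR) imaging workflow for recovering the absorption
coefficient μa and the reduced scattering coefficient μs′ of a homogeneous
turbid medium, together with a synthetic instrument that makes the whole
chain testable without hardware. This note records the models, the
numerical choices, and what the synthetic studies do and do not demonstrate.

## Forward model

Photon transport in the sample follows standard radiative-transfer Monte
Carlo for a homogeneous slab:

* **Medium.** μa, μs′ (mm⁻¹), Henyey–Greenstein phase function with
  anisotropy g (default 0.8, giving μs = μs′/(1−g)), refractive index n
  (default 1.33, water). Slab thickness default 55.5 mm — a filled sample
  beaker — with a matched-index escape at the bottom (transmitted photons
  are counted and discarded; negligible at these thicknesses).
* **Launch.** Positions are drawn from a 2D beam-profile image (the
  measured or synthetic surface image of the incident beam, which also
  carries the instrument response), jittered uniformly within the selected
  pixel to avoid lattice artifacts; the in-medium direction is the Snell
  refraction of the 21° oblique incidence, with the incidence plane fixed
  along the +x image axis. Photons start inside the medium with weight 1:
  the specular entry loss, source power, sensor gain and collection
  efficiency are all absorbed by the scaling calibration below, mirroring
  the reference-sample calibration practice of SRR instruments.
* **Propagation.** Free paths are sampled from μs alone; absorption is
  applied as a terminal factor exp(−μa·L) over the total path length L.
  This is equivalent in expectation to per-collision albedo weighting, has
  lower variance, and makes the stored per-photon statistics (collision
  count j, path length L) an exact basis for perturbation-MC reweighting.
* **Boundaries.** At the top interface an unpolarized Fresnel reflectance
  (mean of s and p) decides reflect-back versus refract-out
  probabilistically. Every photon that refracts out is recorded at its exit
  pixel regardless of exit angle (no detection solid angle). Polarization
  is not modeled.
* **Termination.** Russian roulette (threshold 10⁻⁴ on the attenuated
  weight, survival 0.1, unbiased) plus an event cap. An optional lateral
  kill radius (0 = unbounded; the validation studies use 30 mm, the sample
  vessel radius) terminates photons that wander far outside the detector:
  low-absorption photons otherwise scatter for thousands of collisions with
  almost no chance of returning to the imaged region. The small truncation
  it introduces is shared identically by every curve a fit compares, so it
  cancels in the inversion.
* **Determinism.** A single seed reproduces images bit-exactly. The kernel
  uses an inline xorshift128+ generator with one SplitMix64-derived stream
  *per photon* (counter-based). Per-photon streams are essential for common
  random numbers: with one shared stream, a parameter change that alters a
  single photon's event count desynchronizes every later photon and
  destroys the coupling between simulations at nearby parameters.
* **Energy accounting.** Detected (top), transmitted (bottom), absorbed,
  net roulette and truncation buckets close to the launched weight to
  ~10⁻⁶ relative (floating-point accumulation only).

The beam-integrated launch and the pencil-beam-then-convolution route are
both provided and agree within Monte Carlo error; the integrated launch is
the default (one convolution of full-size images per iteration is slower).

A diffusion-dipole closed form (isotropic source at depth 1/(μa+μs′),
image source across the extrapolated boundary z_b = 2AD, partial-current
surface detection with fluence and flux coefficients computed from the
Fresnel angular moments) serves as an independent oracle in the diffusive
regime (μa ≪ μs′, ρ·μs′ ≳ 2); Monte Carlo agrees with it to a few percent
there, well within the 15 % tolerance asserted by the tests.

## Perturbation Monte Carlo

A stored simulation at (μa, μs) is reweighted exactly to perturbed
coefficients by per-photon factors
(μ̂s/μs)^j · exp(−(μ̂s−μs)L) · exp(−(μ̂a−μa)L); a μs′ perturbation at fixed g
is a μs perturbation. Derivatives of the radially binned reflectance use
finite differences of the rescaled curve with a relative step δp (default
0.05). Reweighting degrades as the perturbation grows (the factor
distribution becomes heavy-tailed); factors above 10³ trigger a warning,
and the inversion tracks the effective sample size (ESS) explicitly.

## Camera pipeline

Raw 16-bit frames carry integration time (ms), mean monitor-photodiode
voltage (V) and wavelength. Processing: flat-field division (mean-one gain
map), columnar bloom detection (saturated seeds at 0.95 of full scale,
same-column runs above 0.8 of full scale connected to a seed, dilated by
one pixel to cover partially filled run ends), backfill of masked pixels
from the radial profile evaluated at the pixel's own radius (log-linear
interpolation between annulus means; a bare annulus mean is offered too but
is biased on steep profiles by the within-annulus radial spread), exposure
stitching, normalization by t·V·pixel-area, and radial binning about the
beam-incidence pixel with bin width d_rho = one pixel (0.0361 mm).

Exposure stitching selects, per annulus, the longest of the 1×/10×/100×
frames *predicted* not to saturate anywhere in that annulus, the prediction
being the shortest (auto-exposed) frame scaled by the exposure ratio with a
10 % headroom for shot noise. Judging saturation from the long frame itself
would admit annuli whose bright side is already clipped and bloom-masked —
the surface image of an oblique beam is azimuthally asymmetric, and
backfilling the bright side from the dim side biases the annulus low.

The radial fit window runs from the first bin beyond the beam radius plus
one bin (ρ0 = ρr + d_rho) to the first bin where the 5-bin median-smoothed
curve has fallen a thousandfold relative to ρ0; beyond three decades of
attenuation the binned reflectance is noise-dominated. Curves that never
reach the bound get a truncated window and a warning.

## Calibration

On a reference sample of independently known properties, k(ρ) =
R_MC(ρ)/R_exp(ρ) (units V·ms) and its arithmetic mean k̄ over the window's
P bins (bins with non-positive experimental reflectance are excluded and P
reduced) convert experimental images to the per-photon mm⁻² scale:
R_exp,sc = k̄·R_exp. The scalar k̄ is the default (a ρ-resolved application
exists behind a flag but couples the reference sample's noise and ρ
structure into every measurement); k̄ is per-wavelength from measured
values, with any spectral fit left as a diagnostic.

## Inversion

The cost is the mean squared log₁₀ residual over the window (σ = 1),
minimized over (μa, μs′) in log space (positivity) by a damped Gauss–Newton
(Levenberg–Marquardt) iteration with bounds μa ∈ [10⁻⁶, 10],
μs′ ∈ [0.1, 20] mm⁻¹. Base-10 logs match the decade-based window rule; any
fixed base only rescales the cost.

Two design points matter at desk-scale photon budgets (10⁵–10⁶ photons per
iteration, versus effectively noise-free curves when a GPU-scale simulator
is available):

1. **Pooled pMC objective.** The model curve at the current parameters is
   a per-bin ESS-weighted combination of pMC-rescaled curves from a pool of
   anchor simulations; a fresh simulation (derived sub-seed per anchor, all
   deterministic in the fit seed) is added whenever the best ESS fraction
   at the evaluated parameters falls below 0.5, and trial steps are never
   judged on a stale rescale. The squared log residuals are debiased by the
   model curve's per-bin variance (computed from the photon weight sums of
   squares) and both the model and data logs are corrected for their
   first-order concavity bias (E[log S] < log E[S]; the data-side variance
   comes from the within-annulus pixel scatter), so the expected objective
   equals the noiseless cost and Monte Carlo noise cannot masquerade as
   misfit. Without pooling, pointwise accept/reject on single rough
   realizations traps the search in noise-scale local minima tens of
   percent from the optimum (measured during development); with it,
   closed-loop recovery reaches a few percent at 10⁵–2×10⁵ photons per
   iteration. The fit window is additionally capped at the largest annulus
   fully covered by the detector grid: corner annuli carry partial azimuth
   coverage and degenerate statistics.
2. **Seeding.** The default start is a closed-form diffusion-dipole
   least-squares pre-fit of the curve (deterministic, milliseconds), which
   lands the Monte Carlo search near the valley floor; the long curved
   valley from a fixed distant guess is what the noise-limited search
   traverses worst. `init="fixed"` restores the constant (0.01, 1.0) mm⁻¹
   start.

Steps are capped per iteration (0.5 in log-μa, 0.15 in log-μs′, matching
pMC validity), accepted only when the objective decreases, and convergence
requires a small accepted step with a small relative objective change after
the pool has been refined at the optimum. Degenerate inputs (flat or empty
curves, bound hits) return a non-converged result instead of raising.
Bins where either curve is non-positive are excluded from that iteration's
sum with P reduced.

## Origin-shift sensitivity

A one-pixel error in the assumed beam-incidence pixel is emulated by
re-binning the experimental 2D image about a displaced origin and
refitting. The first-order effect of a displacement averages out
azimuthally at large radius (it enters as cos φ), leaving a second-order
distortion concentrated just outside the beam; re-indexing the 1D curve by
one bin instead (supported when only a curve is available) shifts every
bin's log-value coherently and overstates the response by an order of
magnitude. The coefficient response is a sub-percent to ~1 % effect, so the
dedicated study renders a low-noise acquisition (6×10⁶-photon truth,
noiseless camera chain) and refits both binnings on the unshifted fit's
frozen anchor pool from a common start — the model surface is then
bit-identical for the two fits and refit scatter cancels from the reported
differences. The χ² penalty of the mismatch is carried almost entirely by
the granular structure of the (shared) measured beam profile: aligned
origins cancel that structure in the residuals, a one-pixel shift
decorrelates it. With noisy data or a perfectly smooth beam the penalty
sinks below the χ² noise floor and the shifted-to-unshifted ratio is not
resolvable.

## Synthetic instrument

The camera model emulates what the processing chain must undo: gain
(counts per mm⁻²·ms·V), Poisson shot noise, Gaussian read noise, dark
offset, 16-bit quantization, full-well clipping with a columnar "sandpile"
bloom (excess charge tops up pixels marching away from the saturated run;
charge pushed past the frame edge is lost), a ±5 % smooth flat field, ~1 %
slow photodiode drift (the mean is reported, as in the normalization
convention), and 1×/10×/100× auto-exposed triplets targeting a 30,000-count
peak. Gain, read noise and dark level are plausible placeholders chosen to
reproduce that operating regime, not measured constants of any particular
camera. The synthetic beam is a super-Gaussian core of radius 0.27 mm,
elongated along the incidence plane by 1/cos 21°, plus a power-law halo
standing in for the instrument response.

Not emulated: monochromator bandwidth, stray-light artifacts, surface
roughness or curvature, sedimentation kinetics, fluorescence, polarization,
layered media. Passing closed-loop tests therefore demonstrates the
internal consistency of the digital twin — that the pipeline and inversion
recover what the forward model produced through a realistic camera — not
immunity to those unmodeled experimental effects.

## Validation studies and problem sizes

The closed-loop study fixes seven scenarios spanning μs′ ∈ [1, 4] mm⁻¹ and
μa ∈ [5×10⁻⁴, 0.5] mm⁻¹ (g = 0.8, n = 1.33), a dilution-series analog from
a water-baseline absorber to a strongly ink-absorbing sample; the
mid-absorption scenario (0.01, 2.0) serves as the calibration reference.
Study sizes — 10⁶-photon truth renders, 2×10⁵ photons per fit iteration,
513² detector at the instrument pixel scale of 0.0361 mm — keep a full run
in minutes on one CPU core while leaving the worst-case recovery errors
(μs′ within 6 %, μa within 20 % for μa ≥ 10⁻³ mm⁻¹) limited by the method
rather than by the photon budget. `scripts/acceptance.py` re-runs these
studies end-to-end and writes the headline numbers.

## Known limitations

* Perturbations of g, n or thickness are not supported by the pMC
  machinery; g is never fitted (a ±10 % g sensitivity is a known small
  effect but outside scope).
* The χ² landscape is only explored locally; the well-posedness of the
  two-parameter problem (no local minima at realistic windows) is relied
  upon, as in practice.
* The diffusion seed can start the search poorly for extreme
  absorption-to-scattering ratios; bounds plus the trust caps keep the
  search stable, but pathological inputs return non-converged results.
* The bloom model is columnar and deterministic per column; real sensors
  leak a little charge across columns too.
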