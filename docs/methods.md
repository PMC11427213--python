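# Methods

This note documents the models, parameter choices and numerical details
behind `silmas`, and what the synthetic-phantom tests do and do not
demonstrate about real data.

## Coordinate and data model

A volume is a Z-ordered stack of 2D planes; rows are Y (the modulation
axis of the structured light sheet), columns are X (the propagation axis
of the illumination), and the plane index is Z (the detection axis). All
computation is in floating point; integer TIFF input is promoted on
read, and the output dtype (with clip or rescale semantics) is chosen at
write time, because ratio images and compensation gains are inherently
non-integer. Planes are streamed in chunks so peak memory is bounded by
the chunk size, not the stack.

## Three-phase demodulation

With phases at 0°/120°/240°, `I_k = A + B cos(θ + φ_k)` gives pairwise
differences whose squares sum to `(9/2)B²`, so the
root-of-sum-of-squared-differences estimator with prefactor **2/3**
returns `√2·B`; the phase-plane mean returns `A` exactly (cosines at
120° spacing sum to zero). The prefactor is exposed as the named
constant `SI_PREFACTOR` because a typographically similar constant,
`√2/3`, circulates in the literature and returns `B` instead; all tests
in this package pin the `√2·B` convention. Demodulation runs in float64:
squared differences of 16-bit counts overflow 32-bit integer ranges.

## Destriping

### Why bandpass, and why log-domain

Plain wavelet-Fourier filtering damps low frequencies along the stripe
axis in the vertical detail coefficients. It removes an *absolute*
stripe amplitude estimated from the whole plane, so in a high-contrast
field it systematically overshoots in dim regions and undershoots in
bright ones, imprinting counter-stripes. Splitting the plane into
multiplicative bands (ratios to Gaussian local means) normalises stripe
strength to local intensity before filtering.

One further step matters. A shadow stripe is a multiplicative
attenuation: in a band ratio it appears as `structure(y) × stripe(x)`.
Filtering that product linearly leaves cross-terms away from the zero
stripe-axis frequency, and the filter then undercorrects near region
boundaries; on our two-region phantom the suppression ceiling was ~76%
with dark-region artifact energy five times the unfiltered level. Taking
the logarithm of each band ratio makes the stripe additive and exactly
separable (`log structure + log stripe`), after which the linear
wavelet-Fourier machinery removes it by the same relative amount
everywhere, and the exponential return guarantees positive filtered
bands. Measured on the same phantom this raises suppression to ~93% and
*reduces* dark-region stripe energy below the unfiltered level. The
public `wavelet_fourier_filter_band` operation remains strictly linear;
`destripe_plane` applies it to `log(ratio)`.

### Parameters

- `gauss_sizes` (px; default `(15, 801)`): per-band local-mean kernel
  sizes, σ_spatial = size/4 truncated at 3σ. The first size bounds the
  smallest dark structure the high-pass band protects; the *last* size
  sets a hard floor on achievable suppression, because the terminal
  local-mean image is never filtered and retains a smoothed stripe dip
  of relative depth ≈ `depth·width/(√(2π)·size/4)`. For 30%-deep,
  16 px-wide stripes, a 801 px final kernel leaves ≈ 2% residual.
- `dec_levels` (default `(1..6, 1..11)`): decomposition levels filtered
  per band. The filter only touches detail coefficients; whatever stripe
  energy lies below the coarsest filtered scale survives in the
  approximation plane. A super-Gaussian stripe has a flat low-frequency
  tail, so levels must extend well past `log2(width)`: at levels 1..4 a
  width-8 stripe keeps ~45% of its column-mean dip; levels 1..7 reduce
  it to ~6%. With symmetric padding the coefficient planes converge to
  roughly the filter length instead of halving forever, so deep levels
  remain exactly invertible; the level-feasibility error triggers only
  when a coefficient plane would fall below 2 samples.
- `wavelet` (default `db45`): high-order Daubechies for sharp
  level-frequency separation. PyWavelets ships filters only to `db38`;
  higher orders are synthesised in-package by spectral factorisation of
  the Daubechies polynomial in 120-digit arithmetic (mpmath), which
  reproduces the builtin `db4`/`db38` filters bit-for-bit and
  round-trips random 512² planes at ~1e−15 relative.
- `sigma` (frequency bins; default auto): width of the Gaussian
  high-pass damping. `g(0) = 0` always, so perfectly straight stripes
  are removed at any σ; σ matters for stripes that wander or tilt,
  spreading energy off zero frequency. The auto estimator fits a
  Gaussian (by second moment) to the contiguous central peak of the
  stripe-axis power profile of the vertical coefficients, clamped to
  [1, n/4] bins, falling back to 3 bins for all-zero coefficients. For
  straight synthetic stripes it returns ~1 bin independent of stripe
  width — the stripe-axis spectrum of a straight stripe is a delta, so
  no width dependence exists to estimate — and grows with the wander
  amplitude of the stripe path, which is the physically relevant driver.
- Boundary handling: symmetric (half-point) padding project-wide; no
  de-rotation of slightly tilted stripes (σ absorbs them). Filtering is
  strictly 2D per plane: stripes are one-dimensional artifacts continuous
  only within a plane, and 3D filtering would couple unrelated planes.

With a tissue mask, only masked pixels take the filtered values, so the
filter cannot imprint line structure on pure background noise.

### Distortion accounting

`energy_change_ratio` (ECR) quantifies total change. On a fixed striped
input, ECR grows with σ and with the number of filtered levels —
strictly so along the linear filtering path; through the multiplicative
band recombination sub-percent inversions can occur at sub-bin σ, which
is why the end-to-end monotonicity test uses a coarse σ grid with 1%
slack. The package's chosen two-band configuration distorts less than a
wide-σ single-band filter of the same coverage while matching its
suppression — the sharp-versus-wide trade-off that motivates per-level
damping in the first place.

## Segmentation

Per plane: Gaussian noise suppression (radius 5 px, implemented as
σ = radius/2), Otsu bootstrap threshold, depth map from the cumulative
mask sum along X, exponential fit to the median intensity per depth,
division by the decay, and one re-thresholding iteration (default
`max_iterations = 2`) that recovers tissue the bootstrap missed at
depth; the refreshed depth map feeds the final compensation. Median
profile points within one smoothing radius of the tissue border are
excluded from the fit — they are blurred toward background and would
bias the rate low (measured ~10% on half-space phantoms). The final
threshold is the lower edge of the first histogram bin after the
background peak whose 3-bin-smoothed count rounds to zero; the
background peak is the *first* prominent mode (≥5% of the maximum), not
necessarily the tallest, because after compensation the tissue mode can
out-grow the background mode. If no empty bin exists, the minimum
between the first two modes is used (logged). Morphology: closing with
a radius-3 disk, hole filling, removal of components under 64 px —
values the underlying procedure leaves open; they are deliberately
conservative for 2 µm-voxel data. The optional previous-plane coupling
decides pixels within ±δ of the threshold by the neighbouring plane's
mask (δ defaults to 10% of the threshold).

## Extinction calibration and compensation

Depth maps: excitation depth is the inclusive cumulative mask sum along
+X (the incident sheet's NA is low and neglected); emission depth uses
the recurrence `D(k) = blur(D(k−1)) + mask(k)` toward the detector,
where `blur` is a normalised disk of radius 1 (≈10° collection
half-angle at these voxel sizes) — radius 0 degenerates to a plain
cumulative sum, which is also what the phantom oracles use since the
generator applies no NA blur.

Power steps are estimated from the data, not the nominal schedule
(nominal laser powers are unreliable at the low end): the log-ratio of
forward to backward moving means (window 20 planes) of the per-plane
tissue signal forms a ramp of half-width `window` around a step and a
constant under a smooth trend; a running-median baseline removes the
trend for detection, and each step factor is measured against a baseline
taken just outside the ramp so smooth decay cancels exactly. A
user-supplied schedule switches to anchored mode: factors are measured
at the given planes, and the measured values win.

The fit bins tissue voxels by integer (depth_x, depth_z), normalises bin
means to the maximum bin, and solves the log-linear model by least
squares weighted with bin occupancy (deterministic, seed-free — the
model is linear in its parameters, so nothing is gained from a nonlinear
optimiser). Bins under 10 voxels are excluded. Only the combined
effective extinction per axis is identifiable; no absorption/scattering
split is attempted. `boundary_erosion_px` erodes the segmentation
in-plane before selecting fit voxels (depth maps keep the full mask):
segmented boundaries overshoot real tissue by roughly the noise-filter
radius plus the closing radius, and those partial-volume voxels
otherwise contaminate the shallowest bins — on an SNR-20 phantom this
contamination biased μx from 0.008 to 0.002 per voxel; with erosion 8 px
the fit recovers both coefficients within 5%. Compensation multiplies by
`exp(μx·dx + μz·dz)` capped at `max_gain = 50` (capped voxels are
counted): at depth the signal is noise-dominated and unbounded gain
would amplify noise without recovering information.

Stage order is enforced at configuration time: segmentation → destriping
∥ calibration → compensation. Calibration runs on pre-destriping data
(its per-bin averaging tolerates stripes), while compensation must
follow destriping, or it would amplify the noise inside shadow stripes.

## The synthetic module

Phantoms emulate exactly the structure the pipeline assumes: sinusoidal
phase triplets (modulation along Y), super-Gaussian shadow stripes
multiplying columns (`1 − depth·exp(−((x−c)/(w/2))^p)`, default order
p = 4, so `width_px` is the visually apparent width), dual-axis
exponential attenuation inside a half-space or ellipsoid mask, hard-
sphere puncta of radius 1–3 voxels as stand-ins for sparse bright
aggregates, a transverse illumination profile, stepped Z power, and
Gaussian or Poisson-Gaussian (sCMOS-like) noise. Generators are
deterministic under a fixed seed; emission depth is accumulated toward
increasing plane index by default (flippable).

What the phantoms do **not** emulate: optical PSF blur and axial-sweep
timing, multiple-scattering halos, spatially varying extinction between
anatomical regions, tile seams, and stripe profiles other than
super-Gaussian. Passing tests therefore demonstrate correctness of the
algorithms under the stated physical model and their noise robustness at
the stated SNRs — not performance on tissue whose optical properties
deviate from that model (e.g. strongly heterogeneous clearing). The
global extinction model in particular assumes near-uniform optical
properties; regional calibration is out of scope.

## Problem sizes and tolerances

The verification suite uses 512² planes for destriping (two stripe
widths, 4 and 16 px, 30% deep), 200×256×256 stacks at SNR 10 for
segmentation (Dice ≥ 0.95 on ≥ 95% of planes; per-plane decay rate
within 10%), and 200×256×256 phantoms at SNR 20 over 20 seeded
replicates for extinction recovery (both coefficients within 5%;
noiseless recovery to 1e−4 and compensated depth-profile CV below 1%
noiseless / 10% noisy). Wavelet round trips are checked at 1e−8 relative
for db4–db45 and levels 1–6; pipeline reruns must be byte-identical.
These sizes keep the full suite and the acceptance script in the
low-minutes range on one CPU while leaving each statistical margin wide
(observed: suppression ≈ 93% vs the 90% bar, extinction errors
< 0.1% vs the 5% bar).
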