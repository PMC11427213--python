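# silmas

Post-processing for structured-illumination light-sheet fluorescence
microscopy of cleared tissue: three-phase demodulation,
bandpass-wavelet-Fourier destriping, extinction-aware tissue
segmentation, and Beer-Lambert light-attenuation compensation — with a
synthetic-phantom module so every stage is verifiable without real data.

## Who this is for

Light-sheet microscopy of cleared samples (whole mouse-brain hemispheres
at micron-scale voxels) with optical scattered-light suppression yields
high-contrast volumes, but precisely because multiply scattered light is
removed, the remaining physical artifacts stand out: shadow stripes cast
along the illumination axis, strong exponential signal attenuation with
tissue depth on both the excitation and emission paths, and
illumination inhomogeneity (transverse sheet profile, stepped laser
power along the scan). This package implements the corresponding
post-processing chain for Z-ordered stacks of 2D planes (multi-page TIFF
or TIFF series), streaming planes so stacks far larger than memory can
be processed.

Axis convention throughout: plane rows = Y (modulation axis), plane
columns = X (light-propagation axis), plane index = Z (detection axis).

## The methods

**Demodulation.** Each plane is recorded three times with the sinusoidal
illumination structure phase-shifted by 120°. The demodulated image is

    I_SI = (2/3) · sqrt((I0−I120)² + (I0−I240)² + (I120−I240)²),

which for the model `I_k = A + B·cos(θ + φ_k)` equals `√2·B`
independently of θ; the conventional image is the plane mean, `A`.

**Destriping.** Shadow stripes are vertical structures: constant along
the propagation axis of a plane, so their energy concentrates at zero
frequency along that axis inside the *vertical* detail coefficients of a
2D wavelet decomposition. A Gaussian high-pass `g(f) = 1 − exp(−f²/2σ²)`
damps those frequencies level by level (wavelet-Fourier filtering). To
keep the filter honest across bright and dark regions, the plane is
first split into multiplicative frequency bands — ratios of successively
Gaussian-smoothed versions of the image — so stripe strength is
normalised to local intensity; each band ratio is filtered on its
logarithm (stripes are multiplicative attenuations, additive and exactly
separable in log space) and the filtered bands are multiplied back with
the final local-mean image. Distortion is tracked by the energy change
ratio `ECR = Σ(I_o − I_f)²/ΣI_o²`.

**Segmentation.** A global threshold fails on strongly attenuated
planes, so each plane is pre-compensated first: smooth, bootstrap
threshold (Otsu), build a propagation depth map from the cumulative mask
sum along X, fit `exp(−rate·depth)` to the median intensity per depth,
divide it out, and iterate. The final threshold is the first empty
histogram bin after the background peak; morphology cleans the mask.

**Extinction compensation.** With scattered light suppressed, tissue
signal follows a dual-axis Beer-Lambert law,
`I = A·exp(−μx·x − μz·z)`, where x and z are per-voxel cumulative tissue
thicknesses along the excitation (X) and emission (Z) paths (the
emission depth includes a cumulative circular blur approximating the
collection-NA cone). After dividing out known illumination variations —
the measured Y sheet profile and data-estimated Z power steps — tissue
voxels are binned by integer depth pair, bin means are fitted log-linearly
by weighted least squares, and every voxel is multiplied by the inverse
decay, capped to bound noise amplification at depth.

The stage order is contractual: segmentation first; destriping and
extinction *calibration* in parallel on pre-destriping data; extinction
*compensation* last, applied to the destriped planes.

## Worked example

Calibrate and compensate a synthetic attenuated volume with a hidden
×1.3 laser-power step:

```python
import numpy as np
from silmas import (PhantomVolumeSpec, NoiseModel, make_attenuated_volume,
                    apply_acquisition_effects, segment_plane, estimate_z_power_steps,
                    IlluminationCorrections, apply_illumination_corrections,
                    build_depth_maps, fit_extinction, compensate_volume)

spec = PhantomVolumeSpec(shape=(60, 64, 96), mu_x=0.010, mu_z=0.005,
                         noise_model=NoiseModel("gaussian", sigma=30.0), seed=4)
vol, truth_mask, *_ = make_attenuated_volume(spec)
acquired = apply_acquisition_effects(vol, None, [(30, 1.3)])

masks = np.stack([segment_plane(acquired[k]).mask for k in range(60)])
z_power, steps = estimate_z_power_steps(acquired, masks, window=8)
print(f"detected power steps: {[(p, round(f, 3)) for p, f in steps]}")

corr = IlluminationCorrections.from_measured(np.ones(64), z_power)
corrected = apply_illumination_corrections(acquired, corr)
depths = build_depth_maps(masks, na_blur_radius=0)
model = fit_extinction(corrected, depths, masks, boundary_erosion_px=8)
print(f"mu_x = {model.mu_x:.5f} /voxel   (truth 0.01000)")
print(f"mu_z = {model.mu_z:.5f} /voxel   (truth 0.00500)")
```

prints

```
detected power steps: [(30, 1.299)]
mu_x = 0.01000 /voxel   (truth 0.01000)
mu_z = 0.00500 /voxel   (truth 0.00500)
```

The ×1.3 power step injected at plane 30 is found from the data alone
(moving-mean ratio of tissue signal), and both effective extinction
coefficients are recovered to three significant figures at this noise
level. `compensate_volume` then flattens the tissue intensity back to
its surface value.

A command-line interface mirrors the library
(`silmas simulate|reconstruct|destripe|segment|calibrate-extinction|compensate|pipeline`),
and `silmas pipeline --config run.yaml` executes the whole chain with a
run manifest recording configuration, hashes and warnings.

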