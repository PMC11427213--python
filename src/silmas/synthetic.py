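"""Ground-truthed phantom generators for structured-illumination light-sheet stacks.

Every downstream stage of the pipeline (demodulation, destriping,
segmentation, extinction compensation) assumes a particular physical
structure in the data: sinusoidal phase-modulated triplets, shadow
stripes cast along the illumination axis, dual-axis Beer-Lambert
attenuation inside tissue, a transverse illumination profile, and
stepped laser power along the detection axis.  The generators here
produce volumes with exactly that structure together with the ground
truth used as test oracles.

Axis convention (project-wide): axis 0 of a plane is Y (the modulation
axis), axis 1 is X (light-propagation axis), plane index is Z
(detection axis).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StripeSpec",
    "NoiseModel",
    "PhantomVolumeSpec",
    "PhaseTriplet",
    "make_phase_triplet",
    "add_stripes",
    "make_attenuated_volume",
    "apply_acquisition_effects",
]

PHASES = (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)


@dataclass(frozen=True)
class PhaseTriplet:
    """Three co-registered planes recorded at modulation phases 0/120/240 degrees."""

    i0: np.ndarray
    i120: np.ndarray
    i240: np.ndarray

    def __post_init__(self) -> None:
        if not (self.i0.shape == self.i120.shape == self.i240.shape):
            raise ValueError("phase triplet planes must share one shape")
        for p in (self.i0, self.i120, self.i240):
            if np.any(np.asarray(p) < 0):
                raise ValueError("phase triplet intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.i0.shape

    def planes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.i0, self.i120, self.i240)


@dataclass(frozen=True)
class StripeSpec:
    """One super-Gaussian shadow stripe.

    The stripe multiplies every image row by
    ``1 - depth * exp(-((x - center_px) / (width_px / 2)) ** order)``,
    so ``width_px`` is the visually apparent full width and ``depth`` the
    fractional attenuation at the stripe centre.
    """

    center_px: float
    width_px: float
    depth: float
    order: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth < 1.0:
            raise ValueError("stripe depth must lie in [0, 1)")
        if self.width_px < 1:
            raise ValueError("stripe width must be >= 1 pixel")
        if self.order < 2 or self.order % 2:
            raise ValueError("super-Gaussian order must be an even integer >= 2")

    def profile(self, nx: int) -> np.ndarray:
        x = np.arange(nx, dtype=float)
        u = (x - self.center_px) / (self.width_px / 2.0)
        return 1.0 - self.depth * np.exp(-(u ** self.order))


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise: ``none``, ``gaussian`` (additive), or ``poisson_gaussian``.

    ``poisson_gaussian`` mimics an sCMOS camera: shot noise with the given
    electron ``gain`` (counts per photo-electron) plus Gaussian read noise
    of standard deviation ``sigma`` counts.
    """

    kind: str = "none"
    sigma: float = 0.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "poisson_gaussian"):
            raise ValueError(f"unknown noise model {self.kind!r}")
        if self.sigma < 0 or self.gain <= 0:
            raise ValueError("noise sigma must be >= 0 and gain > 0")

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return signal
        if self.kind == "gaussian":
            return signal + rng.normal(0.0, self.sigma, signal.shape)
        shot = self.gain * rng.poisson(np.maximum(signal, 0.0) / self.gain)
        return shot + rng.normal(0.0, self.sigma, signal.shape)


@dataclass(frozen=True)
class PhantomVolumeSpec:
    """Specification of a Beer-Lambert attenuated tissue phantom.

    ``mu_x`` is the effective excitation-axis extinction per voxel,
    ``mu_z`` the emission-axis extinction per voxel.  Inside the tissue
    mask the noiseless signal is
    ``base_intensity * exp(-mu_x * depth_x - mu_z * depth_z)`` where the
    depth maps count cumulative tissue thickness along +X and (by default)
    toward increasing plane index.  ``puncta_density`` adds small bright
    spheres (objects per 1000 voxels) standing in for sparse high-intensity
    aggregates.
    """

    shape: tuple[int, int, int]  # (nz, ny, nx)
    voxel_size_um: float = 2.0
    tissue_mask_kind: str = "half_space"
    mu_x: float = 0.0
    mu_z: float = 0.0
    base_intensity: float = 1000.0
    puncta_density: float = 0.0
    puncta_intensity_factor: float = 3.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    entry_px: int | None = None  # half-space tissue entry column; default nx // 8
    emission_toward_low_z: bool = False

    def __post_init__(self) -> None:
        nz, ny, nx = self.shape
        if min(nz, ny, nx) < 1:
            raise ValueError("all volume dimensions must be >= 1")
        if self.mu_x < 0 or self.mu_z < 0:
            raise ValueError("extinction coefficients must be >= 0")
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be > 0")
        if self.tissue_mask_kind not in ("half_space", "ellipsoid"):
            raise ValueError(f"unknown tissue_mask_kind {self.tissue_mask_kind!r}")


def make_phase_triplet(
    dc: np.ndarray,
    amplitude: np.ndarray,
    period_px: float,
    phase0: float = 0.0,
) -> PhaseTriplet:
    """Generate three sinusoidally modulated planes from DC and amplitude maps.

    I_k(y, x) = dc(y, x) + amplitude(y, x) * cos(2*pi*y / period_px + phase0 + phi_k)
    with phi_k in {0, 120, 240} degrees, modulation along Y (axis 0).
    The mean of the three planes equals ``dc`` exactly because cosines at
    120-degree spacing sum to zero.
    """
    dc = np.asarray(dc, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    amplitude, dc = np.broadcast_arrays(amplitude, dc)
    if period_px <= 2:
        raise ValueError("modulation period must exceed 2 px (Nyquist)")
    if np.any(amplitude > dc):
        raise ValueError("amplitude must not exceed dc anywhere (negative intensities)")
    if np.any(amplitude < 0) or np.any(dc < 0):
        raise ValueError("dc and amplitude must be non-negative")
    y = np.arange(dc.shape[0], dtype=float)[:, None]
    theta = 2.0 * math.pi * y / period_px + phase0
    planes = [dc + amplitude * np.cos(theta + phi) for phi in PHASES]
    return PhaseTriplet(*planes)


def add_stripes(img: np.ndarray, stripes: list[StripeSpec]) -> np.ndarray:
    """Attenuate image columns by a product of super-Gaussian shadow stripes."""
    img = np.asarray(img, dtype=float)
    nx = img.shape[1]
    factor = np.ones(nx)
    for s in stripes:
        if not 0 <= s.center_px < nx:
            raise ValueError(f"stripe center {s.center_px} outside image width {nx}")
        factor *= s.profile(nx)
    return img * factor[None, :]


def _tissue_mask(spec: PhantomVolumeSpec) -> np.ndarray:
    nz, ny, nx = spec.shape
    if spec.tissue_mask_kind == "half_space":
        entry = spec.entry_px if spec.entry_px is not None else nx // 8
        if entry >= nx:
            raise ValueError("half-space entry beyond volume extent: mask empty")
        mask = np.zeros(spec.shape, dtype=bool)
        mask[:, :, entry:] = True
        return mask
    z, y, x = np.ogrid[0:nz, 0:ny, 0:nx]
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    az, ay, ax = max(0.42 * nz, 0.5), max(0.42 * ny, 0.5), max(0.42 * nx, 0.5)
    mask = (((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2) <= 1.0
    if not mask.any():
        raise ValueError("ellipsoid mask empty for this shape")
    return mask


def make_attenuated_volume(
    spec: PhantomVolumeSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a Beer-Lambert attenuated volume.

    Returns ``(volume, truth_mask, truth_depth_x, truth_depth_z)``.  Depth
    maps are the cumulative tissue thickness (in voxels, counting the
    current voxel) along +X for the excitation path and along the emission
    path toward the detector.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _tissue_mask(spec)
    maskf = mask.astype(float)
    depth_x = np.cumsum(maskf, axis=2)
    if spec.emission_toward_low_z:
        depth_z = np.cumsum(maskf[::-1], axis=0)[::-1]
    else:
        depth_z = np.cumsum(maskf, axis=0)
    signal = np.where(
        mask,
        spec.base_intensity * np.exp(-spec.mu_x * depth_x - spec.mu_z * depth_z),
        0.0,
    )
    if spec.puncta_density > 0:
        n_puncta = int(round(spec.puncta_density * mask.sum() / 1000.0))
        idx = np.flatnonzero(mask)
        if n_puncta > 0 and idx.size:
            centers = idx[rng.integers(0, idx.size, n_puncta)]
            boost = np.ones(spec.shape)
            nz, ny, nx = spec.shape
            for c in centers:
                cz, cy, cx = np.unravel_index(c, spec.shape)
                r = int(rng.integers(1, 4))  # hard spheres, radius 1-3 voxels
                zsl = slice(max(cz - r, 0), min(cz + r + 1, nz))
                ysl = slice(max(cy - r, 0), min(cy + r + 1, ny))
                xsl = slice(max(cx - r, 0), min(cx + r + 1, nx))
                z, y, x = np.ogrid[zsl, ysl, xsl]
                ball = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= r * r
                sub = boost[zsl, ysl, xsl]
                sub[ball] = spec.puncta_intensity_factor
            signal = signal * np.where(mask, boost, 1.0)
    volume = spec.noise_model.apply(signal, rng)
    return volume, mask, depth_x, depth_z


def apply_acquisition_effects(
    volume: np.ndarray,
    y_profile: np.ndarray | None = None,
    power_steps: list[tuple[int, float]] | None = None,
) -> np.ndarray:
    """Imprint the transverse illumination profile and stepped laser power.

    Each plane ``k`` is multiplied along Y by ``y_profile`` and by the
    cumulative product of all step factors whose plane index is <= k,
    emulating the incremental illumination-power increases used to
    pre-compensate attenuation along the detection axis.
    """
    volume = np.asarray(volume, dtype=float)
    nz, ny, _ = volume.shape
    out = volume.copy()
    if y_profile is not None:
        y_profile = np.asarray(y_profile, dtype=float)
        if y_profile.shape != (ny,):
            raise ValueError(f"y_profile length {y_profile.size} != ny {ny}")
        if np.any(y_profile <= 0):
            raise ValueError("y_profile must be strictly positive")
        out *= y_profile[None, :, None]
    if power_steps:
        indices = [int(i) for i, _ in power_steps]
        if indices != sorted(indices):
            raise ValueError("power step indices must be ascending")
        scale = np.ones(nz)
        for i, factor in power_steps:
            if factor <= 0:
                raise ValueError("power step factors must be positive")
            scale[i:] *= factor
        out *= scale[:, None, None]
    return out
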