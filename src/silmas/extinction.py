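"""Global dual-axis Beer-Lambert extinction calibration and compensation.

In near-homogeneous cleared tissue the excitation light decays
exponentially with the tissue thickness it has traversed along the
propagation axis (X), and the emitted fluorescence decays again along
its path toward the detector (Z).  For a voxel at excitation depth x and
emission depth z (in voxels of tissue),

    I(x, z) = A * exp(-mu_x * x - mu_z * z),

where the amplitude A absorbs the incident intensity, fluorophore
density and quantum yield.  Only the combined effective extinction per
axis is identifiable — the split into absorption and scattering is not.

Calibration proceeds by mapping every tissue voxel to its two
penetration depths (the emission depth including a cumulative circular
blur approximating the collection NA cone), removing known illumination
variations (transverse sheet profile, stepped laser power), aggregating
mean intensity per integer depth pair, and fitting the log-linear model
by weighted least squares.  Compensation multiplies each voxel by the
inverse decay, capped to bound noise amplification at depth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

__all__ = [
    "DepthMaps",
    "ExtinctionModel",
    "IlluminationCorrections",
    "build_depth_maps",
    "estimate_z_power_steps",
    "apply_illumination_corrections",
    "fit_extinction",
    "compensate_volume",
]

logger = logging.getLogger(__name__)


@dataclass
class DepthMaps:
    """Per-voxel cumulative tissue thickness along each optical path (voxels).

    ``depth_x`` counts masked voxels along +X up to and including the
    current one; ``depth_z`` accumulates along the emission axis toward
    the detector, broadened each plane by a circular blur that mimics the
    collection-NA cone.
    """

    depth_x: np.ndarray
    depth_z: np.ndarray

    def __post_init__(self) -> None:
        if self.depth_x.shape != self.depth_z.shape:
            raise ValueError("depth maps must share one shape")


@dataclass
class ExtinctionModel:
    """Fitted amplitude and effective per-voxel decay coefficients.

    ``mu_x`` applies to the excitation path, ``mu_z`` to the emission
    path; ``amplitude`` is on the normalized (max-bin = 1) scale;
    ``fit_residual`` is the weighted RMS of log-domain residuals.
    """

    amplitude: float
    mu_x: float
    mu_z: float
    fit_residual: float
    n_bins: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.mu_x < 0 or self.mu_z < 0:
            raise ValueError("decay coefficients must be >= 0")

    def to_json(self, path, extra: dict | None = None) -> None:
        payload = {
            "amplitude": self.amplitude,
            "mu_x": self.mu_x,
            "mu_z": self.mu_z,
            "fit_residual": self.fit_residual,
            "n_bins": self.n_bins,
        }
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ExtinctionModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            amplitude=d["amplitude"],
            mu_x=d["mu_x"],
            mu_z=d["mu_z"],
            fit_residual=d.get("fit_residual", 0.0),
            n_bins=d.get("n_bins", 0),
        )


@dataclass
class IlluminationCorrections:
    """Known illumination variations to divide out before calibration.

    ``y_profile`` is the transverse sheet profile (normalized to mean 1,
    length ny); ``z_power`` the per-plane power scale (normalized to
    plane 0 = 1, length nz).
    """

    y_profile: np.ndarray
    z_power: np.ndarray

    def __post_init__(self) -> None:
        self.y_profile = np.asarray(self.y_profile, dtype=float)
        self.z_power = np.asarray(self.z_power, dtype=float)
        if np.any(self.y_profile <= 0) or np.any(self.z_power <= 0):
            raise ValueError("illumination corrections must be strictly positive")
        if abs(self.y_profile.mean() - 1.0) > 1e-6:
            raise ValueError("y_profile must be normalized to mean 1")
        if abs(self.z_power[0] - 1.0) > 1e-9:
            raise ValueError("z_power must be normalized to plane 0 = 1")

    @classmethod
    def from_measured(cls, y_profile, z_power) -> "IlluminationCorrections":
        """Normalize a measured profile/schedule into valid corrections."""
        y = np.asarray(y_profile, dtype=float)
        z = np.asarray(z_power, dtype=float)
        return cls(y / y.mean(), z / z[0])


def _disk_kernel(radius: int) -> np.ndarray:
    k = morphology.disk(radius).astype(float)
    return k / k.sum()


def build_depth_maps(mask_volume: np.ndarray, na_blur_radius: int = 1) -> DepthMaps:
    """Map every voxel to its excitation- and emission-path tissue depth.

    Excitation depth is the cumulative mask sum along +X (the incident
    sheet's NA is low enough to neglect).  Emission depth uses the
    recurrence D(k) = circular_blur(D(k-1)) + mask(k) accumulated toward
    the detector: each traversed plane spreads the accumulated thickness
    over the collection cone (disk of ``na_blur_radius``) before adding
    the local tissue.  Radius 0 reduces to a plain cumulative sum.
    """
    mask = np.asarray(mask_volume).astype(bool)
    maskf = mask.astype(float)
    depth_x = np.cumsum(maskf, axis=2)
    depth_z = np.empty_like(maskf)
    if na_blur_radius > 0:
        kernel = _disk_kernel(na_blur_radius)
        acc = np.zeros(mask.shape[1:])
        for k in range(mask.shape[0]):
            acc = ndimage.convolve(acc, kernel, mode="nearest") + maskf[k]
            depth_z[k] = acc
    else:
        np.cumsum(maskf, axis=0, out=depth_z)
    return DepthMaps(depth_x=depth_x, depth_z=depth_z)


def estimate_z_power_steps(
    volume: np.ndarray,
    mask_volume: np.ndarray,
    window: int = 20,
    step_threshold: float = 0.05,
    known_step_planes: list[int] | None = None,
) -> tuple[np.ndarray, list[tuple[int, float]]]:
    """Isolate discrete illumination-power shifts from per-plane tissue means.

    For each plane the ratio of the forward to the backward moving mean of
    the tissue signal (``window`` planes each way) is computed; a step
    produces a localized peak in this ratio while smooth biological trends
    (e.g. gradual attenuation along Z) shift it uniformly and are removed
    by a running-median baseline.  Detected factors are the
    baseline-corrected ratios at the peaks; the returned per-plane scale is
    their cumulative product, normalized to plane 0 = 1.

    ``known_step_planes`` switches from free detection to anchored mode:
    factors are measured at exactly the given plane indices (the measured,
    not the nominal, factors win on conflict).
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask_volume).astype(bool)
    nz = volume.shape[0]
    if window < 2:
        raise ValueError("window must be >= 2")
    if nz < 2 * window:
        raise ValueError(f"stack of {nz} planes shorter than 2*window={2*window}")
    means = np.array(
        [volume[k][mask[k]].mean() if mask[k].any() else np.nan for k in range(nz)]
    )
    if np.isnan(means).any():
        idx = np.arange(nz)
        good = ~np.isnan(means)
        if not good.any():
            raise ValueError("no plane contains tissue")
        means = np.interp(idx, idx[good], means[good])
    log_ratio = np.zeros(nz)
    for k in range(window, nz - window + 1):
        fwd = means[k : k + window].mean()
        bwd = means[k - window : k].mean()
        log_ratio[k] = np.log(fwd / bwd)
    baseline = ndimage.median_filter(log_ratio, size=4 * window + 1, mode="nearest")
    detrended = log_ratio - baseline

    def _step_factor(k: int) -> float:
        # the moving-mean ratio forms a ramp of half-width `window` around a
        # step; measure against a baseline taken just outside the ramp so a
        # smooth decay trend cancels exactly
        left = log_ratio[max(k - 2 * window, window) : max(k - window, window)]
        right = log_ratio[
            min(k + window, nz - window) : min(k + 2 * window, nz - window + 1)
        ]
        outside = np.concatenate([left, right])
        local_base = np.median(outside) if outside.size else baseline[k]
        return float(np.exp(log_ratio[k] - local_base))

    detections: list[tuple[int, float]] = []
    if known_step_planes is not None:
        for k in known_step_planes:
            detections.append((int(k), _step_factor(int(k))))
    else:
        candidate = np.abs(detrended) > np.log1p(step_threshold)
        k = window
        while k <= nz - window:
            if candidate[k]:
                group = slice(k, min(k + window, nz - window + 1))
                local = np.abs(detrended[group])
                peak = k + int(np.argmax(local))
                detections.append((peak, _step_factor(peak)))
                k = peak + window
            else:
                k += 1
    factors = np.ones(nz)
    for plane, f in detections:
        factors[plane:] *= f
    factors /= factors[0]
    return factors, detections


def apply_illumination_corrections(
    volume: np.ndarray, corr: IlluminationCorrections
) -> np.ndarray:
    """Divide out the transverse sheet profile and per-plane power scale."""
    volume = np.asarray(volume, dtype=float)
    nz, ny, _ = volume.shape
    if corr.y_profile.size != ny:
        raise ValueError(f"y_profile length {corr.y_profile.size} != ny {ny}")
    if corr.z_power.size != nz:
        raise ValueError(f"z_power length {corr.z_power.size} != nz {nz}")
    return volume / (corr.y_profile[None, :, None] * corr.z_power[:, None, None])


def fit_extinction(
    volume: np.ndarray,
    depths: DepthMaps,
    mask_volume: np.ndarray,
    min_bin_count: int = 10,
    boundary_erosion_px: int = 0,
) -> ExtinctionModel:
    """Fit the dual-axis exponential decay to depth-binned mean intensities.

    Tissue voxels are binned by integer (depth_x, depth_z); the mean
    intensity of each occupied bin realises the per-depth aggregation of
    the model, normalized to the maximum bin.  The log-linear model
    ``log I = log A - mu_x dx - mu_z dz`` is solved by least squares
    weighted with bin occupancy; bins with fewer than ``min_bin_count``
    voxels are excluded.

    ``boundary_erosion_px`` erodes the mask in-plane before selecting the
    voxels that inform the fit (the depth maps are untouched): segmented
    boundaries overshoot the tissue by roughly the segmentation's noise
    filter radius, and those partial-volume voxels would contaminate the
    shallowest depth bins.
    """
    mask = np.asarray(mask_volume).astype(bool)
    if boundary_erosion_px > 0:
        selem = morphology.disk(boundary_erosion_px)
        mask = np.stack([morphology.erosion(m, selem) for m in mask])
    if not mask.any():
        raise ValueError("mask is empty; nothing to calibrate on")
    vals = np.asarray(volume, dtype=float)[mask]
    dx = np.rint(depths.depth_x[mask]).astype(np.int64)
    dz = np.rint(depths.depth_z[mask]).astype(np.int64)
    nx_bins, nz_bins = dx.max() + 1, dz.max() + 1
    flat = dx * nz_bins + dz
    counts = np.bincount(flat, minlength=nx_bins * nz_bins)
    sums = np.bincount(flat, weights=vals, minlength=nx_bins * nz_bins)
    occupied = counts >= max(min_bin_count, 1)
    occupied &= sums > 0
    if not occupied.any():
        raise ValueError("no depth bin reaches the minimum occupancy")
    bin_dx = (np.nonzero(occupied)[0] // nz_bins).astype(float)
    bin_dz = (np.nonzero(occupied)[0] % nz_bins).astype(float)
    bin_mean = sums[occupied] / counts[occupied]
    bin_w = counts[occupied].astype(float)
    if np.unique(bin_dx).size < 2:
        raise ValueError("degenerate design: all tissue at one excitation (X) depth")
    if np.unique(bin_dz).size < 2:
        raise ValueError("degenerate design: all tissue at one emission (Z) depth")
    norm = bin_mean.max()
    logm = np.log(bin_mean / norm)
    design = np.column_stack([np.ones_like(bin_dx), -bin_dx, -bin_dz])
    sw = np.sqrt(bin_w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], logm * sw, rcond=None)
    log_a, mu_x, mu_z = (float(c) for c in coef)
    if mu_x < 0 or mu_z < 0:
        logger.warning(
            "negative fitted extinction (mu_x=%.3g, mu_z=%.3g); clamping to 0",
            mu_x,
            mu_z,
        )
        mu_x, mu_z = max(mu_x, 0.0), max(mu_z, 0.0)
    resid = logm - (log_a - mu_x * bin_dx - mu_z * bin_dz)
    rms = float(np.sqrt(np.sum(bin_w * resid**2) / np.sum(bin_w)))
    return ExtinctionModel(
        amplitude=float(np.exp(log_a)),
        mu_x=mu_x,
        mu_z=mu_z,
        fit_residual=rms,
        n_bins=int(occupied.sum()),
    )


def compensate_volume(
    volume: np.ndarray,
    model: ExtinctionModel,
    depths: DepthMaps,
    max_gain: float = 50.0,
) -> np.ndarray:
    """Multiply every voxel by the inverse fitted decay, capped at ``max_gain``.

    Voxels outside any tissue path (both depths zero) receive unit gain.
    The cap bounds noise amplification at extreme depth; capped voxels
    are counted in the log.
    """
    volume = np.asarray(volume, dtype=float)
    gain = np.exp(
        model.mu_x * np.asarray(depths.depth_x) + model.mu_z * np.asarray(depths.depth_z)
    )
    n_capped = int(np.count_nonzero(gain > max_gain))
    if n_capped:
        logger.info("compensation gain capped at %.1f for %d voxels", max_gain, n_capped)
    np.minimum(gain, max_gain, out=gain)
    return volume * gain
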