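"""Extinction-aware per-plane tissue segmentation.

A single global threshold fails on strongly attenuated planes: deep
tissue falls below any threshold that still excludes background.  The
procedure here therefore pre-compensates each plane for attenuation
before thresholding: smooth, bootstrap-threshold, build a propagation
depth map from the cumulative mask sum along X, fit an exponential decay
to the median intensity per depth, divide the plane by the decay, and
iterate.  The final mask is taken from the histogram of the compensated
plane — the first empty bin after the background peak separates
background noise from endogenous tissue fluorescence — and cleaned up
morphologically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

__all__ = [
    "SegmentationParams",
    "DecayFit1D",
    "SegmentationResult",
    "EmptyMaskError",
    "depth_profile_median",
    "fit_depth_decay",
    "precompensate_plane",
    "threshold_first_zero",
    "finalize_mask",
    "segment_plane",
]

logger = logging.getLogger(__name__)


class EmptyMaskError(ValueError):
    """Raised when a plane contains no tissue above threshold."""


@dataclass
class SegmentationParams:
    """Tunables of the per-plane segmentation.

    ``noise_gauss_radius`` is the radius (px) of the initial noise
    suppression filter (Gaussian sigma = radius / 2).  ``initial_threshold``
    bootstraps the depth map; ``"auto"`` uses Otsu's threshold on the
    smoothed plane, whose inaccuracy the pre-compensation iterations
    correct.  ``neighbor_weight_delta`` is the intensity half-window around
    the threshold inside which the previous plane's mask decides borderline
    pixels; ``None`` uses 10% of the threshold.
    """

    noise_gauss_radius: float = 5.0
    initial_threshold: float | str = "auto"
    histogram_bins: int = 256
    max_iterations: int = 2
    morph_close_radius: int = 3
    min_object_px: int = 64
    neighbor_weight_delta: float | None = None

    def __post_init__(self) -> None:
        if self.noise_gauss_radius < 0 or self.morph_close_radius < 0:
            raise ValueError("radii must be >= 0")
        if self.histogram_bins < 16:
            raise ValueError("need at least 16 histogram bins")
        if self.max_iterations < 1:
            raise ValueError("need at least one compensation iteration")


@dataclass
class DecayFit1D:
    """Exponential decay fitted to a normalized depth profile.

    ``rate`` is per pixel of tissue depth; ``amplitude`` is the fitted
    value at depth 0 of the normalized profile (close to 1 for a clean
    exponential); ``residual`` is the RMS of log-domain residuals.
    """

    rate: float
    amplitude: float
    valid_range: tuple[float, float]
    residual: float


@dataclass
class SegmentationResult:
    mask: np.ndarray
    fit: DecayFit1D
    threshold: float
    compensated: np.ndarray


def _smooth(plane: np.ndarray, radius: float) -> np.ndarray:
    if radius <= 0:
        return np.asarray(plane, dtype=float)
    return ndimage.gaussian_filter(np.asarray(plane, dtype=float), sigma=radius / 2.0)


def depth_profile_median(
    plane: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Median intensity at each propagation depth.

    The depth of pixel (y, x) is the number of masked pixels in row y up
    to and including x; the profile holds, for every occupied depth, the
    median plane value over masked pixels at that depth.  An empty mask
    yields an empty profile.
    """
    plane = np.asarray(plane, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != plane.shape:
        raise ValueError("mask shape must match the plane")
    if not mask.any():
        return np.empty(0), np.empty(0)
    depth = np.cumsum(mask, axis=1)
    d = depth[mask]
    v = plane[mask]
    order = np.argsort(d, kind="stable")
    d, v = d[order], v[order]
    depths, starts = np.unique(d, return_index=True)
    medians = np.array(
        [np.median(v[s:e]) for s, e in zip(starts, np.append(starts[1:], v.size))]
    )
    return depths.astype(float), medians


def fit_depth_decay(
    profile: tuple[np.ndarray, np.ndarray], floor_threshold: float
) -> DecayFit1D:
    """Least-squares exponential fit to a trimmed, normalized depth profile.

    Medians below ``floor_threshold`` are discarded, the remainder is
    normalized to its first value and fitted in the log domain to
    ``amplitude * exp(-rate * depth)``.  A negative fitted rate is clamped
    to zero with a warning (attenuation cannot brighten with depth).
    """
    depths, medians = profile
    keep = medians >= floor_threshold
    depths, medians = depths[keep], medians[keep]
    if depths.size < 5:
        raise EmptyMaskError(
            f"only {depths.size} profile points above the floor; "
            "reduce the threshold to fit a decay"
        )
    if medians[0] <= 0 or np.any(medians <= 0):
        raise EmptyMaskError("depth profile is not strictly positive; nothing to fit")
    norm = medians / medians[0]
    logm = np.log(norm)
    design = np.column_stack([np.ones_like(depths), -depths])
    (log_a, rate), *_ = np.linalg.lstsq(design, logm, rcond=None)
    if rate < 0:
        logger.warning("fitted decay rate %.3g < 0; clamping to 0", rate)
        rate, log_a = 0.0, float(np.mean(logm))
    resid = logm - (log_a - rate * depths)
    return DecayFit1D(
        rate=float(rate),
        amplitude=float(np.exp(log_a)),
        valid_range=(float(depths[0]), float(depths[-1])),
        residual=float(np.sqrt(np.mean(resid**2))),
    )


def _bootstrap_threshold(smoothed: np.ndarray, params: SegmentationParams) -> float:
    if params.initial_threshold == "auto":
        return float(filters.threshold_otsu(smoothed))
    return float(params.initial_threshold)


def precompensate_plane(
    plane: np.ndarray, params: SegmentationParams
) -> tuple[np.ndarray, DecayFit1D, np.ndarray]:
    """Iteratively compensate one plane for attenuation along X.

    The bootstrap threshold delimits an initial mask whose cumulative sum
    along X is the first depth map; the decay of the median intensity per
    depth is fitted and the smoothed plane divided by the resulting
    extinction map.  Each further iteration re-applies the threshold to
    the compensated plane — recovering tissue the bootstrap missed at
    depth — refreshes the depth map, and refits the decay of the *raw*
    smoothed plane against it.  Returns the final compensated plane,
    decay fit and depth map.
    """
    smoothed = _smooth(plane, params.noise_gauss_radius)
    threshold = _bootstrap_threshold(smoothed, params)
    mask = smoothed >= threshold
    fit: DecayFit1D | None = None
    depth = np.zeros_like(smoothed)
    compensated = smoothed
    for _ in range(params.max_iterations):
        if not mask.any():
            raise EmptyMaskError("no pixels above the bootstrap threshold")
        depth = np.cumsum(mask, axis=1).astype(float)
        depths_arr, medians_arr = depth_profile_median(smoothed, mask)
        # within one smoothing radius of the tissue border the medians are
        # blurred toward background and would tilt the fit
        guard = depths_arr > params.noise_gauss_radius
        fit = fit_depth_decay(
            (depths_arr[guard], medians_arr[guard]), floor_threshold=threshold
        )
        extinction = np.exp(-fit.rate * depth)
        compensated = smoothed / np.maximum(extinction, 1e-12)
        mask = compensated >= threshold
    assert fit is not None
    return compensated, fit, depth


def threshold_first_zero(plane: np.ndarray, bins: int = 256) -> float:
    """Histogram threshold at the first empty bin after the background peak.

    The histogram over the plane's own range is smoothed with a 3-bin
    moving mean; the threshold is the lower edge of the first bin after
    the global (background) peak whose smoothed count rounds to zero.  If
    no such gap exists the minimum between the first two modes is used
    instead (logged).
    """
    plane = np.asarray(plane, dtype=float).ravel()
    lo, hi = float(plane.min()), float(plane.max())
    if lo == hi:
        raise ValueError("constant plane has no histogram threshold")
    counts, edges = np.histogram(plane, bins=bins, range=(lo, hi))
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    # background sits at the low end: take the first prominent mode, which
    # need not be the tallest once compensation concentrates the tissue
    prominent = smooth >= 0.05 * smooth.max()
    peak = int(np.argmax(smooth))
    for i in range(1, bins - 1):
        if prominent[i] and smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]:
            peak = i
            break
    after = np.nonzero(smooth[peak + 1 :] < 0.5)[0]
    if after.size:
        return float(edges[peak + 1 + after[0]])
    # fallback: minimum between the first two modes
    maxima = [
        i
        for i in range(1, bins - 1)
        if smooth[i] >= smooth[i - 1] and smooth[i] > smooth[i + 1]
    ]
    if len(maxima) < 2:
        logger.warning("unimodal histogram without gap; using Otsu fallback")
        return float(filters.threshold_otsu(plane))
    m1, m2 = maxima[0], maxima[1]
    valley = m1 + int(np.argmin(smooth[m1 : m2 + 1]))
    logger.info("no empty histogram bin; using inter-mode minimum")
    return float(edges[valley])


def finalize_mask(
    mask: np.ndarray,
    params: SegmentationParams,
    previous_mask: np.ndarray | None = None,
    plane: np.ndarray | None = None,
    threshold: float | None = None,
) -> np.ndarray:
    """Morphological cleanup, optionally weighting borderline pixels by the
    previous plane's mask.

    Pixels whose intensity lies within ``neighbor_weight_delta`` of the
    threshold are included iff their Z-neighbour was tissue; then closing,
    hole filling and small-object removal are applied.
    """
    mask = np.asarray(mask, dtype=bool)
    if previous_mask is not None and plane is not None and threshold is not None:
        if previous_mask.shape != mask.shape:
            raise ValueError("previous mask shape must match")
        delta = params.neighbor_weight_delta
        if delta is None:
            delta = 0.1 * abs(threshold)
        borderline = np.abs(np.asarray(plane, dtype=float) - threshold) <= delta
        mask = np.where(borderline, previous_mask, mask)
    if params.morph_close_radius > 0:
        mask = morphology.closing(mask, morphology.disk(params.morph_close_radius))
    mask = ndimage.binary_fill_holes(mask)
    if params.min_object_px > 0:
        labels, n = ndimage.label(mask)
        if n:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            mask = (sizes >= params.min_object_px)[labels] & mask
    return mask


def segment_plane(
    plane: np.ndarray,
    params: SegmentationParams | None = None,
    previous_mask: np.ndarray | None = None,
) -> SegmentationResult:
    """Segment tissue in one plane via extinction pre-compensation."""
    params = params or SegmentationParams()
    compensated, fit, _depth = precompensate_plane(plane, params)
    threshold = threshold_first_zero(compensated, params.histogram_bins)
    mask = compensated >= threshold
    mask = finalize_mask(mask, params, previous_mask, compensated, threshold)
    return SegmentationResult(
        mask=mask, fit=fit, threshold=threshold, compensated=compensated
    )
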