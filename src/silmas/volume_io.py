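"""Out-of-core plane-stack I/O and pipeline configuration.

Volumetric light-sheet stacks routinely exceed memory (terabyte-range at
micron voxels), so every stage streams planes: a :class:`StackHandle`
abstracts a multi-page TIFF, a numbered TIFF series or an in-memory
array behind a uniform per-plane read interface with an access counter,
and :func:`iterate_planes` yields planes in chunks without ever holding
more than the requested chunk resident.

All internal computation runs in floating point; integer inputs are
promoted on read and the output dtype is chosen at write time.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import tifffile
import yaml

__all__ = [
    "StackHandle",
    "open_stack",
    "iterate_planes",
    "write_planes",
    "PipelineConfig",
    "StageOrderError",
]

logger = logging.getLogger(__name__)

#: Canonical stage order: segmentation first, destriping and extinction
#: calibration in parallel on pre-destriping data, compensation last.
CANONICAL_STAGES = ("reconstruct", "segment", "destripe", "calibrate", "compensate")


class StageOrderError(ValueError):
    """Raised for configurations that violate the pipeline's order contract."""


@dataclass
class StackHandle:
    """Uniform handle over a Z-ordered stack of 2D grayscale planes.

    Axis convention: rows = Y (modulation axis), cols = X (propagation
    axis), plane index = Z (detection axis).  ``reads`` counts plane
    accesses so tests can assert the out-of-core memory contract.
    """

    source: object  # Path, list[Path], or np.ndarray
    n_planes: int
    plane_shape: tuple[int, int]
    dtype: np.dtype
    reads: int = 0

    @classmethod
    def from_array(cls, volume: np.ndarray) -> "StackHandle":
        volume = np.asarray(volume)
        if volume.ndim != 3:
            raise ValueError("expected a (nz, ny, nx) volume")
        return cls(
            source=volume,
            n_planes=volume.shape[0],
            plane_shape=volume.shape[1:],
            dtype=volume.dtype,
        )

    def read_plane(self, index: int) -> np.ndarray:
        """Read one plane, promoted to float64.  Errors name the plane index."""
        if not 0 <= index < self.n_planes:
            raise IndexError(f"plane {index} outside stack of {self.n_planes}")
        self.reads += 1
        try:
            if isinstance(self.source, np.ndarray):
                plane = self.source[index]
            elif isinstance(self.source, list):
                plane = tifffile.imread(self.source[index])
            else:
                with tifffile.TiffFile(self.source) as tf:
                    plane = tf.pages[index].asarray()
        except Exception as exc:  # noqa: BLE001 - surface the plane index
            raise IOError(f"failed to read plane {index}: {exc}") from exc
        plane = np.asarray(plane)
        if plane.shape != tuple(self.plane_shape):
            raise IOError(
                f"plane {index} shape {plane.shape} != stack shape {self.plane_shape}"
            )
        return plane.astype(np.float64)

    def read_volume(self) -> np.ndarray:
        return np.stack([self.read_plane(i) for i in range(self.n_planes)])


def open_stack(source) -> StackHandle:
    """Open a multi-page TIFF, a directory of TIFFs, or a list of plane files."""
    if isinstance(source, np.ndarray):
        return StackHandle.from_array(source)
    path = Path(source) if not isinstance(source, (list, tuple)) else None
    if path is not None and path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF planes under {path}")
        source = files
    if isinstance(source, (list, tuple)):
        files = [Path(p) for p in source]
        first = tifffile.imread(files[0])
        handle = StackHandle(
            source=files,
            n_planes=len(files),
            plane_shape=first.shape,
            dtype=first.dtype,
        )
        return handle
    with tifffile.TiffFile(path) as tf:
        n = len(tf.pages)
        first = tf.pages[0]
        shape, dtype = first.shape, first.dtype
    return StackHandle(source=path, n_planes=n, plane_shape=shape, dtype=dtype)


def iterate_planes(
    handle: StackHandle, chunk: int = 16
) -> Iterator[tuple[int, np.ndarray]]:
    """Yield (index, plane) ascending, holding at most ``chunk`` planes resident."""
    if chunk < 1:
        raise ValueError("chunk must be >= 1")
    for start in range(0, handle.n_planes, chunk):
        batch = [
            (i, handle.read_plane(i))
            for i in range(start, min(start + chunk, handle.n_planes))
        ]
        yield from batch
        del batch


def write_planes(
    stream: Iterable,
    dest,
    dtype: str = "float32",
    scaling: str = "none",
    value_range: tuple[float, float] | None = None,
) -> StackHandle:
    """Write a stream of planes (or ``(index, plane)`` pairs) to a multi-page TIFF.

    ``scaling`` controls integer conversion: ``clip`` saturates at the
    dtype range (clipped pixel counts are logged), ``rescale`` maps
    ``value_range`` (or the stream's own range, buffering the stream) onto
    the full dtype range, ``none`` casts as-is.  float32 output
    round-trips bit-exactly.
    """
    if scaling not in ("clip", "rescale", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    out_dtype = np.dtype(dtype)
    planes = []
    for item in stream:
        plane = item[1] if isinstance(item, tuple) else item
        planes.append(np.asarray(plane, dtype=np.float64))
    if not planes:
        raise ValueError("empty plane stream")
    if any(p.shape != planes[0].shape for p in planes):
        raise ValueError("planes must have uniform shape")
    if scaling == "rescale":
        if value_range is None:
            lo = min(float(p.min()) for p in planes)
            hi = max(float(p.max()) for p in planes)
        else:
            lo, hi = value_range
        span = hi - lo if hi > lo else 1.0
    n_clipped = 0
    dest = Path(dest)
    with tifffile.TiffWriter(dest) as tw:
        for p in planes:
            if np.issubdtype(out_dtype, np.integer):
                info = np.iinfo(out_dtype)
                if scaling == "rescale":
                    p = (p - lo) / span * info.max
                elif scaling == "clip":
                    n_clipped += int(np.count_nonzero((p < info.min) | (p > info.max)))
                p = np.clip(np.rint(p), info.min, info.max)
            tw.write(p.astype(out_dtype), contiguous=True)
    if n_clipped:
        logger.warning("%d pixels clipped writing %s", n_clipped, dest)
    handle = open_stack(dest)
    handle.clipped_pixels = n_clipped  # type: ignore[attr-defined]
    return handle


@dataclass
class PipelineConfig:
    """Validated end-to-end pipeline configuration.

    ``layout`` describes the input stack: ``planes`` (already demodulated),
    ``interleaved`` (I0, I120, I240 triplets per Z in one stack) or
    ``separate`` (three parallel stacks).  The stage order is fixed by
    contract; configurations that apply compensation before destriping are
    rejected because compensation would amplify the noise inside shadow
    stripes.
    """

    input_path: str = ""
    layout: str = "planes"
    output_dir: str = "silmas_out"
    # destriping
    gauss_sizes: tuple[float, ...] = (15.0, 801.0)
    dec_levels: tuple[tuple[int, ...], ...] = (
        (1, 2, 3, 4, 5, 6),
        (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11),
    )
    wavelet: str = "db45"
    sigma: float = -1.0
    # segmentation
    noise_gauss_radius: float = 5.0
    max_iterations: int = 2
    morph_close_radius: int = 3
    min_object_px: int = 64
    use_previous_plane: bool = False
    # extinction
    na_blur_radius: int = 1
    power_window: int = 20
    step_threshold: float = 0.05
    max_gain: float = 50.0
    min_bin_count: int = 10
    y_profile_path: str | None = None
    power_schedule_path: str | None = None
    # plumbing
    chunk: int = 16
    seed: int = 0
    stage_order: tuple[str, ...] = CANONICAL_STAGES

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.layout not in ("planes", "interleaved", "separate"):
            raise ValueError(f"unknown layout {self.layout!r}")
        order = [s for s in self.stage_order if s in CANONICAL_STAGES]
        if sorted(set(order)) != sorted(order):
            raise StageOrderError("duplicate stages in stage_order")
        required = {"segment", "destripe", "calibrate", "compensate"}
        if not required.issubset(order):
            raise StageOrderError(f"stage_order must contain {sorted(required)}")

        def pos(stage: str) -> int:
            return order.index(stage)

        if pos("compensate") != len(order) - 1:
            raise StageOrderError("extinction compensation must run last")
        if pos("compensate") < pos("destripe"):
            raise StageOrderError(
                "shadowing suppression must be applied before extinction compensation"
            )
        if pos("segment") != ("reconstruct" in order):
            raise StageOrderError("segmentation must run first (after reconstruction)")
        if self.chunk < 1:
            raise ValueError("chunk must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "gauss_sizes" in raw:
            raw["gauss_sizes"] = tuple(raw["gauss_sizes"])
        if "dec_levels" in raw:
            raw["dec_levels"] = tuple(tuple(l) for l in raw["dec_levels"])
        if "stage_order" in raw:
            raw["stage_order"] = tuple(raw["stage_order"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
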