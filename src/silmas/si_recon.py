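"""Three-phase structured-illumination demodulation.

A structured light sheet records each plane three times with the
sinusoidal modulation phase-shifted by 120 degrees.  The modulated
(in-focus, singly scattered) component is recovered from the pairwise
differences; the unmodulated residual — multiply scattered and
out-of-focus light — cancels.  For the model
``I_k = A + B cos(theta + phi_k)`` the demodulated image is ``sqrt(2) B``
and the conventional image is ``A``, independent of ``theta``.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator

import numpy as np

from .synthetic import PhaseTriplet

__all__ = ["SI_PREFACTOR", "si_image", "conventional_image", "demodulate_planes"]

#: Prefactor of the root-of-sum-of-squared-differences demodulation formula.
#: With three phases at 120-degree spacing the squared differences sum to
#: (9/2) B^2, so the 2/3 prefactor yields sqrt(2)*B — the RMS-to-peak
#: normalisation conventional for SLIPI-style reconstruction.  (Beware the
#: typographically similar sqrt(2)/3, which would yield B instead.)
SI_PREFACTOR = 2.0 / 3.0


def _as_planes(t: PhaseTriplet | tuple) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(t, PhaseTriplet):
        planes = t.planes()
    else:
        planes = tuple(t)
        if len(planes) != 3:
            raise ValueError("expected exactly three phase planes")
    a, b, c = (np.asarray(p, dtype=np.float64) for p in planes)
    if not (a.shape == b.shape == c.shape):
        raise ValueError("phase planes must share one shape")
    return a, b, c


def si_image(t: PhaseTriplet | tuple, prefactor: float = SI_PREFACTOR) -> np.ndarray:
    """Demodulated (scattered-light-suppressed) plane.

    ``prefactor * sqrt((I0-I120)^2 + (I0-I240)^2 + (I120-I240)^2)``,
    computed in float64 (squared differences of 16-bit counts overflow
    32-bit integers).  Non-negative, zero exactly where the three phases
    agree, and invariant under adding a common constant to all three.
    """
    i0, i120, i240 = _as_planes(t)
    d01 = i0 - i120
    d02 = i0 - i240
    d12 = i120 - i240
    return prefactor * np.sqrt(d01 * d01 + d02 * d02 + d12 * d12)


def conventional_image(t: PhaseTriplet | tuple) -> np.ndarray:
    """Pointwise mean of the three phases: the homogeneous light-sheet image."""
    i0, i120, i240 = _as_planes(t)
    return (i0 + i120 + i240) / 3.0


def demodulate_planes(
    planes: Iterable[tuple[int, np.ndarray]],
    layout: str = "interleaved",
) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
    """Stream (plane_index, SI, conventional) from an interleaved triplet stream.

    ``layout='interleaved'`` expects planes ordered I0, I120, I240 per Z;
    with ``layout='separate'`` the caller streams three parallel stacks and
    should zip them into triplets before calling :func:`si_image` directly.
    """
    if layout != "interleaved":
        raise ValueError("demodulate_planes streams interleaved stacks only")
    buf: list[np.ndarray] = []
    base = 0
    for idx, plane in planes:
        buf.append(np.asarray(plane, dtype=np.float64))
        if len(buf) == 3:
            t = (buf[0], buf[1], buf[2])
            yield base, si_image(t), conventional_image(t)
            buf = []
            base += 1
    if buf:
        raise ValueError(
            f"interleaved stack length not divisible by 3 (dangling {len(buf)} plane(s))"
        )


def modulation_amplitude(si: np.ndarray) -> np.ndarray:
    """Underlying cosine amplitude B implied by an SI plane (= SI / sqrt(2))."""
    return np.asarray(si, dtype=float) / math.sqrt(2.0)
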