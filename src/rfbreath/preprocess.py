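"""Raw phase cleaning: pi-radian disambiguation, 2*pi unwrapping, resampling.

The reader hardware may report a tag's phase offset by pi radians, and the
wrapped phase jumps by ~2*pi whenever the accumulated carrier phase crosses
a period boundary.  Both artefacts are removed sequentially, each sample
compared against the previous *corrected* value (a running reference), so a
single correction cannot trigger a cascade of misfires.

Breathing moves the phase by well under a radian between consecutive reads
(tens of samples per breath), which is what makes jump detection by
thresholding sound: a genuine inter-sample step sits near 0, an ambiguity
event near pi, a wrap near 2*pi.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidArgumentError
from .streams import TWO_PI, TagStream


@dataclass
class CleanStream:
    """Disambiguated, unwrapped phase on a uniform time grid."""

    epc: str
    t: np.ndarray  # seconds, uniform grid
    phase: np.ndarray  # radians, unbounded after unwrapping
    fs: float  # Hz

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0


def _circular_distance(a: float, b: float) -> float:
    """Distance between two angles on the circle, in [0, pi]."""
    return abs(((a - b) + np.pi) % TWO_PI - np.pi)


def disambiguate(phases, delta: float = 1.8) -> np.ndarray:
    """Remove pi-radian ambiguity events from a wrapped phase sequence.

    Scanning in time order with a running corrected reference ``prev``, a
    sample whose circular distance to ``prev`` falls within ``delta`` of pi
    is deemed ambiguous and corrected by +pi or -pi, whichever lands closer
    to ``prev``.  All other samples pass through.  Output length equals
    input length.
    """
    if not 0.0 < delta < np.pi:
        raise InvalidArgumentError(f"delta must be in (0, pi), got {delta}")
    out = np.array(phases, dtype=float, copy=True)
    if out.size == 0:
        return out
    prev = out[0]
    for i in range(1, len(out)):
        if _circular_distance(out[i], prev) >= np.pi - delta:
            lo, hi = out[i] - np.pi, out[i] + np.pi
            out[i] = lo if abs(lo - prev) <= abs(hi - prev) else hi
        prev = out[i]
    return out


def unwrap(phases, delta: float = 1.0) -> np.ndarray:
    """Undo 2*pi wrapping, accumulating corrections over the sequence.

    A running offset (a multiple of 2*pi) is carried forward so that later
    samples are compared in the unwrapped frame: when the offset-adjusted
    sample sits within ``delta`` of a full period away from the previous
    corrected value, it is shifted by -+2*pi toward continuity and the
    offset updated.  The output may therefore leave [0, 2*pi).
    """
    if not delta > 0:
        raise InvalidArgumentError(f"delta must be > 0, got {delta}")
    out = np.array(phases, dtype=float, copy=True)
    if out.size == 0:
        return out
    offset = 0.0
    prev = out[0]
    for i in range(1, len(out)):
        cur = out[i] + offset
        d = cur - prev
        if TWO_PI - delta <= abs(d) <= TWO_PI + delta:
            step = TWO_PI if cur < prev else -TWO_PI
            cur += step
            offset += step
        out[i] = cur
        prev = cur
    return out


def estimate_fs(t_ms) -> float:
    """Mean sampling rate from timestamps: ``(N-1) / span`` in Hz."""
    t = np.asarray(t_ms, dtype=float)
    if t.size < 2:
        raise InsufficientDataError("need at least 2 timestamps to estimate Fs")
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("timestamps must be strictly increasing")
    return (t.size - 1) / ((t[-1] - t[0]) / 1000.0)


def resample_uniform(t_s, phase, fs: float, epc: str = "") -> CleanStream:
    """Linearly interpolate an irregular series onto a uniform grid at ``fs``.

    The grid is ``t[0] + k/fs`` for ``k = 0 .. floor((t[-1]-t[0])*fs)``, so
    the first sample is preserved exactly and the last grid point never
    extrapolates.
    """
    if not fs > 0:
        raise InvalidArgumentError("fs must be > 0")
    t = np.asarray(t_s, dtype=float)
    y = np.asarray(phase, dtype=float)
    if t.size < 2:
        raise InsufficientDataError("need at least 2 samples to resample")
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("timestamps must be strictly increasing")
    n = int(np.floor((t[-1] - t[0]) * fs)) + 1
    grid = t[0] + np.arange(n) / fs
    return CleanStream(epc=epc, t=grid, phase=np.interp(grid, t, y), fs=fs)


def clean_stream(stream: TagStream, delta_ambiguity: float = 1.8,
                 delta_unwrap: float = 1.0) -> CleanStream:
    """Full preprocessing of one tag: disambiguate, unwrap, resample.

    The sampling rate of the uniform grid is the stream's own mean rate
    estimated from its timestamps.
    """
    phases = disambiguate(stream.phase, delta_ambiguity)
    phases = unwrap(phases, delta_unwrap)
    fs = estimate_fs(stream.t_ms)
    return resample_uniform(stream.t_s, phases, fs, epc=stream.epc)
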