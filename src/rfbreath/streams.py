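"""In-memory containers for reader observations.

A UHF reader reports, for every successful tag inventory, the tag EPC, a
millisecond timestamp, the backscatter phase (both as a 12-bit code and the
mapped radian value) and optionally an RSSI.  ``PhaseSample`` is one such
observation; ``TagStream`` is the time-ordered sequence for a single EPC.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

TWO_PI = 2.0 * np.pi

#: Width of the reader's phase field.
PHASE_CODE_BITS = 12
PHASE_CODES = 1 << PHASE_CODE_BITS  # 4096
#: Smallest phase increment the reader can represent, 2*pi/4096 rad.
PHASE_RESOLUTION_RAD = TWO_PI / PHASE_CODES


@dataclass(frozen=True)
class PhaseSample:
    """One reader observation of one tag."""

    epc: str
    t_ms: int
    phase: float  # radians in [0, 2*pi)
    raw_code: int  # integer in [0, 4095]
    rssi: float | None = None  # dBm

    def __post_init__(self):
        if not 0 <= self.raw_code < PHASE_CODES:
            raise InvalidArgumentError(
                f"raw_code {self.raw_code} outside [0, {PHASE_CODES})")
        if not 0.0 <= self.phase < TWO_PI:
            raise InvalidArgumentError(f"phase {self.phase} outside [0, 2*pi)")


@dataclass
class TagStream:
    """Time-ordered samples of a single EPC.

    Arrays are kept column-wise (one array per field) because every
    downstream operation is vectorised.
    """

    epc: str
    t_ms: np.ndarray  # int64 milliseconds, strictly increasing
    phase: np.ndarray  # float radians in [0, 2*pi)
    raw_code: np.ndarray | None = None
    rssi: np.ndarray | None = None

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=np.int64)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.raw_code is not None:
            self.raw_code = np.asarray(self.raw_code, dtype=np.int64)
        if self.rssi is not None:
            self.rssi = np.asarray(self.rssi, dtype=float)
        if self.t_ms.shape != self.phase.shape:
            raise InvalidArgumentError("t_ms and phase must have equal length")
        if len(self.t_ms) > 1 and np.any(np.diff(self.t_ms) < 0):
            raise InvalidArgumentError(
                f"timestamps of EPC {self.epc} are not non-decreasing")

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def t_s(self) -> np.ndarray:
        """Timestamps in seconds."""
        return self.t_ms / 1000.0

    @property
    def duration_s(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(self.t_ms[-1] - self.t_ms[0]) / 1000.0

    def samples(self):
        """Iterate over the stream as :class:`PhaseSample` records."""
        for i in range(len(self)):
            yield PhaseSample(
                epc=self.epc,
                t_ms=int(self.t_ms[i]),
                phase=float(self.phase[i]),
                raw_code=int(self.raw_code[i]) if self.raw_code is not None
                else int(round(self.phase[i] / PHASE_RESOLUTION_RAD)) % PHASE_CODES,
                rssi=float(self.rssi[i]) if self.rssi is not None else None,
            )
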