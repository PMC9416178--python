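"""Respiratory waveform reconstruction via wavelet approximation extremes.

The filtered phase still carries high-frequency detail that obscures the
breath-by-breath envelope.  The reconstruction chain is:

1. choose the decomposition depth ``n`` so the approximation's effective
   rate ``Fs / 2**n`` lands in 0.6–2.0 Hz and is the smallest admissible
   value at or above twice a 0.3 Hz reference breathing rate;
2. take the level-``n`` db2 approximation coefficients (details discarded);
3. detect strict local maxima/minima of the coefficients — the candidate
   breath peaks and troughs;
4. drop extremes whose swing from the last accepted one is below
   ``alpha * (mean(maxima) - mean(minima))`` — sub-breath wiggles;
5. difference the surviving extremes and prune until consecutive
   differences alternate in sign (a peak must follow a trough);
6. pass a natural cubic spline through the survivors.

The coefficient count shrinks by 2**n, so extremum timing is mapped back as
``t_k = t0 + k * 2**n / Fs``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import CubicSpline

from .errors import (InsufficientDataError, InvalidArgumentError,
                     InvalidSamplingRateError)

#: Admissible band for the post-decomposition effective sampling rate, Hz.
LEVEL_BAND = (0.6, 2.0)
#: Reference respiratory rate (18 bpm) used to pick among admissible levels.
DEFAULT_FRR_HZ = 0.3
DEFAULT_WAVELET = "db2"


@dataclass(frozen=True)
class WaveletPlan:
    """Chosen decomposition depth and the admissible set it was drawn from."""

    fs: float
    n: int
    omega: tuple[int, ...]
    frr: float = DEFAULT_FRR_HZ
    wavelet: str = DEFAULT_WAVELET

    @property
    def effective_fs(self) -> float:
        return self.fs / 2 ** self.n


@dataclass(frozen=True)
class Extremum:
    """A local maximum or minimum of the approximation coefficients."""

    time: float
    value: float
    kind: str  # "max" | "min"
    index: int  # coefficient index at level n


@dataclass(frozen=True)
class DiffSequence:
    """Differences between consecutive surviving extremes."""

    extrema: tuple[Extremum, ...]

    @property
    def d(self) -> np.ndarray:
        return np.diff([e.value for e in self.extrema])

    @property
    def L(self) -> int:
        return max(len(self.extrema) - 1, 0)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([e.time for e in self.extrema])


def select_levels(fs: float, lo: float = LEVEL_BAND[0], hi: float = LEVEL_BAND[1],
                  frr: float = DEFAULT_FRR_HZ, max_level: int = 32) -> WaveletPlan:
    """Pick the decomposition depth from the sampling rate.

    The admissible set is ``Omega = {e >= 0 : lo <= fs/2**e <= hi}``; among
    members with ``f(n) = fs/2**n - 2*frr >= 0`` the minimiser of ``f`` is
    chosen (i.e. the effective rate closest to twice the reference rate from
    above).  If no member clears that floor, the member with the smallest
    ``|f(n)|`` is used instead.
    """
    if not 0 < lo < hi:
        raise InvalidArgumentError(f"need 0 < lo < hi, got ({lo}, {hi})")
    omega = tuple(e for e in range(max_level + 1) if lo <= fs / 2 ** e <= hi)
    if not omega:
        raise InvalidSamplingRateError(
            f"no admissible decomposition level for Fs = {fs} Hz in [{lo}, {hi}] Hz")

    def f(n: int) -> float:
        return fs / 2 ** n - 2.0 * frr

    feasible = [n for n in omega if f(n) >= 0]
    if feasible:
        n = min(feasible, key=f)
    else:
        n = min(omega, key=lambda e: (abs(f(e)), -e))
    return WaveletPlan(fs=fs, n=n, omega=omega, frr=frr)


def approximation(x, plan: WaveletPlan, t0: float = 0.0,
                  decimated: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Level-``n`` db2 approximation of the signal, details discarded.

    Returns ``(coeffs, times)``.  With ``decimated=True`` (default) these
    are the decimated approximation coefficients with times
    ``t0 + k * 2**n / fs``; with ``decimated=False`` the full-length
    lowpass reconstruction sampled at ``fs``.  Symmetric boundary
    extension, so a constant input yields a constant approximation (scaled
    by ``2**(n/2)`` in the decimated convention).
    """
    x = np.asarray(x, dtype=float)
    w = pywt.Wavelet(plan.wavelet)
    if x.size < 2 ** plan.n + w.dec_len:
        raise InsufficientDataError(
            f"signal of {x.size} samples is too short for a level-{plan.n} decomposition")
    coeffs = pywt.wavedec(x, w, mode="symmetric", level=plan.n)[0]
    if decimated:
        times = t0 + np.arange(coeffs.size) * (2 ** plan.n / plan.fs)
        return coeffs, times
    approx = pywt.upcoef("a", coeffs, w, level=plan.n, take=x.size)
    return approx, t0 + np.arange(approx.size) / plan.fs


def detect_extrema(values, times) -> list[Extremum]:
    """Strict interior local extremes; a plateau counts once, at its first sample."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if v.size != t.size:
        raise InvalidArgumentError("values and times must have equal length")
    if v.size < 3:
        return []
    # compress equal-value runs so plateaus compare against their flanks
    starts = [0]
    for i in range(1, v.size):
        if v[i] != v[starts[-1]]:
            starts.append(i)
    out: list[Extremum] = []
    for j in range(1, len(starts) - 1):
        i = starts[j]
        left, right = v[starts[j - 1]], v[starts[j + 1]]
        if v[i] > left and v[i] > right:
            out.append(Extremum(time=float(t[i]), value=float(v[i]), kind="max", index=i))
        elif v[i] < left and v[i] < right:
            out.append(Extremum(time=float(t[i]), value=float(v[i]), kind="min", index=i))
    return out


def filter_extrema(extrema, alpha: float = 0.5) -> list[Extremum]:
    """Keep only extremes whose swing from the last kept one is large enough.

    The threshold ``alpha * (mean of maxima - mean of minima)`` is computed
    once over the input; the scan keeps the first extremum unconditionally
    and accepts each later one iff ``|e - e_last| >= threshold``.  When the
    input contains only one kind of extremum the threshold is undefined and
    the sequence passes through unchanged.
    """
    if not 0.0 < alpha <= 1.0:
        raise InvalidArgumentError(f"alpha must be in (0, 1], got {alpha}")
    extrema = list(extrema)
    if not extrema:
        return []
    maxima = [e.value for e in extrema if e.kind == "max"]
    minima = [e.value for e in extrema if e.kind == "min"]
    if not maxima or not minima:
        return extrema
    threshold = alpha * (float(np.mean(maxima)) - float(np.mean(minima)))
    kept = [extrema[0]]
    for e in extrema[1:]:
        if abs(e.value - kept[-1].value) >= threshold:
            kept.append(e)
    return kept


def difference(extrema) -> DiffSequence:
    """Differences ``d_i = e_{i+1} - e_i`` of the extremum values."""
    return DiffSequence(extrema=tuple(extrema))


def enforce_alternation(diffs: DiffSequence) -> DiffSequence:
    """Prune extremes until consecutive differences alternate in sign.

    While some adjacent pair of differences shares a sign (a peak following
    a peak), the middle extremum of the offending triple with the smallest
    ``|d|`` contribution is removed and the differences recomputed.
    Zero-valued differences count as violations.
    """
    ex = list(diffs.extrema)
    while len(ex) >= 3:
        d = np.diff([e.value for e in ex])
        bad = [i for i in range(len(d) - 1) if np.sign(d[i]) * np.sign(d[i + 1]) >= 0]
        if not bad:
            break
        i = min(bad, key=lambda i: min(abs(d[i]), abs(d[i + 1])))
        del ex[i + 1]
    return DiffSequence(extrema=tuple(ex))


def spline_waveform(extrema, fs_out: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline through the surviving extremes.

    Evaluated on a uniform grid at ``fs_out`` spanning the first to last
    extremum; the curve passes through every knot exactly.  With two knots
    the natural spline degenerates to the straight line between them.
    """
    extrema = list(extrema)
    if len(extrema) < 2:
        raise InsufficientDataError("need at least 2 extremes to fit a spline")
    t = np.asarray([e.time for e in extrema])
    v = np.asarray([e.value for e in extrema])
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("extremum times must be strictly increasing")
    spline = CubicSpline(t, v, bc_type="natural")
    n = int(math.floor((t[-1] - t[0]) * fs_out)) + 1
    grid = t[0] + np.arange(n) / fs_out
    return grid, spline(grid)
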