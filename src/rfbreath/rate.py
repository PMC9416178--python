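"""Respiratory-rate extraction: DC removal, Butterworth bandpass, FFT peak.

The cleaned phase of a breathing tag is a near-sinusoid riding on a large
constant (the baseline distance term).  Rate extraction removes that DC
term, bandpass-filters to the physiological band 0.1–1 Hz (quiet breathing
sits at 0.2–0.33 Hz) with a 2nd-order Butterworth, and reads the rate off
the largest FFT magnitude inside the band.  The spectrum is zero-padded so
the readout grid is at least as fine as 0.01 Hz.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import (InsufficientDataError, InvalidArgumentError,
                     InvalidSamplingRateError)

DEFAULT_BAND = (0.1, 1.0)
#: Target FFT readout resolution in Hz.
RATE_RESOLUTION_HZ = 0.01


@dataclass(frozen=True)
class RateEstimate:
    """Band-limited spectral-peak rate with the spectrum it came from."""

    rate_hz: float
    peak_amplitude: float
    freqs: np.ndarray
    spectrum: np.ndarray
    band: tuple[float, float]

    @property
    def rate_bpm(self) -> float:
        return 60.0 * self.rate_hz


def remove_dc(x) -> np.ndarray:
    """Subtract the mean of the sequence (the zero-frequency component)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("cannot remove DC from an empty sequence")
    return x - x.mean()


def bandpass(x, fs: float, band: tuple[float, float] = DEFAULT_BAND,
             order: int = 2, zero_phase: bool = True) -> np.ndarray:
    """Digital Butterworth bandpass of the given order and band.

    Zero-phase (forward-backward) by default so extremum timing is not
    skewed; set ``zero_phase=False`` for causal single-pass filtering.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise InvalidArgumentError(f"band must satisfy 0 < lo < hi, got {band}")
    if order < 1:
        raise InvalidArgumentError("filter order must be >= 1")
    if not fs > 2 * hi:
        raise InvalidSamplingRateError(
            f"sampling rate {fs} Hz cannot support a band up to {hi} Hz")
    x = np.asarray(x, dtype=float)
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def extract_rate(x, fs: float, band: tuple[float, float] = DEFAULT_BAND,
                 window: str | None = None) -> RateEstimate:
    """Rate = argmax of the FFT magnitude restricted to ``band``.

    Requires at least ~10 s of signal (two breath cycles at the slow end of
    the band).  Zero-padding to the next power of two above
    ``max(8 N, fs / 0.01)`` interpolates the spectrum onto a grid no coarser
    than 0.01 Hz; exact ties break toward the lower frequency.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10 * fs:
        raise InsufficientDataError(
            f"need >= {int(10 * fs)} samples (10 s) for a rate estimate, got {x.size}")
    lo, hi = band
    if window == "hann":
        x = x * np.hanning(x.size)
    elif window is not None:
        raise InvalidArgumentError(f"unknown window {window!r}")
    nfft = 1 << int(np.ceil(np.log2(max(8 * x.size, fs / RATE_RESOLUTION_HZ))))
    spectrum = np.abs(np.fft.rfft(x, nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise InvalidSamplingRateError("no FFT bins inside the requested band")
    freqs, spectrum = freqs[mask], spectrum[mask]
    peak = int(np.argmax(spectrum))  # first max -> lowest frequency on ties
    return RateEstimate(rate_hz=float(freqs[peak]),
                        peak_amplitude=float(spectrum[peak]),
                        freqs=freqs, spectrum=spectrum, band=(lo, hi))
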