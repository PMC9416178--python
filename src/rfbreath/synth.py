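"""Backscatter phase model and a seeded multi-tag breathing simulator.

Physical model
--------------
A passive UHF tag at distance ``R`` from the reader antenna returns a
carrier phase

    theta = 2*pi * 2R/lambda + theta_t + theta_r + theta_tag   (mod 2*pi)

where ``lambda = c/f`` is the carrier wavelength and the three offsets are
constant hardware phase shifts of the transmitter, receiver and tag.  The
reader quantises phase onto a 12-bit grid (step ``2*pi/4096 ~ 0.0015`` rad)
and may report either ``theta`` or ``(theta + pi) mod 2*pi`` — the pi-radian
ambiguity the preprocessing stage removes.

Breathing moves the chest/abdomen wall (and the tag on it) sinusoidally by
a few millimetres (peak-to-peak displacement ~0.5 cm) at 0.2–0.33 Hz, so the
round-trip phase oscillates with peak-to-peak amplitude ``8*pi*A/lambda``.
The simulator composes this motion model with the phase map, quantisation,
Gaussian phase noise, i.i.d. pi-ambiguity events, 2*pi wrapping and
irregular (jittered) sampling, and emits the generative ground truth
alongside the streams so recovery can be scored exactly.

Doppler utilities are included for completeness only: the frequency shift a
breathing chest induces (``2 v cos(alpha) / lambda``, well below 1e-2 Hz) is
far beneath the reader's 0.0625 Hz Doppler resolution, which is why phase,
not Doppler, carries the respiratory signal.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .epc import encode_epc
from .errors import InvalidArgumentError
from .streams import (PHASE_CODES, PHASE_RESOLUTION_RAD, TWO_PI, TagStream)

#: Propagation speed of electromagnetic waves, m/s.
SPEED_OF_LIGHT = 3.0e8

#: Default carrier frequency of the reader's lowest channel, Hz.
DEFAULT_CARRIER_HZ = 920.625e6

#: Doppler-shift resolution of the reader, Hz (2**-4).
DOPPLER_RESOLUTION_HZ = 2.0 ** -4


def _listify(obj):
    """Recursively turn tuples into lists and numpy scalars into Python ones
    so YAML/JSON can carry them."""
    if isinstance(obj, (list, tuple)):
        return [_listify(o) for o in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


# --------------------------------------------------------------------------
# phase model
# --------------------------------------------------------------------------

def wavelength(carrier_freq_hz: float) -> float:
    """Carrier wavelength ``c / f`` in metres."""
    if not carrier_freq_hz > 0:
        raise InvalidArgumentError(f"carrier frequency must be > 0, got {carrier_freq_hz}")
    return SPEED_OF_LIGHT / carrier_freq_hz


@dataclass(frozen=True)
class PhaseModelParams:
    """Constants of the distance -> phase map.

    The three hardware offsets are constant during one use of the reader;
    by default they are lumped into ``theta_tag``.
    """

    carrier_freq_hz: float = DEFAULT_CARRIER_HZ
    theta_t: float = 0.0
    theta_r: float = 0.0
    theta_tag: float = 0.0
    c: float = SPEED_OF_LIGHT

    def __post_init__(self):
        if not self.carrier_freq_hz > 0:
            raise InvalidArgumentError("carrier_freq_hz must be > 0")
        for name in ("theta_t", "theta_r", "theta_tag"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidArgumentError(f"{name} must be finite")

    @property
    def wavelength_m(self) -> float:
        return self.c / self.carrier_freq_hz

    @property
    def offset(self) -> float:
        return self.theta_t + self.theta_r + self.theta_tag


def ideal_phase(r_m, params: PhaseModelParams | None = None):
    """Round-trip carrier phase of a tag at distance ``r_m``, wrapped to [0, 2*pi)."""
    params = params or PhaseModelParams()
    r = np.asarray(r_m, dtype=float)
    if np.any(r <= 0):
        raise InvalidArgumentError("distance must be > 0")
    theta = (TWO_PI * 2.0 * r / params.wavelength_m + params.offset) % TWO_PI
    return float(theta) if np.isscalar(r_m) else theta


def quantize_phase(phase):
    """Map phase to the reader's 12-bit grid.

    Returns ``(raw_code, quantized_phase)`` with
    ``raw_code = round(((phase mod 2*pi)/2*pi) * 4096) mod 4096`` and
    ``quantized_phase = raw_code * 2*pi/4096``; the (circular) quantisation
    error never exceeds half a step, pi/4096.
    """
    p = np.asarray(phase, dtype=float)
    if not np.all(np.isfinite(p)):
        raise InvalidArgumentError("phase must be finite")
    raw = np.rint((p % TWO_PI) / PHASE_RESOLUTION_RAD).astype(np.int64) % PHASE_CODES
    quant = raw * PHASE_RESOLUTION_RAD
    if np.isscalar(phase):
        return int(raw), float(quant)
    return raw, quant


def doppler_shift(v_mps: float, alpha_rad: float, lambda_m: float) -> float:
    """Doppler shift ``2 v cos(alpha) / lambda`` of a tag moving at speed v."""
    if not lambda_m > 0:
        raise InvalidArgumentError("wavelength must be > 0")
    return 2.0 * v_mps * math.cos(alpha_rad) / lambda_m


def doppler_from_phase(dtheta_rad: float, dt_s: float) -> float:
    """Doppler shift inferred from a phase increment: ``dtheta / (4*pi*dT)``."""
    if not dt_s > 0:
        raise InvalidArgumentError("dT must be > 0")
    return dtheta_rad / (4.0 * math.pi * dt_s)


# --------------------------------------------------------------------------
# breathing scenario
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TagPlacement:
    """Motion parameters of one tag on one body part.

    ``amplitude_m`` is the sinusoidal displacement amplitude; the default
    2.5 mm gives the ~0.5 cm peak-to-peak chest excursion of quiet breathing.
    """

    baseline_distance_m: float = 1.2
    amplitude_m: float = 0.0025
    rate_hz: float = 0.25
    phase_offset_rad: float = 0.0

    def __post_init__(self):
        if not self.baseline_distance_m > 0:
            raise InvalidArgumentError("baseline_distance_m must be > 0")
        if self.amplitude_m < 0:
            raise InvalidArgumentError("amplitude_m must be >= 0")
        if not self.rate_hz >= 0:
            raise InvalidArgumentError("rate_hz must be >= 0")


@dataclass(frozen=True)
class SubjectSpec:
    """One monitored person: a chest tag, an abdomen tag, optional apnea.

    Chest and abdomen may have different amplitudes (thoracic vs abdominal
    vs mixed breathing).  During ``apnea_intervals`` (seconds) the breathing
    displacement of both tags is forced to zero.
    """

    subject_id: int
    chest: TagPlacement = field(default_factory=TagPlacement)
    abdomen: TagPlacement = field(default_factory=TagPlacement)
    apnea_intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        for t0, t1 in self.apnea_intervals:
            if not t1 > t0 >= 0:
                raise InvalidArgumentError(
                    f"apnea interval ({t0}, {t1}) must satisfy 0 <= t0 < t1")

    def placement(self, body_part: str) -> TagPlacement:
        return getattr(self, body_part)


@dataclass(frozen=True)
class BreathingScenario:
    """Generative description of a multi-subject recording session."""

    subjects: tuple[SubjectSpec, ...]
    sample_rate_mean_hz: float = 30.0
    sample_jitter: float = 0.2
    noise_sigma_rad: float = 0.02
    ambiguity_prob: float = 0.05
    carrier_freq_hz: float = DEFAULT_CARRIER_HZ
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "subjects", tuple(self.subjects))
        if not 0.0 <= self.ambiguity_prob <= 1.0:
            raise InvalidArgumentError("ambiguity_prob must be in [0, 1]")
        if not 0.0 <= self.sample_jitter < 1.0:
            raise InvalidArgumentError("sample_jitter must be in [0, 1)")
        if self.noise_sigma_rad < 0:
            raise InvalidArgumentError("noise_sigma_rad must be >= 0")
        rates = [p.rate_hz for s in self.subjects
                 for p in (s.chest, s.abdomen)]
        if rates and not self.sample_rate_mean_hz > 2 * max(rates):
            raise InvalidArgumentError(
                "sample_rate_mean_hz must exceed twice the fastest breathing rate")

    @property
    def params(self) -> PhaseModelParams:
        return PhaseModelParams(carrier_freq_hz=self.carrier_freq_hz)

    def to_dict(self) -> dict:
        return _listify(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "BreathingScenario":
        subjects = tuple(
            SubjectSpec(
                subject_id=s["subject_id"],
                chest=TagPlacement(**s["chest"]),
                abdomen=TagPlacement(**s["abdomen"]),
                apnea_intervals=tuple(tuple(iv) for iv in s.get("apnea_intervals", ())),
            )
            for s in d["subjects"]
        )
        kwargs = {k: v for k, v in d.items() if k != "subjects"}
        return cls(subjects=subjects, **kwargs)


def default_scenario(n_subjects: int = 3, seed: int = 0, **overrides) -> BreathingScenario:
    """A realistic multi-subject scenario: distinct rates in the 0.2–0.33 Hz
    band, ~0.5 cm peak-to-peak displacement, subjects 0.8–2 m from the antenna."""
    if n_subjects < 1:
        raise InvalidArgumentError("need at least one subject")
    if n_subjects == 1:
        rates = [0.25]
    else:
        rates = [float(r) for r in np.linspace(0.20, 0.33, n_subjects)]
    subjects = []
    for i, fr in enumerate(rates):
        r0 = 0.8 + 0.3 * i
        subjects.append(SubjectSpec(
            subject_id=i + 1,
            chest=TagPlacement(baseline_distance_m=r0, amplitude_m=0.0025,
                               rate_hz=fr, phase_offset_rad=0.0),
            abdomen=TagPlacement(baseline_distance_m=r0 + 0.03, amplitude_m=0.0025,
                                 rate_hz=fr, phase_offset_rad=0.4),
        ))
    return BreathingScenario(subjects=tuple(subjects), seed=seed, **overrides)


# --------------------------------------------------------------------------
# simulator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TagTruth:
    """Ground truth for one simulated tag stream."""

    epc: str
    subject_id: int
    body_part: str
    rate_hz: float
    amplitude_m: float
    baseline_distance_m: float
    apnea_intervals: tuple[tuple[float, float], ...]


_BP_SEED = {"chest": 1, "abdomen": 2}


def _tag_timestamps(rng, duration_s: float, rate_hz: float, jitter: float) -> np.ndarray:
    """Strictly increasing integer-ms timestamps with jittered inter-arrivals."""
    mean_dt = 1.0 / rate_hz
    n_max = int(duration_s * rate_hz * (1.0 / max(1.0 - jitter, 1e-9))) + 2
    dts = mean_dt * (1.0 + rng.uniform(-jitter, jitter, size=n_max))
    t = np.concatenate(([0.0], np.cumsum(dts)))
    t = t[t <= duration_s]
    t_ms = np.rint(t * 1000.0).astype(np.int64)
    # integer rounding can only collide at extreme rates; enforce strictness
    for i in range(1, len(t_ms)):
        if t_ms[i] <= t_ms[i - 1]:
            t_ms[i] = t_ms[i - 1] + 1
    return t_ms


def simulate_streams(scenario: BreathingScenario, duration_s: float
                     ) -> tuple[dict[str, TagStream], dict[str, TagTruth]]:
    """Simulate one recording session.

    For every subject x body part one stream is produced:
    ``R(t) = R0 + A sin(2 pi fr t + offset)`` (A forced to 0 inside apnea
    intervals), mapped through the phase model, perturbed by Gaussian phase
    noise, quantised to the 12-bit grid, and each sample independently
    replaced by ``(phase + pi) mod 2*pi`` with probability
    ``ambiguity_prob``.  Identical scenarios and seeds give identical
    output.  Returns ``(streams, truth)`` keyed by EPC.
    """
    if not duration_s > 0:
        raise InvalidArgumentError("duration must be > 0")
    if not scenario.subjects:
        raise InvalidArgumentError("scenario has no subjects")

    params = scenario.params
    streams: dict[str, TagStream] = {}
    truth: dict[str, TagTruth] = {}
    for subject in scenario.subjects:
        for body_part in ("chest", "abdomen"):
            place = subject.placement(body_part)
            # per-tag substream: deterministic regardless of iteration order
            ss = np.random.SeedSequence(
                [scenario.seed, subject.subject_id, _BP_SEED[body_part]])
            rng = np.random.default_rng(ss)

            t_ms = _tag_timestamps(rng, duration_s,
                                   scenario.sample_rate_mean_hz,
                                   scenario.sample_jitter)
            t = t_ms / 1000.0

            amp = np.full_like(t, place.amplitude_m)
            for t0, t1 in subject.apnea_intervals:
                amp[(t >= t0) & (t < t1)] = 0.0
            r = place.baseline_distance_m + amp * np.sin(
                TWO_PI * place.rate_hz * t + place.phase_offset_rad)

            theta = ideal_phase(r, params)
            if scenario.noise_sigma_rad > 0:
                theta = (theta + rng.normal(0.0, scenario.noise_sigma_rad,
                                            size=theta.shape)) % TWO_PI
            raw, phase = quantize_phase(theta)

            flips = rng.random(len(phase)) < scenario.ambiguity_prob
            phase = np.where(flips, (phase + np.pi) % TWO_PI, phase)
            raw = np.where(flips, (raw + PHASE_CODES // 2) % PHASE_CODES, raw)

            # RSSI placeholder: constant level + reader noise, 0.5 dB grid
            rssi = np.round((-55.0 + 0.5 * rng.standard_normal(len(phase))) * 2) / 2

            epc = encode_epc(subject.subject_id, body_part)
            streams[epc] = TagStream(epc=epc, t_ms=t_ms, phase=phase,
                                     raw_code=raw, rssi=rssi)
            truth[epc] = TagTruth(
                epc=epc, subject_id=subject.subject_id, body_part=body_part,
                rate_hz=place.rate_hz, amplitude_m=place.amplitude_m,
                baseline_distance_m=place.baseline_distance_m,
                apnea_intervals=subject.apnea_intervals)
    return streams, truth
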