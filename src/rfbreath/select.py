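"""Tag selection, per-subject assessment, apnea detection and accuracy.

Each monitored person wears two tags (chest, abdomen).  A tag is considered
to be observing real respiration only if its reconstructed extremum
difference sequence satisfies two principles:

* **length** — enough extremes per unit time, ``2 * fmin * dt < L`` with
  ``fmin = 0.05`` Hz (an apparent rate below 0.05 Hz is not breathing);
* **amplitude** — mean absolute difference above a threshold, i.e. the
  phase actually swings on a respiration scale.

If one tag fails, the other is consulted; if both fail, the person is
flagged as apneic.  Monitoring accuracy against a reference rate ``R`` is
``100 * (1 - |R_hat - R| / R)`` percent.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import preprocess, rate as rate_mod, reconstruct
from .config import PipelineConfig
from .epc import BODY_PARTS, decode_epc, encode_epc
from .errors import (InsufficientDataError, InvalidArgumentError,
                     InvalidSamplingRateError, PhaseLogFormatError,
                     UnmappedTagError)
from .rate import RateEstimate
from .reconstruct import DiffSequence
from .streams import TagStream

DEFAULT_FMIN_HZ = 0.05


# --------------------------------------------------------------------------
# subject map
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectMap:
    """EPC -> (subject_id, body_part), at most one tag per body part per subject."""

    entries: dict[str, tuple[int, str]]

    def __post_init__(self):
        seen: set[tuple[int, str]] = set()
        for epc, (sid, bp) in self.entries.items():
            if bp not in BODY_PARTS:
                raise InvalidArgumentError(
                    f"EPC {epc}: body part must be one of {BODY_PARTS}, got {bp!r}")
            if (sid, bp) in seen:
                raise InvalidArgumentError(
                    f"subject {sid} has more than one {bp} tag")
            seen.add((sid, bp))

    def lookup(self, epc: str) -> tuple[int, str]:
        try:
            return self.entries[epc]
        except KeyError:
            raise UnmappedTagError(epc) from None

    def subjects(self) -> dict[int, dict[str, str]]:
        """subject_id -> {body_part: epc}, chest first."""
        out: dict[int, dict[str, str]] = {}
        for epc, (sid, bp) in self.entries.items():
            out.setdefault(sid, {})[bp] = epc
        return {sid: {bp: tags[bp] for bp in BODY_PARTS if bp in tags}
                for sid, tags in sorted(out.items())}

    @classmethod
    def from_epcs(cls, epcs) -> "SubjectMap":
        """Decode the (id, body part) word embedded in each EPC."""
        return cls(entries={epc: decode_epc(epc) for epc in epcs})

    @classmethod
    def from_csv(cls, path) -> "SubjectMap":
        """Read a mapping file with header ``epc,subject_id,body_part``."""
        entries: dict[str, tuple[int, str]] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"epc", "subject_id", "body_part"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise PhaseLogFormatError(
                    f"subject map {path} must have columns {sorted(required)}")
            for row in reader:
                entries[row["epc"]] = (int(row["subject_id"]), row["body_part"])
        return cls(entries=entries)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epc", "subject_id", "body_part"])
            for epc, (sid, bp) in self.entries.items():
                writer.writerow([epc, sid, bp])


# --------------------------------------------------------------------------
# selection principles
# --------------------------------------------------------------------------

def min_expected_extrema(dt_s: float, fmin: float = DEFAULT_FMIN_HZ) -> float:
    """``2 * fmin * dt``: the fewest difference entries credible breathing
    produces in ``dt`` seconds (each breath yields a peak and a trough)."""
    if not dt_s > 0:
        raise InvalidArgumentError("monitoring time must be > 0")
    return 2.0 * fmin * dt_s


def length_principle(L: int, dt_s: float, fmin: float = DEFAULT_FMIN_HZ) -> bool:
    """True iff ``2 * fmin * dt < L``."""
    if L < 0:
        raise InvalidArgumentError("L must be >= 0")
    return min_expected_extrema(dt_s, fmin) < L


def amplitude_principle(d, threshold: float) -> bool:
    """True iff the mean |d_i| exceeds ``threshold``; an empty sequence fails."""
    if not threshold > 0:
        raise InvalidArgumentError("threshold must be > 0")
    if isinstance(d, DiffSequence):
        d = d.d
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        return False
    return bool(np.mean(np.abs(d)) > threshold)


def accuracy(rate_est_hz: float, rate_true_hz: float) -> float:
    """Monitoring accuracy ``100 * (1 - |R_hat - R| / R)`` percent.

    Can be negative when the estimate is off by more than the true rate.
    """
    if not rate_true_hz > 0:
        raise InvalidArgumentError("true rate must be > 0")
    return 100.0 * (1.0 - abs(rate_est_hz - rate_true_hz) / rate_true_hz)


# --------------------------------------------------------------------------
# per-tag analysis
# --------------------------------------------------------------------------

@dataclass
class TagReport:
    """Everything the selector needs to know about one tag."""

    epc: str
    subject_id: int | None
    body_part: str | None
    fs_hz: float
    duration_s: float
    wavelet_level: int | None
    diffs: DiffSequence
    mean_abs_diff: float
    passes_length: bool
    passes_amplitude: bool
    rate: RateEstimate | None = None

    @property
    def L(self) -> int:
        return self.diffs.L

    @property
    def informative(self) -> bool:
        """The tag is observing real respiration: both principles hold."""
        return self.passes_length and self.passes_amplitude


def _analyze_clean(clean: preprocess.CleanStream, config: PipelineConfig,
                   use_bandpass: bool, estimate_rate: bool,
                   subject_id=None, body_part=None) -> TagReport:
    x = rate_mod.remove_dc(clean.phase)
    if use_bandpass:
        x = rate_mod.bandpass(x, clean.fs, band=config.band,
                              order=config.filter_order,
                              zero_phase=config.zero_phase)
    rate_est = None
    if estimate_rate:
        try:
            rate_est = rate_mod.extract_rate(x, clean.fs, band=config.band,
                                             window=config.fft_window)
        except InsufficientDataError:
            rate_est = None

    level = None
    diffs = DiffSequence(extrema=())
    try:
        plan = reconstruct.select_levels(clean.fs, *config.level_band,
                                         frr=config.frr_hz)
        plan = reconstruct.WaveletPlan(fs=plan.fs, n=plan.n, omega=plan.omega,
                                       frr=plan.frr, wavelet=config.wavelet)
        level = plan.n
        coeffs, times = reconstruct.approximation(x, plan, t0=clean.t[0])
        extrema = reconstruct.detect_extrema(coeffs, times)
        extrema = reconstruct.filter_extrema(extrema, alpha=config.alpha)
        diffs = reconstruct.enforce_alternation(reconstruct.difference(extrema))
    except (InsufficientDataError, InvalidSamplingRateError):
        pass  # too little data -> empty difference sequence -> tag fails

    d = diffs.d
    mean_abs = float(np.mean(np.abs(d))) if d.size else 0.0
    duration = clean.duration_s
    return TagReport(
        epc=clean.epc, subject_id=subject_id, body_part=body_part,
        fs_hz=clean.fs, duration_s=duration, wavelet_level=level,
        diffs=diffs, mean_abs_diff=mean_abs,
        passes_length=(duration > 0 and length_principle(diffs.L, duration,
                                                         config.fmin_hz)),
        passes_amplitude=amplitude_principle(d, config.amplitude_threshold_rad),
        rate=rate_est)


def analyze_tag(stream: TagStream, config: PipelineConfig | None = None,
                subject_map: SubjectMap | None = None,
                use_bandpass: bool = True, estimate_rate: bool = True) -> TagReport:
    """Run the full chain (clean -> filter -> rate -> reconstruct -> principles)
    on one tag stream."""
    config = config or PipelineConfig()
    sid = bp = None
    if subject_map is not None:
        sid, bp = subject_map.lookup(stream.epc)
    clean = preprocess.clean_stream(stream, config.delta_ambiguity,
                                    config.delta_unwrap)
    return _analyze_clean(clean, config, use_bandpass, estimate_rate,
                          subject_id=sid, body_part=bp)


# --------------------------------------------------------------------------
# per-subject assessment and reports
# --------------------------------------------------------------------------

def assess_subject(tag_reports) -> tuple[TagReport | None, bool]:
    """Select the informative tag for one subject; flag apnea if none is.

    The chest tag is preferred when both pass; a subject with every tag
    failing a principle is apneic.
    """
    reports = list(tag_reports)
    if not 1 <= len(reports) <= 2:
        raise InvalidArgumentError("a subject has one or two tags")
    order = {bp: i for i, bp in enumerate(BODY_PARTS)}
    reports.sort(key=lambda r: order.get(r.body_part, len(order)))
    passing = [r for r in reports if r.informative]
    if passing:
        return passing[0], False
    return None, True


@dataclass
class SubjectResult:
    subject_id: int
    selected_epc: str | None
    apnea: bool
    rate_hz: float | None

    @property
    def rate_bpm(self) -> float | None:
        return None if self.rate_hz is None else 60.0 * self.rate_hz


@dataclass
class MonitoringReport:
    """Pipeline output: per-tag verdicts plus per-subject selection."""

    tags: dict[str, TagReport]
    subjects: dict[int, SubjectResult]

    def to_dict(self) -> dict:
        return {
            "tags": {
                epc: {
                    "subject_id": r.subject_id,
                    "body_part": r.body_part,
                    "fs_hz": r.fs_hz,
                    "duration_s": r.duration_s,
                    "wavelet_level": r.wavelet_level,
                    "L": r.L,
                    "mean_abs_diff_rad": r.mean_abs_diff,
                    "passes_length": r.passes_length,
                    "passes_amplitude": r.passes_amplitude,
                    "rate_hz": None if r.rate is None else r.rate.rate_hz,
                    "rate_bpm": None if r.rate is None else r.rate.rate_bpm,
                }
                for epc, r in self.tags.items()
            },
            "subjects": {
                str(sid): {
                    "selected_epc": s.selected_epc,
                    "apnea": s.apnea,
                    "rate_hz": s.rate_hz,
                    "rate_bpm": s.rate_bpm,
                }
                for sid, s in self.subjects.items()
            },
        }


def monitor(streams: dict[str, TagStream], subject_map: SubjectMap,
            config: PipelineConfig | None = None) -> MonitoringReport:
    """Full monitoring pass over a multi-tag recording."""
    config = config or PipelineConfig()
    tags = {epc: analyze_tag(s, config, subject_map) for epc, s in streams.items()}
    subjects: dict[int, SubjectResult] = {}
    for sid, part_to_epc in subject_map.subjects().items():
        reports = [tags[epc] for epc in part_to_epc.values() if epc in tags]
        if not reports:
            continue
        selected, apnea = assess_subject(reports)
        rate_hz = None
        if selected is not None and selected.rate is not None:
            rate_hz = selected.rate.rate_hz
        subjects[sid] = SubjectResult(
            subject_id=sid,
            selected_epc=None if selected is None else selected.epc,
            apnea=apnea, rate_hz=rate_hz)
    return MonitoringReport(tags=tags, subjects=subjects)


# --------------------------------------------------------------------------
# apnea detection on sliding windows
# --------------------------------------------------------------------------

@dataclass
class ApneaResult:
    subject_id: int
    apnea: bool
    flagged_windows: list[tuple[float, float]] = field(default_factory=list)


def _window_informative(diffs: DiffSequence, w0: float, w1: float,
                        config: PipelineConfig) -> bool:
    """Re-evaluate both principles on the extremes falling inside a window."""
    values = [e.value for e in diffs.extrema if w0 - 1e-9 <= e.time <= w1 + 1e-9]
    L = max(len(values) - 1, 0)
    d = np.diff(values)
    return (length_principle(L, w1 - w0, config.fmin_hz)
            and amplitude_principle(d, config.amplitude_threshold_rad))


def detect_apnea(streams: dict[str, TagStream], subject_map: SubjectMap,
                 config: PipelineConfig | None = None,
                 window_s: float | None = None, hop_s: float | None = None,
                 use_bandpass: bool = False) -> dict[int, ApneaResult]:
    """Flag subjects whose every tag fails a principle in some window.

    The reconstruction chain runs once over each tag's full recording (so
    the extremum filter threshold reflects breathing-scale swings and
    prunes noise extremes during a breath-hold); the two principles are
    then re-evaluated on the surviving extremes inside each sliding window
    (default 20 s, hop half a window).  The bandpass stage is off by
    default: its transient smears the onset of a breath-hold, and apnea
    detection is more faithful without it.
    """
    config = config or PipelineConfig()
    window_s = window_s or config.apnea_window_s
    hop_s = hop_s or window_s / 2.0

    reports: dict[str, TagReport] = {}
    for epc, stream in streams.items():
        sid_bp = subject_map.lookup(epc)
        clean = preprocess.clean_stream(stream, config.delta_ambiguity,
                                        config.delta_unwrap)
        reports[epc] = _analyze_clean(clean, config, use_bandpass,
                                      estimate_rate=False,
                                      subject_id=sid_bp[0], body_part=sid_bp[1])

    results: dict[int, ApneaResult] = {}
    for sid, part_to_epc in subject_map.subjects().items():
        epcs = [epc for epc in part_to_epc.values() if epc in streams]
        if not epcs:
            continue
        t0 = max(float(streams[epc].t_s[0]) for epc in epcs)
        t_end = min(float(streams[epc].t_s[-1]) for epc in epcs)
        starts = [t0]
        while starts[-1] + window_s < t_end - 1e-9:
            starts.append(min(starts[-1] + hop_s, t_end - window_s))
        result = ApneaResult(subject_id=sid, apnea=False)
        for w0 in starts:
            w1 = min(w0 + window_s, t_end)
            if not any(_window_informative(reports[epc].diffs, w0, w1, config)
                       for epc in epcs):
                result.apnea = True
                result.flagged_windows.append((float(w0), float(w1)))
        results[sid] = result
    return results
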