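"""Pipeline configuration with the method's published defaults."""
from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the monitoring pipeline in one place.

    Defaults are the values the method was designed around: disambiguation
    threshold 1.8 rad, unwrap threshold 1.0 rad, 2nd-order Butterworth over
    0.1–1.0 Hz, extremum filter alpha 0.5, minimum credible rate
    fmin = 0.05 Hz, reference rate 0.3 Hz, db2 wavelet.  The amplitude
    threshold (0.015 rad, ten quantisation steps) separates
    respiration-scale phase swings from quantisation noise.
    """

    delta_ambiguity: float = 1.8
    delta_unwrap: float = 1.0
    band: tuple[float, float] = (0.1, 1.0)
    filter_order: int = 2
    zero_phase: bool = True
    fft_window: str | None = None
    alpha: float = 0.5
    fmin_hz: float = 0.05
    amplitude_threshold_rad: float = 0.015
    frr_hz: float = 0.3
    wavelet: str = "db2"
    level_band: tuple[float, float] = (0.6, 2.0)
    apnea_window_s: float = 20.0
    spline_fs_hz: float = 10.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "band", tuple(self.band))
        object.__setattr__(self, "level_band", tuple(self.level_band))
        if not 0 < self.band[0] < self.band[1]:
            raise InvalidArgumentError(f"invalid band {self.band}")
        if self.filter_order < 1:
            raise InvalidArgumentError("filter_order must be >= 1")
        if not 0 < self.alpha <= 1:
            raise InvalidArgumentError("alpha must be in (0, 1]")
        for name in ("delta_ambiguity", "fmin_hz", "amplitude_threshold_rad",
                     "frr_hz", "apnea_window_s", "spline_fs_hz"):
            if not getattr(self, name) > 0:
                raise InvalidArgumentError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        d["level_band"] = list(self.level_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
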