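"""Exception hierarchy for the monitoring pipeline."""


class RfbreathError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(RfbreathError, ValueError):
    """A parameter violates its contract (non-positive frequency, bad delta, ...)."""


class InsufficientDataError(RfbreathError, ValueError):
    """The input is too short for the requested operation."""


class InvalidSamplingRateError(RfbreathError, ValueError):
    """The sampling rate cannot support the requested band or decomposition."""


class UnmappedTagError(RfbreathError, KeyError):
    """An EPC has no (subject, body part) mapping."""

    def __init__(self, epc: str):
        super().__init__(epc)
        self.epc = epc

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"EPC {self.epc!r} is not present in the subject map"


class PhaseLogFormatError(RfbreathError, ValueError):
    """A phase log file is malformed; the message names the offending line."""
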