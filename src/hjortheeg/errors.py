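"""Exception hierarchy shared across the pipeline."""


class HjorthEEGError(Exception):
    """Base class for all package errors."""


class InvalidBandError(HjorthEEGError):
    """A frequency band is empty, inverted, or exceeds Nyquist."""


class SignalTooShortError(HjorthEEGError):
    """A signal is too short for the requested operation."""


class ChannelMismatchError(HjorthEEGError):
    """Channels of a recording do not match the expected montage."""

    def __init__(self, missing=(), unknown=()):
        self.missing = tuple(missing)
        self.unknown = tuple(unknown)
        parts = []
        if self.missing:
            parts.append(f"missing channels: {', '.join(self.missing)}")
        if self.unknown:
            parts.append(f"unknown channels: {', '.join(self.unknown)}")
        super().__init__("; ".join(parts) or "channel mismatch")


class AlignmentError(HjorthEEGError):
    """Inputs that must agree in length or epoch count do not."""


class ConfigurationError(HjorthEEGError):
    """A configuration value is invalid for the requested operation."""


class UndefinedMetricError(HjorthEEGError):
    """A metric is undefined for the given inputs (e.g. one class absent)."""


class FoldFailureError(HjorthEEGError):
    """A cross-validation fold failed; carries the held-out subject."""

    def __init__(self, subject, cause):
        self.subject = subject
        super().__init__(f"fold holding out subject {subject!r} failed: {cause}")
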