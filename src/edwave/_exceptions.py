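"""Exception types shared across edwave modules."""


class EdwaveError(Exception):
    """Base class for edwave errors."""


class SignalFormatError(EdwaveError, ValueError):
    """A signal file could not be parsed under its declared format."""


class MissingParameterError(EdwaveError, ValueError):
    """A required side parameter (e.g. sampling rate for CSV) was not supplied."""


class LabelValidationError(EdwaveError, ValueError):
    """A label or wave-annotation record violates the label-file contract."""


class DegenerateNormalizationError(EdwaveError, ValueError):
    """The chord-area normalization factor N was <= 0 for a (peak, MP) pair."""


class InsufficientSampleError(EdwaveError, ValueError):
    """Too few annotated waves to derive detection thresholds."""


class ConfigurationError(EdwaveError, ValueError):
    """An operation was configured inconsistently with its inputs."""


class UndefinedMetricError(EdwaveError, ValueError):
    """A per-class metric is undefined (e.g. no positive examples of a class)."""
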