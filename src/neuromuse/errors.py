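"""Exception hierarchy.

Every error raised by the library derives from :class:`NeuromuseError`, so
callers (and the CLI) can distinguish user-input problems from bugs. The
subclasses map onto the distinct failure categories of the pipeline:
montage problems, malformed files, invalid parameters, numerically
degenerate inputs, structural problems in scores, and insufficient data.
"""


class NeuromuseError(Exception):
    """Base class for all library errors."""

    exit_code = 1


class MontageError(NeuromuseError):
    """A required electrode label is absent from a recording."""

    exit_code = 3


class FormatError(NeuromuseError):
    """A file could not be parsed (ragged rows, non-numeric cells, bad MIDI)."""

    exit_code = 4


class ParameterError(NeuromuseError):
    """A configuration value violates its contract (e.g. band edge >= Nyquist)."""

    exit_code = 5


class DegenerateInputError(NeuromuseError):
    """Input is numerically degenerate (zero alpha sum, constant series, ...)."""

    exit_code = 6


class StructureError(NeuromuseError):
    """A score violates a structural requirement (e.g. polyphony)."""

    exit_code = 7


class ModelError(NeuromuseError):
    """Model/feature dimension mismatch or unusable design matrix."""

    exit_code = 8


class CoverageError(NeuromuseError):
    """A session log does not cover the requested analysis window."""

    exit_code = 9


class InsufficientDataError(NeuromuseError):
    """Too few observations for the requested statistic."""

    exit_code = 10


class ConfigError(NeuromuseError):
    """Invalid run configuration (schema violation, empty playlist, ...)."""

    exit_code = 11
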