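"""Exception hierarchy shared across the pipeline.

The CLI maps :class:`ConfigurationError` to exit code 2 and
:class:`DataError` (and subclasses) to exit code 3.
"""


class SatrainError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SatrainError):
    """Invalid configuration value; the message names the offending field."""


class DataError(SatrainError):
    """Malformed, degenerate or insufficient input data."""


class DegenerateDataError(DataError):
    """Input formally valid but statistically degenerate (e.g. constant RTs)."""


class JoinError(DataError):
    """A trial row failed to join to exactly one block-scores row."""


class QualityError(DataError):
    """Signal quality too poor to continue (e.g. >25% bad EEG channels)."""
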