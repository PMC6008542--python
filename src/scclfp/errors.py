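"""Exception hierarchy for the LFP analysis pipeline.

Every error raised by this package derives from :class:`ScclfpError`
(warnings derive from :class:`ScclfpWarning`), so callers can catch the
whole family at a pipeline boundary while tests assert specific types.
"""


class ScclfpError(Exception):
    """Base class for all package errors."""


class ScclfpWarning(UserWarning):
    """Base class for all package warnings."""


# --- io ---------------------------------------------------------------


class FormatError(ScclfpError):
    """A file is unreadable, truncated, or violates its container format."""


class EmptyRecordingError(ScclfpError):
    """A recording contains no signal channels."""


class SchemaError(ScclfpError):
    """A sidecar table row violates its schema (types, ranges, labels)."""


class DuplicateCycleError(SchemaError):
    """Two cycle rows share the same (patient, stimulation contact)."""


# --- preprocess -------------------------------------------------------


class NyquistError(ScclfpError):
    """Sampling rate too low for the requested filter band."""


class EmptyEpochError(ScclfpError):
    """Artifact pruning removed every sample of an epoch."""


class NoDifferentialError(ScclfpError):
    """The contact of interest has fewer than two flanking contacts."""


class EpochBoundsError(ScclfpError):
    """The recording does not cover the requested pre/post windows."""


# --- spectral ---------------------------------------------------------


class ShortEpochWarning(ScclfpWarning):
    """Epoch shorter than two cycles of the lowest analysis frequency."""


class DegenerateBaselineError(ScclfpError):
    """The pre-stimulation median is zero; relative change is undefined."""


class ConfigError(ScclfpError):
    """An analysis configuration value is out of its supported range."""


# --- stats ------------------------------------------------------------


class AllZeroError(ScclfpError):
    """Every observation equals the null value; no test is possible."""


class InsufficientDataError(ScclfpError):
    """Too few observations for the requested statistic."""


class DegenerateSampleError(ScclfpError):
    """Zero-variance sample; a standardized effect size is undefined."""


# --- clinical ---------------------------------------------------------


class UndefinedBaselineError(ScclfpError):
    """Baseline score of zero; a percent decrease is undefined."""
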