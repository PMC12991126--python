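"""Exception hierarchy for the perisacc pipeline.

Every stage raises a subclass of :class:`PerisaccError` so that the pipeline
driver can abort with the offending stage and entity attached.
"""


class PerisaccError(Exception):
    """Base class for all perisacc errors."""


class SchemaError(PerisaccError):
    """A session file violates the CSV schema or a session invariant.

    The message names the offending row/entity.
    """


class AbortedTrialError(PerisaccError):
    """An operation requiring a completed trial was given an aborted one."""


class DegenerateThresholdError(PerisaccError):
    """Velocity SD is zero, so no finite detection threshold exists.

    Raised on synthetic noiseless traces; callers should set a velocity floor
    or add measurement noise.
    """


class NoSaccadeError(PerisaccError):
    """No above-threshold, large-amplitude movement followed the go cue."""


class UndefinedRateError(PerisaccError):
    """A hit or false-alarm rate has a zero denominator."""


class DegenerateSplitError(PerisaccError):
    """A median split was requested on all-identical values."""


class DegenerateBaselineError(PerisaccError):
    """Baseline firing-rate SD is zero, so z-scoring is impossible."""


class DegenerateStatError(PerisaccError):
    """A significance test was handed data with no variance to test."""


class DataError(PerisaccError):
    """Required per-trial data (e.g. a saccade time) is missing."""


class ConfigError(PerisaccError):
    """A run configuration references unknown options or missing files."""
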