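"""Exception hierarchy for the gait-analysis pipeline.

Every error raised by the package derives from :class:`BroilerGaitError`
so that the pipeline driver can catch per-bird failures, log them and
continue over the remaining birds (mirroring how non-walking birds are
excluded from a live trial rather than aborting it).
"""


class BroilerGaitError(Exception):
    """Base class for all package errors."""


class FormatError(BroilerGaitError):
    """A keypoint table does not follow the expected CSV dialect."""


class ConfigError(BroilerGaitError):
    """A configuration value is out of range or unknown."""


class TooShortTrialError(BroilerGaitError):
    """A trial has too few frames for the requested operation."""


class BoundsNotSetError(BroilerGaitError):
    """Manual clip bounds were required but not set on the trial."""


class NoWalkError(BroilerGaitError):
    """No walking motion (no usable pose of any kind) detected for a bird."""


class NoPoseError(NoWalkError):
    """No candidate frame found for one specific pose kind."""


class DegeneratePoseError(BroilerGaitError):
    """A pose's geometry does not admit the requested feature (zero-length
    segment, inverted normalization factor, coincident feet, ...)."""


class InfeasibleGeometryError(BroilerGaitError):
    """Simulator parameters describe a physically impossible skeleton."""


class InsufficientDataError(BroilerGaitError):
    """Not enough observations for the requested statistic."""
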