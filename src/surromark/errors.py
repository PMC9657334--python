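"""Exception hierarchy shared across the pipeline.

Every error raised by surromark derives from :class:`SurromarkError`, so
callers (and the CLI) can catch pipeline failures without masking bugs.
"""


class SurromarkError(Exception):
    """Base class for all surromark errors."""


class StructuralError(SurromarkError, ValueError):
    """A table violates a structural invariant (duplicate ids, bad shape)."""


class TableParseError(SurromarkError, ValueError):
    """A cell or token could not be interpreted."""


class RangeError(SurromarkError, ValueError):
    """A numeric field lies outside its documented range."""


class ParameterError(SurromarkError, ValueError):
    """An argument or configuration value is invalid."""


class DataError(SurromarkError, ValueError):
    """Input data are insufficient or degenerate for the requested statistic."""


class StatisticError(SurromarkError, ValueError):
    """A statistic is undefined on these inputs (e.g. zero variance)."""


class StateError(SurromarkError, RuntimeError):
    """An operation was called on an object in an unusable state."""
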