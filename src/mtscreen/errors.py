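"""Exception hierarchy shared across the package.

Every error raised on purpose derives from :class:`MtscreenError`, so callers
(and the CLI) can catch package failures without swallowing programming bugs.
"""


class MtscreenError(Exception):
    """Base class for all mtscreen errors."""


class FormatError(MtscreenError, ValueError):
    """A table or file does not conform to the expected layout."""


class ConfigError(MtscreenError, ValueError):
    """A simulation or analysis configuration is invalid or incomplete."""


class DomainError(MtscreenError, ValueError):
    """A value lies outside the mathematical domain of an operation."""


class InsufficientReplicatesError(MtscreenError, ValueError):
    """A statistic requiring replication was asked of too few values."""


class InsufficientDataError(MtscreenError, ValueError):
    """A series or table is too short for the requested computation."""


class UndefinedSeparationError(MtscreenError, ArithmeticError):
    """Control groups have equal means; separation statistics are undefined."""
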