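"""Exception hierarchy shared across the package."""


class CobciError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CobciError, ValueError):
    """A configuration object violates one of its invariants."""


class PipelineError(CobciError, ValueError):
    """A signal-processing operation received invalid input."""


class DegenerateVarianceError(CobciError, ValueError):
    """A statistic is undefined because a variance term is zero."""


class ChannelMismatchError(CobciError, ValueError):
    """Channel labels or frequency grids do not line up across inputs."""


class TrialMismatchError(CobciError, ValueError):
    """Participants do not have the same number of trials."""


class ParseError(CobciError, ValueError):
    """A file could not be parsed; the message names the offending field."""


class SchemaError(CobciError, ValueError):
    """A structured record does not match a known schema version."""


class ProtocolError(CobciError, RuntimeError):
    """A session-protocol contract was violated."""
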