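"""Exception hierarchy for keystroke-session parsing and analysis."""


class KeydynError(Exception):
    """Base class for all package-specific errors."""


class EmptySessionError(KeydynError):
    """A session log contained no keystroke events."""


class MalformedLogError(KeydynError):
    """A session log violated the event invariants (fields, ordering, ranges)."""


class InsufficientEventsError(KeydynError):
    """An operation needs more keystroke events than the session provides."""


class EmptyAfterFilteringError(KeydynError):
    """Conditional flight-time filtering removed every element."""


class NoValidWindowsError(KeydynError):
    """No time window of the sequence satisfies the minimum-element rule."""


class ConstantWindowError(KeydynError):
    """A window has zero dispersion; standardized moments are undefined."""


class StratificationError(KeydynError):
    """A train/test split cannot represent both classes."""


class SchemaError(KeydynError):
    """A feature table is missing columns a fitted model requires."""


class NoSessionsError(KeydynError):
    """A subject-level vote was requested over an empty probability set."""


class ConfigError(KeydynError):
    """Inconsistent generator or pipeline configuration."""
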