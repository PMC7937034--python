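"""Exception hierarchy for funlink.

All package-specific failures derive from :class:`FunlinkError` so callers
can catch one base class at pipeline boundaries.
"""


class FunlinkError(Exception):
    """Base class for all funlink errors."""


class ParseError(FunlinkError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(FunlinkError):
    """An object violates a domain invariant (self-pair, bad score, ...)."""


class SchemaError(FunlinkError):
    """Feature columns or table columns do not match what was expected."""


class CapacityError(FunlinkError):
    """A sampling request exceeds the number of available items."""


class LeakageError(FunlinkError):
    """Held-out data overlaps training data."""


class IllPosedEquationError(FunlinkError):
    """The interactome-size equation has no meaningful solution
    (sensitivity <= 1 - specificity)."""


class UndefinedDensityError(FunlinkError):
    """Inter-set density has a zero denominator."""


class UndefinedAUCError(FunlinkError):
    """ROC AUC requested with a single-class label vector."""


class ConfigError(FunlinkError):
    """A run configuration contains unknown keys or invalid values."""
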