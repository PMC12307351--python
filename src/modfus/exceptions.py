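"""Exception hierarchy used across the package."""


class ModfusError(Exception):
    """Base class for package errors."""


class ValidationError(ModfusError, ValueError):
    """Invalid domain object (bad template, missing score, unknown label...)."""


class ScoreRangeError(ValidationError):
    """A clinical score fell outside its scale's declared range."""


class CapacityError(ModfusError, RuntimeError):
    """The built-in paraphrase bank cannot produce the requested variant count."""


class ConfigError(ModfusError, ValueError):
    """Invalid or unknown configuration key/value."""


class NumericError(ModfusError, ValueError):
    """Numerically invalid input (zero-norm rows, non-finite entries...)."""


class StratificationError(ModfusError, ValueError):
    """A class has too few members for the requested fold count."""


class UndefinedAUCError(ModfusError, ValueError):
    """AUC requested with only one class present in the truth vector."""


class UnsupportedDirectionError(ModfusError, ValueError):
    """Attention-map export requested for a direction with no spatial key axis."""
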