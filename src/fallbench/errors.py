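"""Exception hierarchy shared across the package."""


class FallbenchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FallbenchError):
    """A file does not parse under the declared dialect (e.g. missing column)."""


class DataError(FallbenchError):
    """Parsed data violate a recording invariant (e.g. non-monotone timestamps)."""


class ConfigError(FallbenchError):
    """An invalid configuration value (e.g. cutoff above Nyquist)."""


class ContractError(FallbenchError):
    """A caller violated an operation's precondition."""


class UndefinedOrientationError(FallbenchError):
    """Orientation cannot be derived from an all-zero acceleration vector."""


class UndefinedAngleError(FallbenchError):
    """An angle between vectors is undefined because one has zero norm."""
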