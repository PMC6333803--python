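"""Exception types shared across the package."""


class HemoclockError(Exception):
    """Base class for package errors."""


class ConfigError(HemoclockError, ValueError):
    """Invalid configuration; the message names the offending field."""


class DataError(HemoclockError, ValueError):
    """Input data violate an operation's preconditions."""


class DegenerateInputError(HemoclockError, ValueError):
    """Degenerate numerical input (zero variance, zero MAD, zero MAE...)."""
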