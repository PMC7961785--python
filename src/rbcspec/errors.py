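"""Exception hierarchy shared across the package."""


class RbcspecError(Exception):
    """Base class for all package errors."""


class InputError(RbcspecError):
    """Invalid data handed to an operation (bad values, wrong coverage, ...)."""


class ParseError(InputError):
    """A file could not be parsed; message names the offending line."""


class ConfigError(RbcspecError):
    """Invalid configuration value or combination."""


class UsageError(RbcspecError):
    """Operation called on an object in the wrong state (e.g. wrong stage)."""
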