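"""Exception hierarchy shared by all mirage modules."""


class MirageError(Exception):
    """Base class for all user-facing errors raised by this package."""


class ConfigError(MirageError):
    """A simulation or pipeline configuration is internally inconsistent."""


class InputError(MirageError):
    """An input object or file violates a documented precondition."""


class ParseError(InputError):
    """A file could not be parsed; the message names the offending record."""


class UndefinedCorrelationError(MirageError):
    """Pearson correlation requested on a zero-variance vector."""
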