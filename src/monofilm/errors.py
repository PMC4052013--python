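"""Exception hierarchy."""


class MonofilmError(Exception):
    """Base class for all package errors."""


class IsothermParseError(MonofilmError):
    """A delimited isotherm file could not be parsed; message names the line."""


class ValidationError(MonofilmError):
    """A domain-type invariant was violated; message names the rule."""


class DomainError(MonofilmError, ValueError):
    """An argument is outside the operation's mathematical domain."""


class RangeError(MonofilmError):
    """A requested pressure/area lies outside the data's usable range."""


class InsufficientDataError(MonofilmError):
    """Too few usable points for the requested numerical operation."""
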