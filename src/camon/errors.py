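"""Exception hierarchy. All validation failures derive from :class:`CamonError`."""


class CamonError(Exception):
    """Base class for all package errors."""


class InvalidArgument(CamonError, ValueError):
    """An operation received an argument violating its preconditions."""


class InvalidConfiguration(CamonError, ValueError):
    """A configuration object is internally inconsistent (e.g. empty analysis band)."""


class TooShortError(CamonError, ValueError):
    """Signal shorter than one analysis frame."""


class HeaderError(CamonError, ValueError):
    """CSV header does not match the documented dialect."""


class NonUniformGridError(CamonError, ValueError):
    """Time stamps do not lie on a uniform grid."""


class GapTooLongError(CamonError, ValueError):
    """A gap in the recording exceeds the interpolation policy limit."""


class InsufficientCoherenceError(CamonError, RuntimeError):
    """A metric needed coherent (ungated) samples but found none."""
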