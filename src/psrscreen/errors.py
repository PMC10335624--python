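"""Exception hierarchy used across the package."""


class PsrScreenError(Exception):
    """Base class for all package errors."""


class ParameterError(PsrScreenError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(PsrScreenError, ValueError):
    """A recording file is malformed or inconsistent with its header."""


class QualityError(PsrScreenError):
    """A signal segment is too degraded for the requested measurement."""


class IntegrityError(PsrScreenError):
    """A packaged reference table fails its integrity check."""
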