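"""Exception hierarchy shared across the package."""


class ElmBloomError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ElmBloomError, ValueError):
    """A file does not conform to the expected CSV dialect."""


class ConfigurationError(ElmBloomError, ValueError):
    """An invalid combination of options (e.g. ELM2 without an upstream series)."""


class InsufficientDataError(ElmBloomError, ValueError):
    """Too few usable rows for the requested operation."""


class DegenerateInputError(ElmBloomError, ValueError):
    """Input with no exploitable structure (e.g. all points identical for clustering)."""


class OverfittingGuardError(ElmBloomError, ValueError):
    """Model capacity would meet or exceed the number of training rows."""


class NumericError(ElmBloomError, ArithmeticError):
    """Non-finite values encountered where finite arithmetic is required."""
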