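"""Exception hierarchy. All errors derive from HomeomixError so callers can
catch package failures with one clause; the CLI maps subclasses to exit codes."""


class HomeomixError(Exception):
    """Base class for all package errors."""


class ValidationError(HomeomixError, ValueError):
    """Invalid field values (negative doses, non-unit coupling diagonal, ...)."""


class DimensionError(HomeomixError, ValueError):
    """Inconsistent array shapes between model components."""


class DomainError(HomeomixError, ValueError):
    """Query outside the mathematical domain of an operation."""


class StabilityError(HomeomixError, RuntimeError):
    """Linear relaxation dynamics are unstable; message names the spectral bound."""


class UsageError(HomeomixError, ValueError):
    """Operation invoked without a meaningful objective or with unusable options."""
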