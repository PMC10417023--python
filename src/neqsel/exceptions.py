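"""Exception hierarchy.

All package errors derive from :class:`NeqselError` so callers can catch one
base class; the subclasses distinguish bad parameters, malformed files,
violated call contracts and numerical failures.
"""


class NeqselError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NeqselError, ValueError):
    """A numeric parameter violates its domain (e.g. non-positive sigma)."""


class InsufficientDataError(NeqselError, ValueError):
    """Too few samples/points for the requested operation."""


class FormatError(NeqselError, ValueError):
    """A file or table does not conform to the expected dialect."""


class ContractError(NeqselError, ValueError):
    """Mismatched inputs (method, target, temperature) across operands."""


class ConfigurationError(NeqselError, ValueError):
    """Inconsistent study configuration (missing reference compound etc.)."""


class ConvergenceError(NeqselError, RuntimeError):
    """A root solve or iterative fit failed to converge; carries diagnostics."""


class DegenerateFitError(NeqselError, ValueError):
    """A fit is undefined for the given data (zero variance, constant x)."""


class BootstrapFailureError(NeqselError, RuntimeError):
    """The estimator failed in too many bootstrap replicates."""


class KmUnavailableError(NeqselError, ValueError):
    """Absolute Ki requested but no Km value supplied for the target."""
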