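"""Exception hierarchy.

All package errors derive from :class:`FrocDwiError` so callers can catch
one base class; the parameter/fit/data subclasses additionally derive from
the matching builtin so they behave like ordinary ``ValueError`` etc.
"""


class FrocDwiError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(FrocDwiError, ValueError):
    """A model parameter violates its physical constraints, or a model
    evaluation produced a non-finite value."""


class FitError(FrocDwiError):
    """Base class for voxel-fitting failures."""


class FitDomainError(FitError, ValueError):
    """The signal is outside the fit's domain (e.g. non-positive values
    where a log-transform is required)."""


class InsufficientDataError(FitError, ValueError):
    """Too few usable b-values for the requested fit."""


class ConfigurationError(FrocDwiError, ValueError):
    """An invalid phantom/run configuration (e.g. infeasible quartiles)."""


class DataValidationError(FrocDwiError, ValueError):
    """Inconsistent on-disk inputs (grid mismatch, orphan ROI label, ...)."""


class AnalysisError(FrocDwiError, ValueError):
    """A cohort-statistics operation received degenerate input
    (empty group, one-class labels, unpaired scores, ...)."""
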