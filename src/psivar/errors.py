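"""Exception hierarchy shared across the package."""


class PsivarError(Exception):
    """Base class for package errors."""


class ConfigurationError(PsivarError, ValueError):
    """Invalid generator or run configuration."""


class InputError(PsivarError, ValueError):
    """Malformed or incomplete input table."""


class CohortError(PsivarError, ValueError):
    """Cohort construction failed."""


class EmptyCohortError(CohortError):
    """A filter or subset removed every hospital/record."""


class FitError(PsivarError, RuntimeError):
    """Model estimation failed."""


class ConvergenceError(FitError):
    """Optimiser did not converge."""


class SeparationError(FitError):
    """Perfect separation detected for a covariate."""
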