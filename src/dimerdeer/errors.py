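"""Exception hierarchy shared across the package."""


class DimerDeerError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DimerDeerError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedQuantityError(DimerDeerError, ValueError):
    """The requested quantity is mathematically undefined for this input."""


class InfeasibleObservablesError(DimerDeerError, ValueError):
    """Observables are mutually inconsistent (no valid occupancy state)."""


class DegenerateFitError(DimerDeerError, RuntimeError):
    """A fit collapsed to an uninformative solution."""


class UndefinedScoreError(DimerDeerError, ValueError):
    """A hypothesis score cannot be computed on the requested window."""


class InvalidConfigError(DimerDeerError, ValueError):
    """A scenario or pipeline configuration is internally inconsistent."""


class BundleIOError(DimerDeerError, OSError):
    """A scenario bundle file is missing or malformed."""
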