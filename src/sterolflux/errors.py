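"""Exception hierarchy for sterolflux.

All package-specific failures derive from :class:`SterolFluxError` so callers
can catch one base class at pipeline boundaries.
"""


class SterolFluxError(Exception):
    """Base class for all sterolflux errors."""


class InvalidInputError(SterolFluxError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateSpectrumError(SterolFluxError, ValueError):
    """A spectrum has no usable signal (e.g. zero total intensity)."""


class UnidentifiableModelError(SterolFluxError, ValueError):
    """The label model cannot separate new from pre-existing molecules
    (M0_t == M0_n)."""


class PeakUninformativeError(SterolFluxError, ValueError):
    """A single-peak deconvolution was requested for a peak whose natural and
    fully-labeled abundances are too close to be informative."""


class ConfigurationError(SterolFluxError, ValueError):
    """Inconsistent or incomplete run configuration / registry."""


class QuantitationError(SterolFluxError, ValueError):
    """Internal-standard based quantitation is impossible (zero IS signal,
    zero normalizer)."""


class ConvergenceError(SterolFluxError, RuntimeError):
    """An iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class FitError(SterolFluxError, RuntimeError):
    """Nonlinear kinetic fit failed."""
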