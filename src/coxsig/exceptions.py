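"""Exception and warning types shared across the package."""


class CoxsigError(ValueError):
    """Base class for domain errors raised by coxsig."""


class ZeroVarianceError(CoxsigError):
    """A covariate is constant (or collinear) and cannot enter a Cox fit."""


class NoComparablePairsError(CoxsigError):
    """Concordance is undefined: no usable (shorter-time-has-event) pairs."""


class ConvergenceWarning(UserWarning):
    """A Newton-Raphson Cox fit stopped before meeting its tolerance."""
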