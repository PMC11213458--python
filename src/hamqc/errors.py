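"""Exception hierarchy for hamqc.

``InputError`` and its subclasses map to CLI exit code 2 (bad input),
``NumericalError`` and its subclasses to exit code 3 (numerical failure).
"""


class HamqcError(Exception):
    """Base class for all hamqc errors."""


class InputError(HamqcError):
    """Invalid user-supplied data or configuration."""


class ParameterDomainError(InputError):
    """Cole parameters outside their physical domain (R0 > Rinf >= 0, tau > 0, 0 < alpha <= 1)."""


class DegenerateSpectrumError(InputError):
    """Spectrum carries no usable dispersion, e.g. flat |Z| (pure resistor)."""


class DegenerateDataError(InputError):
    """Statistical input with zero variance or otherwise unusable structure."""


class ConsistencyError(InputError):
    """Mutually inconsistent inputs, e.g. joint-scored observers that disagree."""


class ConfigError(InputError):
    """Invalid simulation or pipeline configuration."""


class NumericalError(HamqcError):
    """Numerical failure in fitting or calibration."""


class NonConvergenceError(NumericalError):
    """Optimizer failed after retries; carries the best result found so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class CalibrationError(NumericalError):
    """Latent-scale calibration failed; carries the best achieved statistics."""

    def __init__(self, message, achieved=None):
        super().__init__(message)
        self.achieved = dict(achieved) if achieved else {}
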