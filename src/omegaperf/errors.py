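"""Exception hierarchy for omegaperf."""


class OmegaPerfError(Exception):
    """Base class for all omegaperf errors."""


class InvalidParameterError(OmegaPerfError, ValueError):
    """A distribution parameter is non-positive or non-finite."""


class DomainError(OmegaPerfError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class SchemeError(OmegaPerfError, ValueError):
    """A progressive censoring scheme violates its accounting invariants."""


class SampleError(OmegaPerfError, ValueError):
    """A censored sample is malformed (length, ordering or positivity)."""


class NumericEvaluationError(OmegaPerfError, ArithmeticError):
    """Two independent evaluation paths disagree beyond tolerance."""


class ConvergenceError(OmegaPerfError, RuntimeError):
    """An iterative procedure failed to converge.

    Carries the best point found so far in ``best`` when available.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class PriorError(OmegaPerfError, ValueError):
    """Invalid prior hyper-parameters."""


class TuningError(OmegaPerfError, RuntimeError):
    """An MCMC chain is untunable (e.g. zero acceptance in a component)."""
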