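"""One-sided hypothesis test H0: C_L <= c* against Ha: C_L > c*.

The MLE of C_L is asymptotically normal with variance psi (delta method), so
the level-alpha test rejects when C_L_hat exceeds the critical value

    C0 = c* + z_alpha sqrt(psi),

equivalently when c* falls below the one-sided lower confidence bound

    LB = C_L_hat - z_alpha sqrt(psi).

Rejection certifies that the product's lifetime performance reaches the
target level c*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConvergenceError, DomainError
from .mle import MLEResult
from .performance import PerformanceSpec

__all__ = ["TestResult", "critical_value", "lower_bound", "conduct_test"]


def _z_upper(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise DomainError("significance level must lie in (0, 1)")
    return float(stats.norm.isf(level))


def critical_value(c_star: float, psi: float, level: float) -> float:
    """C0 = c* + z_level * sqrt(psi) with z the upper-tail normal quantile."""
    if psi < 0.0:
        raise DomainError("psi must be nonnegative")
    return float(c_star + _z_upper(level) * np.sqrt(psi))


def lower_bound(cl_hat: float, psi: float, level: float) -> float:
    """One-sided 100(1-level)% lower confidence bound for C_L."""
    if psi < 0.0:
        raise DomainError("psi must be nonnegative")
    return float(cl_hat - _z_upper(level) * np.sqrt(psi))


@dataclass(frozen=True)
class TestResult:
    """Outcome of the six-step testing procedure for C_L."""

    cl_hat: float
    psi: float
    z_alpha: float
    c0: float
    lb: float
    reject_h0: bool
    level: float
    c_star: float
    ridge_unstable: bool = False

    def summary(self) -> str:
        dec = ("reject H0: the desired level for the performance of the "
               "product is reached"
               if self.reject_h0 else
               "fail to reject H0: the data do not certify the target level")
        lines = [
            f"Test of H0: C_L <= {self.c_star:.5f} vs Ha: C_L > {self.c_star:.5f} "
            f"at level {self.level:g}",
            f"  C_L_hat  = {self.cl_hat:.5f}",
            f"  psi      = {self.psi:.5f}"
            + ("  [ridge-unstable: gamma_hat weakly identified]"
               if self.ridge_unstable else ""),
            f"  z_alpha  = {self.z_alpha:.5f}",
            f"  C0       = {self.c0:.5f}   (critical value)",
            f"  LB       = {self.lb:.5f}   (one-sided lower bound; "
            f"CI = [{self.lb:.5f}, inf))",
            f"  decision: {dec}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "cl_hat": self.cl_hat, "psi": self.psi, "z_alpha": self.z_alpha,
            "c0": self.c0, "lb": self.lb, "reject_h0": self.reject_h0,
            "level": self.level, "c_star": self.c_star,
            "ridge_unstable": self.ridge_unstable,
        }


def conduct_test(fit: MLEResult, spec: PerformanceSpec) -> TestResult:
    """Assemble the test from a converged MLE fit and a performance spec.

    The decision is c* not in [LB, inf), which is algebraically identical to
    C_L_hat > C0.  A fit flagged with a gamma ridge still tests, but the
    result marks psi as ridge-unstable.
    """
    if not fit.converged:
        raise ConvergenceError(
            "refusing to test on a non-converged fit; diagnostics: "
            f"{fit.messages or 'gradient/curvature check failed'}", best=fit,
        )
    if fit.cl_hat is None or fit.psi is None:
        raise DomainError("fit carries no C_L estimate; refit with L set")
    z = _z_upper(spec.level)
    c0 = critical_value(spec.c_star, fit.psi, spec.level)
    lb = lower_bound(fit.cl_hat, fit.psi, spec.level)
    return TestResult(
        cl_hat=float(fit.cl_hat), psi=float(fit.psi), z_alpha=z, c0=c0, lb=lb,
        reject_h0=bool(spec.c_star < lb), level=spec.level, c_star=spec.c_star,
        ridge_unstable=bool(fit.boundary_warning),
    )
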