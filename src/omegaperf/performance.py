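"""The lifetime performance index C_L and the conforming rate P_r.

C_L = (mu - L)/sigma is a larger-the-better capability index: it measures, in
process standard deviations, how far the mean lifetime sits above the lower
specification limit L set by the consumer.  For fixed parameters C_L and the
conforming rate P_r = P(X >= L) determine one another monotonically through
L = mu - C_L * sigma and P_r = S(L).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import distribution as dist
from .distribution import MomentSummary, OmegaParams
from .errors import DomainError

__all__ = [
    "PerformanceSpec",
    "cl_index",
    "spec_limit_for_cl",
    "conforming_rate",
    "tabulate_cl_pr",
]


@dataclass(frozen=True)
class PerformanceSpec:
    """Lower specification limit L, target index value c* and test level."""

    L: float
    c_star: float
    level: float = 0.05

    def __post_init__(self):
        if self.L <= 0.0:
            raise DomainError("lower specification limit L must be positive")
        if not 0.0 < self.level < 1.0:
            raise DomainError("significance level must lie in (0, 1)")


def cl_index(
    params: OmegaParams, L: float, summary: Optional[MomentSummary] = None
) -> float:
    """C_L = (mu - L)/sigma for the given parameters and lower limit L."""
    if L >= params.gamma_:
        raise DomainError(
            "L must lie below the support endpoint gamma; no unit can conform"
        )
    s = summary if summary is not None else dist.moments(params)
    return (s.mu - L) / s.sigma


def spec_limit_for_cl(
    params: OmegaParams, c_l: float, summary: Optional[MomentSummary] = None
) -> float:
    """Invert C_L = (mu - L)/sigma for L; requires c_l < mu/sigma so L > 0."""
    s = summary if summary is not None else dist.moments(params)
    L = s.mu - c_l * s.sigma
    if L <= 0.0:
        raise DomainError(
            f"c_l = {c_l} is at or above the attainable bound mu/sigma = "
            f"{s.mu / s.sigma:.6g}; the implied L would not be positive"
        )
    return float(L)


def conforming_rate(
    params: OmegaParams, c_l, summary: Optional[MomentSummary] = None
) -> float:
    """P_r = P(X >= L) = S(mu - c_l * sigma), strictly increasing in c_l."""
    s = summary if summary is not None else dist.moments(params)
    c_arr = np.asarray(c_l, dtype=float)
    L = s.mu - c_arr * s.sigma
    if np.any(L <= 0.0):
        raise DomainError("c_l at or above mu/sigma: implied L is not positive")
    out = dist.survival(L, params)
    return out if np.ndim(c_l) else float(out)


def tabulate_cl_pr(params: OmegaParams, c_l_grid: Sequence[float]) -> pd.DataFrame:
    """Conforming rate over a grid of C_L values, in the grid's order."""
    s = dist.moments(params)
    grid = list(c_l_grid)
    pr = [conforming_rate(params, c, summary=s) for c in grid]
    return pd.DataFrame({"c_l": grid, "p_r": pr})
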