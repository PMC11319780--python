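"""Maximum likelihood for the Omega law under progressive type-II censoring.

The log-likelihood (dropping the combinatorial constant by default) is

    l = m ln a + m ln b + (b-1) sum ln x_i - sum ln(1 - r_i^2)
        - (a g^b / 2) sum (R_i + 1) A_i,

with r_i = (x_i/g)^b and A_i = ln((g^b + x_i^b)/(g^b - x_i^b)) = 2 atanh(r_i)
(a, b, g short for alpha, beta, gamma).  Each observed failure contributes its
own survival power as well as that of its R_i withdrawn units, hence the
(R_i + 1) factor.  The score below is the exact gradient of this expression;
the observed information is obtained by central differences of that analytic
score, and is cross-checked in the tests against a direct second-difference
Hessian of the log-likelihood.

gamma is weakly identified whenever a*g^b/2 is large: the data then constrain
only the Weibull-limit combination alpha*x^beta, leaving a flat ridge in
gamma.  ``fit_mle`` detects the ridge via the profile likelihood and flags it;
C_L itself is stable along the ridge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from . import distribution as dist
from . import performance
from .censoring import CensoredSample, likelihood_constant
from .distribution import OmegaParams
from .errors import ConvergenceError
from .errors import SampleError

__all__ = ["MLEResult", "loglik", "score", "observed_information", "fit_mle",
           "cl_variance"]


def _arrays(sample: CensoredSample):
    x = sample.times_array()
    w = np.asarray(sample.removals, dtype=float) + 1.0
    return x, w


def _loglik_raw(alpha, beta, gamma_, x, w, m):
    if not (alpha > 0.0 and beta > 0.0 and gamma_ > 0.0):
        return -np.inf
    if gamma_ <= x[-1]:
        return -np.inf
    with np.errstate(over="ignore"):
        r = np.power(x / gamma_, beta)
        r2 = r * r
        if np.any(r2 >= 1.0 - 1e-15):
            return -np.inf
        a_exp = alpha * gamma_**beta / 2.0
        if not np.isfinite(a_exp):
            return -np.inf
        A = 2.0 * np.arctanh(r)
        return (
            m * np.log(alpha)
            + m * np.log(beta)
            + (beta - 1.0) * np.sum(np.log(x))
            - np.sum(np.log1p(-r2))
            - a_exp * np.dot(w, A)
        )


def loglik(theta: OmegaParams, sample: CensoredSample,
           include_constant: bool = False) -> float:
    """Progressive type-II log-likelihood; -inf when gamma <= max observed time.

    ``include_constant`` adds ln C for the exact likelihood value; the constant
    does not depend on the parameters and is excluded by default.
    """
    x, w = _arrays(sample)
    val = _loglik_raw(theta.alpha, theta.beta, theta.gamma_, x, w, sample.m)
    if include_constant and np.isfinite(val):
        val += float(np.log(likelihood_constant(sample.scheme)))
    return float(val)


def score(theta: OmegaParams, sample: CensoredSample) -> np.ndarray:
    """Exact gradient (dl/dalpha, dl/dbeta, dl/dgamma) of :func:`loglik`."""
    x, w = _arrays(sample)
    m = sample.m
    al, be, ga = theta.alpha, theta.beta, theta.gamma_
    if not np.isfinite(_loglik_raw(al, be, ga, x, w, m)):
        raise SampleError("score undefined: log-likelihood is not finite here")
    r = np.power(x / ga, be)
    r2 = r * r
    A = 2.0 * np.arctanh(r)
    g = 2.0 / (1.0 - r2)
    lu = np.log(x) - np.log(ga)
    gb = ga**be
    S1 = np.dot(w, A)

    d_al = m / al - (gb / 2.0) * S1
    d_be = (
        m / be
        + np.sum(np.log(x))
        + np.sum(r2 * g * lu)
        - (al * gb / 2.0) * (np.log(ga) * S1 + np.dot(w, g * r * lu))
    )
    d_ga = (
        -(be / ga) * np.sum(r2 * g)
        - (al * be * gb / (2.0 * ga)) * np.dot(w, A - g * r)
    )
    return np.array([d_al, d_be, d_ga])


def observed_information(theta: OmegaParams, sample: CensoredSample) -> np.ndarray:
    """Negative Hessian of the log-likelihood at theta.

    Central finite differences of the analytic :func:`score`, symmetrized.
    Step sizes are relative; gamma steps are clipped so gamma stays above the
    largest observed time.
    """
    th = np.array([theta.alpha, theta.beta, theta.gamma_])
    xmax = max(sample.times)
    H = np.zeros((3, 3))
    for j in range(3):
        h = 1e-6 * max(abs(th[j]), 1e-3)
        h = min(h, 0.4 * th[j])
        if j == 2:
            h = min(h, 0.4 * (th[2] - xmax))
        tp, tm = th.copy(), th.copy()
        tp[j] += h
        tm[j] -= h
        sp = score(OmegaParams(*tp), sample)
        sm = score(OmegaParams(*tm), sample)
        H[:, j] = (sp - sm) / (2.0 * h)
    H = 0.5 * (H + H.T)
    return -H


@dataclass
class MLEResult:
    """Fitted parameters with curvature, C_L plug-in and delta-method variance."""

    theta_hat: OmegaParams
    loglik: float
    score_at_opt: np.ndarray
    obs_info: np.ndarray
    vcov: np.ndarray
    converged: bool
    boundary_warning: bool
    cl_hat: Optional[float] = None
    psi: Optional[float] = None
    L: Optional[float] = None
    n_obs: int = 0
    messages: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "theta_hat": self.theta_hat.to_dict(),
            "loglik": self.loglik,
            "cl_hat": self.cl_hat,
            "psi": self.psi,
            "L": self.L,
            "converged": self.converged,
            "boundary_warning": self.boundary_warning,
            "vcov": self.vcov.tolist(),
            "messages": list(self.messages),
        }


def _psd_inverse(info: np.ndarray, rel_tol: float = 1e-8):
    """Inverse of the information on its positive-eigenvalue subspace.

    On a Weibull-limit ridge the finite-difference information is numerically
    indefinite in the flat gamma direction; a plain inverse then produces an
    indefinite 'covariance' and negative delta-method variances.  Restricting
    the inverse to eigendirections with eigenvalue > rel_tol * max_eigenvalue
    yields a PSD covariance for the identified directions (quantities such as
    C_L are stable along the discarded flat direction).

    Returns (vcov, fully_positive_definite).
    """
    lam, U = np.linalg.eigh(info)
    lmax = float(np.max(lam))
    if lmax <= 0.0:
        return np.zeros_like(info), False
    keep = lam > rel_tol * lmax
    inv_lam = np.where(keep, 1.0 / np.where(keep, lam, 1.0), 0.0)
    vcov = (U * inv_lam) @ U.T
    return vcov, bool(np.all(keep))


def _weibull_start(sample: CensoredSample):
    """Starting values from the Weibull limit of the Omega law.

    In the large-gamma limit log S(x) = -alpha x^beta, i.e. a Weibull law with
    shape beta and scale alpha^(-1/beta).  Fit that Weibull to the equivalent
    right-censored data (each removal is a censoring at its failure time) and
    translate back.
    """
    durations, events = [], []
    for t, r in zip(sample.times, sample.removals):
        durations.append(t)
        events.append(1)
        durations.extend([t] * int(r))
        events.extend([0] * int(r))
    try:
        from lifelines import WeibullFitter

        wf = WeibullFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wf.fit(np.asarray(durations), np.asarray(events))
        beta0 = float(wf.rho_)
        alpha0 = float(wf.lambda_) ** (-beta0)
        if np.isfinite(alpha0) and np.isfinite(beta0) and alpha0 > 0 and beta0 > 0:
            return alpha0, beta0
    except Exception:  # pragma: no cover - lifelines is robust on these inputs
        pass
    return 1.0, 1.0


def fit_mle(
    sample: CensoredSample,
    L: Optional[float] = None,
    init: Optional[OmegaParams] = None,
    n_starts: int = 4,
    seed: int = 0,
    include_constant: bool = False,
    boundary_check: bool = True,
) -> MLEResult:
    """Maximize the progressive type-II log-likelihood over (alpha, beta, gamma).

    Optimizes in the unconstrained coordinates (ln alpha, ln beta,
    ln(gamma - x_max)) with the analytic gradient, from a Weibull-limit start
    plus randomized restarts.  When ``L`` is given, the C_L plug-in estimate
    (invariance of the MLE) and its delta-method variance psi are attached.
    """
    if sample.m < 3:
        raise SampleError("need at least 3 observed failures to fit 3 parameters")
    x, w = _arrays(sample)
    m = sample.m
    xmax = float(x[-1])
    lnC = float(np.log(likelihood_constant(sample.scheme))) if include_constant else 0.0

    def neg(z):
        al, be = np.exp(z[0]), np.exp(z[1])
        ga = xmax + np.exp(z[2])
        val = _loglik_raw(al, be, ga, x, w, m)
        if not np.isfinite(val):
            return np.inf, np.zeros(3)
        s = score(OmegaParams(al, be, ga), sample)
        grad = -np.array([al * s[0], be * s[1], (ga - xmax) * s[2]])
        return -val, grad

    rng = np.random.default_rng(seed)
    a0, b0 = _weibull_start(sample)
    starts = []
    if init is not None:
        starts.append(
            np.array([np.log(init.alpha), np.log(init.beta),
                      np.log(max(init.gamma_ - xmax, 1e-8 * xmax))])
        )
    starts.append(np.array([np.log(a0), np.log(b0), np.log(4.0 * xmax)]))
    starts.append(np.array([np.log(a0), np.log(b0), np.log(0.5 * xmax)]))
    while len(starts) < max(n_starts, 2):
        jitter = rng.normal(scale=0.7, size=3)
        starts.append(
            np.array([np.log(a0), np.log(b0), np.log(2.0 * xmax)]) + jitter
        )

    # The likelihood is unbounded along gamma -> x_max whenever
    # a_exp*(R_m+1) < 1 (a boundary spike, the usual pathology of
    # bounded-support likelihoods).  The estimator targets the interior
    # stationary point: gamma is kept a little above x_max and candidates
    # that ran into that bound with a sub-unit spike exponent are discarded.
    gap_floor = 1e-6 * xmax
    bounds = [(-30.0, 30.0), (-30.0, 30.0),
              (np.log(gap_floor), np.log(1e9 * xmax))]
    w_last = w[-1]

    def is_spike(res):
        return (np.exp(res.x[2])) < 10.0 * gap_floor

    def run_starts(z0s, bnds):
        best = None
        for z0 in z0s:
            try:
                res = optimize.minimize(
                    neg, np.clip(z0, [b[0] for b in bnds], [b[1] for b in bnds]),
                    jac=True, method="L-BFGS-B", bounds=bnds,
                    options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-10},
                )
            except Exception:
                continue
            if not np.isfinite(res.fun) or is_spike(res):
                continue
            if best is None or res.fun < best.fun:
                best = res
        return best

    messages = []
    best = run_starts(starts, bounds)
    if best is None:
        # every start slid into the spike: the interior stationary point is
        # absent for this sample.  Fall back to the Weibull-limit ridge by
        # keeping gamma well clear of x_max.
        ridge_bounds = [bounds[0], bounds[1],
                        (np.log(0.5 * xmax), bounds[2][1])]
        best = run_starts(starts, ridge_bounds)
        messages.append(
            "interior optimum collapsed onto the gamma -> x_max boundary "
            "spike; Weibull-ridge fit returned"
        )
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(
            "all optimizer starts failed", best=best,
        )

    z = best.x
    theta = OmegaParams(float(np.exp(z[0])), float(np.exp(z[1])),
                        float(xmax + np.exp(z[2])))
    ll = -best.fun + lnC
    s_opt = score(theta, sample)
    info = observed_information(theta, sample)
    vcov, pd_ok = _psd_inverse(info)
    if not pd_ok:
        messages.append(
            "observed information not positive definite (likelihood ridge); "
            "covariance restricted to the identified directions"
        )

    # convergence: scaled gradient small and curvature usable.  A fit on the
    # gamma ridge has an indefinite full information matrix yet is a genuine
    # stationary point with a PSD covariance on the identified subspace, so
    # full positive definiteness is deliberately not required here (the ridge
    # is reported through boundary_warning instead).
    scale = np.array([theta.alpha, theta.beta, theta.gamma_ - xmax])
    converged = bool(
        np.max(np.abs(s_opt * scale)) < 1e-4 * (1.0 + abs(ll))
        and np.all(np.isfinite(vcov))
    )

    boundary = False
    if boundary_check:
        boundary = _ridge_flat(theta, sample, ll - lnC, x, w, m)
        if boundary:
            messages.append(
                "profile log-likelihood in gamma is nearly flat over a decade "
                "(Weibull-limit ridge); gamma_hat is weakly identified"
            )

    result = MLEResult(
        theta_hat=theta, loglik=float(ll), score_at_opt=s_opt, obs_info=info,
        vcov=vcov, converged=converged, boundary_warning=boundary,
        L=L, n_obs=sample.n, messages=messages,
    )
    if L is not None:
        result.cl_hat = performance.cl_index(
            theta, L, summary=dist.moments(theta, check=False)
        )
        result.psi = cl_variance(result, L)
    return result


def _ridge_flat(theta, sample, ll_hat, x, w, m, decade=10.0, threshold=1.0):
    """True when the gamma-profile drops by < ``threshold`` over a decade.

    Re-maximizes over (alpha, beta) at gamma' = x_max + decade*(gamma_hat -
    x_max), starting from the point that keeps alpha*gamma^beta fixed (the
    Weibull-limit invariant).
    """
    xmax = float(x[-1])
    ga2 = xmax + decade * (theta.gamma_ - xmax)
    al0 = theta.alpha * (theta.gamma_ / ga2) ** theta.beta

    def neg2(z):
        al, be = np.exp(z[0]), np.exp(z[1])
        val = _loglik_raw(al, be, ga2, x, w, m)
        if not np.isfinite(val):
            return np.inf, np.zeros(2)
        s = score(OmegaParams(al, be, ga2), sample)
        return -val, -np.array([al * s[0], be * s[1]])

    try:
        res = optimize.minimize(
            neg2, np.array([np.log(al0), np.log(theta.beta)]), jac=True,
            method="L-BFGS-B", options={"maxiter": 200},
        )
        return bool(ll_hat - (-res.fun) < threshold)
    except Exception:  # pragma: no cover
        return False


def cl_variance(result: MLEResult, L: float) -> float:
    """Delta-method variance psi = grad C(theta)' V grad C(theta).

    The gradient of C(theta) = (mu(theta) - L)/sigma(theta) is taken by
    central differences with relative step 1e-5; a negative quadratic form
    (possible when V is only pseudo-inverted on a ridge) is clipped at zero
    with a warning.
    """
    th = np.array([result.theta_hat.alpha, result.theta_hat.beta,
                   result.theta_hat.gamma_])
    grad = np.zeros(3)
    for j in range(3):
        h = 1e-5 * abs(th[j])
        tp, tm = th.copy(), th.copy()
        tp[j] += h
        tm[j] -= h
        cp = performance.cl_index(OmegaParams(*tp), L,
                                  summary=dist.moments(OmegaParams(*tp), check=False))
        cm = performance.cl_index(OmegaParams(*tm), L,
                                  summary=dist.moments(OmegaParams(*tm), check=False))
        grad[j] = (cp - cm) / (2.0 * h)
    psi = float(grad @ result.vcov @ grad)
    if psi < 0.0:
        warnings.warn("negative delta-method variance clipped to 0 "
                      "(non-PSD covariance on a likelihood ridge)", RuntimeWarning)
        psi = 0.0
    return psi
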