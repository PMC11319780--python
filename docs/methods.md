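# Methods

## Model

Lifetimes X follow the Omega distribution on the bounded support (0, γ):

    F(x) = 1 − ((γ^β + x^β)/(γ^β − x^β))^(−a),     a = α γ^β / 2,
    f(x) = α β x^{β−1} γ^{2β}/(γ^{2β} − x^{2β}) · (1 − F(x)),
    h(x) = α β x^{β−1} / (1 − (x/γ)^{2β}),

with shape parameters α, β > 0 and right endpoint γ > 0.  Everything is
evaluated through log S(x) = −2a·atanh((x/γ)^β), which is exact in log space
and respects the two regimes that matter in practice: a of order 1 (the
bounded support is visible in the data; bathtub hazard for β < 1) and a of
order 1e4–1e14 (the Weibull limit, log S ≈ −α x^β, where γ is close to
unidentifiable).  The quantile function is closed-form:
x = γ·tanh(−log(1−u)/(2a))^{1/β}.

The lifetime performance index is C_L = (μ − L)/σ with L the lower
specification limit; the conforming rate is P_r = P(X ≥ L) = S(μ − C_L σ),
strictly increasing in C_L.

## Moments: two evaluation paths

The raw moments have the closed form (derived via Euler's integral
representation of ₂F₁; the hypergeometric argument is −1)

    E[X^p] = α γ^{β+p} B(p/β+1, a) ₂F₁(a+1, p/β+1; p/β+a+1; −1).

Naive evaluation fails for large a on two counts: the ₂F₁ series at a huge
upper parameter, and the beta function underflowing.  We apply the Pfaff
transformation, which maps the function to
2^{−(p/β+1)} ₂F₁(p/β, p/β+1; p/β+a+1; ½) — the huge parameter now sits in the
denominator and the series converges in a handful of terms in ordinary double
precision — and assemble the prefactor with log-gamma functions.  For
a > 1e6 the log-gamma *difference* log Γ(a+d) − log Γ(a) itself loses absolute
precision (both terms ~a·log a), so it is replaced by the Stirling expansion
d·log a + d(d−1)/(2a), which analytically reproduces the Weibull-limit
moments E[X^p] → Γ(p/β+1) α^{−p/β} as a → ∞, entirely in log space (a may
overflow; log a never does).

`moments()` additionally integrates x·f and x²·f by adaptive quadrature
(with quantiles of the law passed as breakpoints, since for large a the mass
occupies a sliver of the support) and enforces agreement with the closed form
at 1e-6 relative; disagreement beyond 1e-4 raises.  The test suite also
checks both paths against a 40-digit arbitrary-precision evaluation.

## Censoring and simulation

A scheme (n, m, R) is valid iff ΣR_i = n − m with nonnegative removals.
Sampling uses the uniform-spacings transform: with independent U(0,1) draws
Z_i and exponents i + Σ_{j=m−i+1}^m R_j,

    V_i = Z_i^{1/exponent_i},  U_i = 1 − V_m V_{m−1} ··· V_{m−i+1},

which yields the exact joint law of the progressive uniform order statistics
in O(m); a literal simulate-n-lifetimes-and-withdraw sampler serves as the
Monte-Carlo oracle in the tests.  Observed failures map through the Omega
quantile.

## Likelihood, score, information

The log-likelihood of an observed scheme is

    l = m ln α + m ln β + (β−1)Σ ln x_i − Σ ln(1 − r_i²)
        − a Σ (R_i+1)·2 atanh(r_i),          r_i = (x_i/γ)^β,

each failure contributing its own survival power plus that of its R_i
withdrawn units.  The score is implemented analytically (certified against
central finite differences at 1e-5 relative); the observed information is the
negative Jacobian of that analytic score by central differences, which the
tests cross-check against a direct second-difference Hessian of the
log-likelihood.

**Boundary spike.** For every sample the likelihood is unbounded as
γ ↓ x_max whenever a·(R_m+1) < 1 — the familiar pathology of
bounded-support likelihoods (as with the three-parameter lognormal
threshold).  The estimator targets the interior stationary point: the
optimizer works in (ln α, ln β, ln(γ − x_max)) with γ − x_max floored at
1e-6·x_max, candidates that collapse onto that floor are discarded, and if
every start collapses a constrained fit with γ ≥ 1.5·x_max (the
Weibull-ridge regime) is returned with an explanatory message.

**Starting values** come from the Weibull limit: a Weibull fit to the
equivalent right-censored data (removals = censorings at their failure
times, via lifelines) gives β₀ and α₀ = scale^{−β₀}; γ starts at several
multiples of x_max, plus seeded random restarts.

**Ridge handling.**  When a is large the data identify only the Weibull
combination α x^β, leaving the profile likelihood flat in γ.  `fit_mle`
re-maximizes over (α, β) at γ ten times farther from x_max; if the profile
drops by less than 1 log-unit over that decade, `boundary_warning` is set.
On such ridges the finite-difference information matrix is numerically
indefinite, so the covariance is the inverse of the information restricted
to its positive-eigenvalue subspace (PSD by construction).  C_L is a
function of the identified directions and is stable along the ridge, so the
delta-method variance ψ = ∇C' V ∇C (gradient by central differences with
relative step 1e-5) remains meaningful; this choice was validated by the
empirical-size study below.  `converged` requires a small scaled gradient
and a finite covariance; full positive definiteness is deliberately not
required, else no ridge fit could ever be tested.

## Bayesian estimation

Independent gamma priors θ_i ~ Gamma(b_i, c_i) (shape/rate), default
b_i = 1, c_i = 1e-3 — proper but nearly flat; the source analyses state no
hyper-parameters, so their posterior tables are not reproducible and are not
targets.  The sampler is component-wise random-walk Metropolis within Gibbs:
normal proposals centred at the current value, accepted with the conditional
kernel ratio; proposals outside {α, β > 0, γ > x_max} count as rejections.
The α-conditional is an exact Gamma(m + b₁, c₁ + (γ^β/2)Σ(R_i+1)A_i) density,
so an exact Gibbs draw for α is available (`exact_alpha_gibbs`); the default
keeps Metropolis for all three components, matching the stated procedure.

Chains start at the MLE with proposal scales set to the delta-method standard
errors; during burn-in the scales adapt toward a 20–45% acceptance rate
(log-scale Robbins–Monro on 50-iteration blocks) and are frozen afterwards so
the retained chain is a genuine Markov chain.  Point estimates: posterior
means (SEL) and LINEX −(1/ε)·log E[e^{−εg}], computed with log-sum-exp;
credible intervals are equal-tail order-statistic intervals (level 0
degenerates to the full chain range by convention).  The default LINEX ε set
is (−2, 2, 0.001).

## Certification test

H₀: C_L ≤ c* vs Hₐ: C_L > c*, using Ĉ_L ~ N(C_L, ψ): reject when
Ĉ_L > C₀ = c* + z_α√ψ, equivalently when c* < LB = Ĉ_L − z_α√ψ; the two
rules are algebraically identical and both are exposed.  z is always
computed from the normal quantile (1.645 at α = 0.05 emerges, never
hard-coded).  Fits flagged with a γ ridge still test, with ψ marked
ridge-unstable in the report.

## Synthetic-data generator and study conditions

The simulation harness draws progressive type-II samples by quantile
inversion (default scheme: complete samples, consistent with generating via
F(x) − u = 0) and refits each replicate.  Study conditions used by the test
suite, chosen once up front:

* true parameters (2, 1.5, 10) — survival exponent a ≈ 31.6, a moderately
  Weibull-like regime typical of fitted lifetime data — for parameter
  recovery, the bias/MSE study (200 replicates, n ∈ {30, 200}; the published
  design's 1000 replicates over six sizes is run at reduced scale to keep the
  suite fast, and the asserted property is the qualitative one: MSE of α̂ and
  β̂ shrinks with n), and the empirical size of the test (500 replicates,
  n = 200, true C_L = c* = 1, level 0.05);
* true parameters (0.5, 0.8, 5) — a ≈ 0.9, bounded support clearly visible,
  γ identified — for the LINEX → SEL limit check, where a ridge-wide γ chain
  would make the Taylor gap (ε/2)·var/mean exceed the 1e-4 target for
  reasons unrelated to the estimator's correctness.

What the generator does not emulate: covariates, ties from coarse recording
(real fixtures have them; the generator produces continuous times), model
misspecification, and informative removal mechanisms.  Passing tests
therefore certify the estimators under the assumed model, not robustness to
departures from it.

## Data fixtures

* `hplc_censored` — 24 of 56 HPLC blood-sample concentrations (scaled by
  980) under removal scheme (7,4,4,0,0,3,0×7,1,5,2,0,0,3,3,0×4).
* `hplc_full` — the 56 raw values.  The available source table concatenates
  all digits, so this listing is a reconstruction by constrained segmentation
  (every value an integer ≤ 980, none below the first observed failure,
  containing the censored observations); it reproduces the published KS
  statistic of the Omega fit to 5e-7 and is labelled synthetic in its
  docstring.
* `ballbearing_full` / `ballbearing_censored` — the 23 classical
  ball-bearing failure times and the m = 11, scheme (0,0,0,3,2,3,1,0,0,0,3)
  censored version (times scaled by 1.2792).  The censored fixture is fully
  consistent with the complete listing: each observed time is a scaled order
  statistic and the removals account for all 23 units.

## Tolerances for published values

The published conforming-rate table is internally consistent only to about
1.5e-4 (no (μ, σ) pair reproduces all central cells at 5 decimals), so
table comparisons use 5e-4 absolute; tail cells (C_L ≤ −4) contain at least
one order-of-magnitude misprint and are excluded.  The worked-example
critical values and bounds were printed with z rounded to 1.645 and one
arithmetic slip of ~1.7e-3, so those comparisons use 2e-3 absolute.  Both
tolerances were fixed from this analysis before the implementation was
tested.

## Known limitations

* γ is near-unidentifiable whenever a is large; point estimates of γ are
  then arbitrary along the ridge (reported, flagged) although α, β in the
  Weibull combination and C_L remain well determined.
* The global MLE does not exist in the strict sense (boundary spike); the
  reported estimator is the interior stationary point, as is standard for
  such families.
* KS p-values ignore parameter estimation (no Lilliefors-type correction),
  matching conventional screening practice; they are optimistic when the
  parameters were fitted to the same data.
* The delta-method test is asymptotic; its empirical size at n = 200 in the
  study conditions is ~0.055 and it should not be trusted for very small m.
* The EM alternative for parameter estimation is out of scope.
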