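# Methods

## Model

Let (E_n) be i.i.d. Exp(λ) inter-arrival times of a Poisson clock N_t and
let (X_n), (Z_n) be i.i.d. nonnegative jumps, all independent. The latent
processes L_{t,1} = Σ_{n≤N_t} X_n and L_{t,2} = Σ_{n≤N_t} Z_n are
nondecreasing compound Poisson processes; the hitting times are
T = inf{t : L_{t,1} ≥ x} and C = inf{t : L_{t,2} ≥ z} for fixed thresholds
x, z > 0. Both margins jump at the same clock ticks, so T = C exactly when
both cumulative sums first cross at the same jump index; this happens with
positive probability and gives the joint law of (T, C) a singular component
on the diagonal. The requirement P[X_1 = 0], P[Z_1 = 0] < 1 keeps both
hitting times almost surely finite when the jump means are positive.

Writing c_{n,X} = P(S_n^X < x) (strict inequality; the crossing rule is
≥ x) and similarly c_{n,Z}, every model function is a Poisson mixture
Σ_n d_n λ e^{−λt}(λt)^n/n!:

| quantity            | coefficient d_n                                   |
|---------------------|---------------------------------------------------|
| tie density f_s     | (c_{n,X} − c_{n+1,X})(c_{n,Z} − c_{n+1,Z})        |
| Model I, δ = 1      | (c_{n,X} − c_{n+1,X}) c_{n,Z}                     |
| Model I/II, δ = 0   | (c_{n,Z} − c_{n+1,Z}) c_{n+1,X}                   |
| Model II, δ = 1     | (c_{n,X} − c_{n+1,X}) c_{n+1,Z}                   |
| Model II, δ = 2     | (c_{n,X} − c_{n+1,X})(c_{n,Z} − c_{n+1,Z})        |

P[T = C] is the coefficient sum of the tie branch (each mixture term
integrates to its coefficient) and is free of λ: only the jump-count
pattern matters. The marginal survivals are
S_T(t) = e^{−λt} Σ c_{n,X}(λt)^n/n! (resp. S_C, and S_Y with the product
c_{n,X} c_{n,Z}), and the hazard of Y is
λ(1 − Σ c_{n+1,X}c_{n+1,Z}(λt)^n/n! / Σ c_{n,X}c_{n,Z}(λt)^n/n!), which
lies in [0, λ] and tends to λ(1 − a) where a is the limit of the product
coefficient ratio.

## Identifiability

The limit a is governed by the class of the jump laws:

* **F1** — jumps bounded away from zero. The c-sequence hits an exact zero
  at n = ⌈threshold/min-jump⌉ and the model density is a *finite* sum.
* **F2** — absolutely continuous with mass near zero (exponential, gamma,
  …). The ratio c_{n+1}/c_n → 0 (empirically like αx/n for Exp(α)).
* **F3** — discrete with an atom at 0 and a smallest positive atom
  (Bernoulli, binomial, Poisson). The ratio → P[jump = 0] with O(1/n)
  discrepancy.

If either law is F1 (assumption H1) or F2 (H2.i), the hazard limit
identifies λ and Model I suffices. If both laws are F3 (H2.ii), the hazard
limit only pins down λ(1 − P[X₁=0]P[Z₁=0]) and the tie-aware Model II is
required; `ModelConfig` refuses Model I in that regime and `check_assumption`
reports the regime plus the finite-sum order N_max under H1. The
`ratio_limit_diagnostic` *reports* the fitted tail trend a + b/n of the
ratio sequence rather than asserting class membership — the constant in the
O(1/n) bound is existential, so only the trend is estimated.

Two counterexamples are shipped as executable functions:
`mixture_identity_gap` exhibits two distinct (intensity, coefficient)
pairs — (1, (1/2)^n) and (2/3, (1/4)^n) — whose mixtures coincide with
e^{−t/2} to machine precision, showing that the intensity is not identified
without structure on the coefficients; `matched_binomial_p` solves
1 − p⁹ = P(Binomial(12, p′) ≤ 8) for the unique p′ matching the first
coefficient of two binomial jump laws of different sizes, a genuinely
non-identifiable pair.

## Coefficient sequences

Closed forms: degenerate(c) → indicator(n·c < threshold); Bernoulli /
binomial / Poisson → the lattice-sum CDF evaluated at the largest integer
strictly below the threshold (this honours the strict inequality exactly on
the lattice); exponential/gamma → regularized lower incomplete gamma with
shape n·k; finite lattices → exact convolution carrying only support points
strictly below the threshold (mass at or above is absorbing). Sequences are
clipped to [0, 1], cached by (family, threshold, order), and for
exponential jumps satisfy the exact product invariance
c_n(α, x) = c_n(kα, x/k) — only αx enters, which is why refitting after
rescaling thresholds returns rescaled rate estimates and an unchanged
intensity.

## Series truncation

Likelihood evaluations truncate the mixtures at a fixed order N (policy
default N = 30; the reference cases use the orders of the original study:
exact N = 17 for the finite-sum case, 25 and 28 for the exponential and
discrete cases). All series are accumulated in log space by log-sum-exp —
(λt)^n/n! overflows in linear space once λt ≳ 30 — and zero coefficients
are skipped rather than logged. The truncation error of the log density on
[0, τ] × {0,1,2} is bounded by

    min_j  j!/(λ_m τ)^j · b_{j,N} · Σ_{n>N} (λ_m τ)^n/n!

with b_{j,N} the larger of the two sup-ratios of omitted to retained branch
coefficients; `remainder_bound` evaluates the sup on a finite window
extended until both numerator sequences verifiably decrease, and returns
both the exact-tail variant and the looser e^{λ_m τ} variant with the
minimizing pivot j*. Two caveats are deliberate: the bound is exactly zero
whenever the series terminates (F1 margins), and for λ_m τ well above N the
exact-tail factor is of order e^{λ_m τ}, so the bound, while valid, is
uninformative — reported magnitudes much below 1 for such regimes could not
be confirmed by this implementation, which reports both variants instead of
forcing agreement. `choose_truncation` scans a grid for the smallest N
meeting a tolerance and otherwise falls back to
N = ⌈λ_m τ + 10 √(λ_m τ)⌉.

Functions whose accuracy must not depend on the policy order — marginal
survivals, the CDF of Y, the hazard — extend the order adaptively to cover
the Poisson(λt) bulk to ~1e−12 tail mass; the c-sequences are closed-form,
so extension is cheap. The likelihood keeps the frozen policy order so the
objective is smooth in θ during optimization.

## Simulation

Each subject carries one inter-arrival stream feeding both margins (the
common clock; independent clocks are deliberately not offered). Jumps are
drawn in blocks sized from the expected crossing counts and extended until
both thresholds are crossed; a per-subject cap of 10⁶ jumps guards against
jump laws with zero mass near 1. Ties are decided by equality of the
crossing jump indices, making the diagonal atom a structural event: on a
tie the two hitting times are bitwise identical. Samples are reproducible
from (seed, n, θ, config) via `numpy.random.default_rng`.

## Estimation and asymptotics

The mean log-likelihood is maximized over a compact box (defaults: rates
and intensity in [0.01, 50], probabilities in [10⁻⁴, 1 − 10⁻⁴];
configurable) by L-BFGS-B on transformed coordinates — log for positive
parameters, logit for probabilities — with 5 random starts by default plus
any user-supplied start, followed by a Nelder-Mead polish at tight
tolerance so that exactly invariant reparametrizations map onto each other
to ≲1e−8. A_n (mean per-observation Hessian of the log density) and B_n
(mean outer product of scores) are computed by central finite differences
with per-coordinate steps 10⁻⁴·max(|θ_j|, 0.1) — near the classical
optimum h ~ ε^{1/4} for second derivatives; analytic derivatives for every
family were judged not worth the code. The sandwich covariance
C_n = A_n⁻¹ B_n A_n⁻¹ and the model-based −A_n⁻¹ are both returned
(symmetrized); standard errors are √(diag(C_n)/n). A_n conditioned worse
than 10¹² raises rather than silently pseudo-inverting.

## Replicated experiments

The three reference configurations (`reference_case`) span the three
identifiability regimes with λ = 1.42: (a) Bernoulli(0.36) vs a degenerate
unit jump, (x, z) = (7, 17); (b) Exp(0.71) vs Exp(2.04), (x, z) = (14, 7);
(c) Bernoulli(0.36) vs Poisson(1.23), (x, z) = (7, 19) under Model II.
Coverage experiments fit M replicates (replicate k seeded base_seed + k;
experiment fits start at the true parameter, which is available by
construction), form s_k = n(θ̂ᵏ − θ⁰)′A(θ̂ᵏ − θ⁰) with A = B_n(θ̂ᵏ) or
A = D⁻¹ where D is the empirical covariance of the √n-scaled estimates
centered at their mean, and report acceptance fractions at χ² quantiles
with 1 + d₁ + d₂ degrees of freedom. Non-positive-definite matrices and
failed fits are excluded and counted. The nx/bias curves are the pointwise
MSE and mean absolute error of the replicate-estimated marginal CDFs
against the true CDF.

Problem sizes used by the shipped tests: coverage tables at
n = 50…800 with M = 100; Monte-Carlo law checks at 10⁵ paths; recovery at
n = 5000; normality at n = 800, M = 100 via the Henze-Zirkler test.

## What the generator does and does not emulate

The simulator *is* the model: data are drawn from the exact latent process,
so passing tests demonstrate internal correctness (simulation ↔ analytic
laws ↔ estimation) under correct specification. They do not probe
misspecification — real longitudinal data (e.g. biomarker series recorded
at irregular visits) may violate the exponential inter-arrival assumption,
the i.i.d. jump assumption, or threshold homogeneity across subjects — and
the fixed-threshold, no-covariate setting is a deliberate scope boundary.
Time-inhomogeneous intensities, covariate-dependent jumps, random
thresholds and non-monotone processes are out of scope.

## Known limitations

* Coverage based on B_n at the estimate is near-nominal in this
  implementation even at n = 50 for the three-parameter exponential case;
  published finite-sample studies of this statistic can show substantially
  lower small-n rates, which are sensitive to optimizer convergence (the
  empirical-covariance statistic absorbs estimator spread, the B_n
  statistic does not).
* The F2 convolution-monotonicity condition is not verified numerically
  for user-supplied laws; only the named families plus finite lattices are
  built in, which avoids an unvalidated numeric-convolution path.
* The minimal identification order N_min is known family-by-family
  (1 for exponential and Poisson jumps; min{n ≥ x} for Bernoulli jumps)
  but no general algorithm exists, so it is documentation, not code.
* The hazard approaches its limit λ slowly under F2 margins (the ratio
  decays like 1/n), so "limit" statements are about t in the thousands for
  the reference scales, not the observed-data range.
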