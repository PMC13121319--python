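# cphit — dependent and censored first hitting times with compound Poisson processes

`cphit` implements a parametric survival model for a pair of event times
that are *dependently* censored and can coincide exactly. Two nondecreasing
compound Poisson processes share one Poisson clock of intensity λ:

    L_{t,1} = Σ_{n ≤ N_t} X_n ,    L_{t,2} = Σ_{n ≤ N_t} Z_n ,

with i.i.d. nonnegative jumps X_n ~ P_α and Z_n ~ P_β. The event time
T and the censoring time C are the first times L_1 and L_2 reach fixed
thresholds x and z. Because both margins jump at the same clock ticks,
P[T = C] > 0: the joint law of (T, C) carries an atom on the diagonal, a
structure that copula-based censoring models with absolutely continuous
dependence cannot represent. The observed data are

* **Model I**: (Y, Δ) = (min{T, C}, 1{T ≤ C}), or
* **Model II**: (Y, Δ) = (min{T, C}, Δ ∈ {0, 1, 2}) distinguishing T > C,
  T < C and the tie T = C.

Everything observable depends on the jump laws only through the coefficient
sequences c_{n,X} = P(X_1 + … + X_n < x) and c_{n,Z} = P(Z_1 + … + Z_n < z):
every outcome density is a Poisson mixture
Σ_n d_n · λ e^{−λt} (λt)^n / n! with coefficients d_n built from forward
differences and products of the two c-sequences, e.g.
P[T = C] = Σ_n (c_{n,X} − c_{n+1,X})(c_{n,Z} − c_{n+1,Z}) and
h_Y(t) = λ (1 − Σ c_{n+1,X} c_{n+1,Z} (λt)^n/n! / Σ c_{n,X} c_{n,Z} (λt)^n/n!).

The package provides, as importable API plus a thin `cphit` command line:

* closed-form c-sequences for degenerate, Bernoulli, binomial, Poisson,
  exponential, gamma and finite-lattice jump laws, with the F1/F2/F3
  classification and ratio-limit diagnostics that determine whether Model I
  identifies the intensity or the tie-aware Model II is required;
* exact simulation of the latent bivariate process, with ties decided by
  jump-count equality (never floating-point time comparison);
* outcome densities, hazard, marginal and minimum survival functions in
  log space, with a uniform bound on the series-truncation error;
* maximum-likelihood estimation over a compact box with sandwich
  covariance C_n = A_n⁻¹ B_n A_n⁻¹ and standard errors;
* replicated experiments: χ² coverage tables and CDF bias/MSE curves.

## Worked example

```python
from cphit import fit_mle, reference_case, simulate_sample

theta, config = reference_case("b")      # λ=1.42, X~Exp(0.71), Z~Exp(2.04), x=14, z=7
sample = simulate_sample(theta, config, n=2000, seed=7)
fit = fit_mle(sample, config, starts=3, seed=0)
```

Running `python examples/fit_censored_sample.py` (which does the above)
prints:

```
simulated n = 2000 outcomes; censoring fraction 0.144
lam          estimate  1.4397  se 0.0482  truth 1.42
alpha.rate   estimate  0.7184  se 0.0257  truth 0.71
beta.rate    estimate  2.1112  se 0.0690  truth 2.04
mean log-likelihood at optimum: -2.88961
||A_n + B_n|| / ||B_n|| = 0.017  (small: model well specified)
```

Each estimate lands within about two sandwich standard errors of the truth,
and the near-cancellation of A_n + B_n is the empirical signature of a
well-specified likelihood. The other scripts in `examples/` demonstrate the
diagonal atom (`simulate_ties.py`), the density/hazard surface
(`densities_and_hazard.py`), the identifiability diagnostics and the two
counterexamples (`identifiability_diagnostics.py`), and a small replicated
coverage study (`coverage_study.py`).

A YAML-driven CLI mirrors the API:
`cphit simulate|fit|coverage|curves|diagnose --config cfg.yaml ...`; every
run writes a manifest (config, seed, version) so artifacts can be
regenerated byte-identically.

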