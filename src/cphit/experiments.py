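"""Simulation experiments: coverage tables, bias/MSE curves, counterexamples.

Three reference configurations span the identifiability regimes:

  case a  lam=1.42, X ~ Bernoulli(0.36), Z = 1 a.s., (x, z) = (7, 17)
          -- a degenerate jump law (H1): the model density is a finite sum;
  case b  lam=1.42, X ~ Exp(0.71), Z ~ Exp(2.04), (x, z) = (14, 7)
          -- absolutely continuous jumps (H2.i), series order N = 25;
  case c  lam=1.42, X ~ Bernoulli(0.36), Z ~ Poisson(1.23), (x, z) = (7, 19)
          -- both laws discrete with atoms at zero (H2.ii): Model II
          required, series order N = 28.

The coverage experiment fits M replicates, forms the Wald-type statistic
n * (theta_hat - theta0)' A (theta_hat - theta0) with A either B_n at the
estimate or the inverse of the empirical covariance D_{M,n} of the sqrt(n)-
scaled estimates, and reports the fraction below chi-square quantiles with
1 + d1 + d2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .families import JumpFamily
from .inference import FitResult, fit_mle
from .model import ModelConfig, Theta, TruncationPolicy, marginal_cdf
from .simulate import simulate_sample

__all__ = [
    "ExperimentConfig", "CoverageReport", "reference_case",
    "replicate_fits", "coverage_from_fits", "coverage_experiment",
    "bias_mse_curves", "mixture_identity_gap", "matched_binomial_p",
]


def reference_case(label: str) -> tuple:
    """(theta_true, ModelConfig) for reference case 'a', 'b' or 'c'."""
    if label == "a":
        theta = Theta(1.42, alpha=(0.36,), beta=())
        config = ModelConfig(
            x_family=JumpFamily.bernoulli(0.36),
            z_family=JumpFamily.degenerate(1.0),
            x_threshold=7.0, z_threshold=17.0, model_type="I",
            truncation=TruncationPolicy(N=17, lam_max=2.0, tau=20.0),
        )
    elif label == "b":
        theta = Theta(1.42, alpha=(0.71,), beta=(2.04,))
        config = ModelConfig(
            x_family=JumpFamily.exponential(0.71),
            z_family=JumpFamily.exponential(2.04),
            x_threshold=14.0, z_threshold=7.0, model_type="I",
            truncation=TruncationPolicy(N=25, lam_max=2.0, tau=20.0),
        )
    elif label == "c":
        theta = Theta(1.42, alpha=(0.36,), beta=(1.23,))
        config = ModelConfig(
            x_family=JumpFamily.bernoulli(0.36),
            z_family=JumpFamily.poisson(1.23),
            x_threshold=7.0, z_threshold=19.0, model_type="II",
            truncation=TruncationPolicy(N=28, lam_max=2.0, tau=20.0),
        )
    else:
        raise ValueError("label must be 'a', 'b' or 'c'")
    return theta, config


@dataclass(frozen=True)
class ExperimentConfig:
    """One replicated-fit experiment over a list of sample sizes."""

    label: str
    theta_true: Theta
    config: ModelConfig
    n_list: tuple = (50, 100, 200)
    M: int = 100
    base_seed: int = 0
    chi2_levels: tuple = (0.90, 0.95, 0.99)
    grid: tuple = tuple(np.linspace(0.0, 20.0, 81))

    def __post_init__(self):
        if self.M < 2:
            raise ValueError("M must be >= 2")

    @property
    def dof(self) -> int:
        return self.config.dim

    @classmethod
    def for_case(cls, label: str, **kw) -> "ExperimentConfig":
        theta, config = reference_case(label)
        return cls(label, theta, config, **kw)


@dataclass
class CoverageReport:
    """Acceptance rates of the chi-square coverage experiment."""

    rates: pd.DataFrame  # index (n, level), columns per matrix choice
    thetas: dict  # n -> (M, p) array of estimates
    D: dict  # n -> empirical covariance of sqrt(n) * theta_hat
    failures: dict  # n -> count of excluded replicates
    exp: ExperimentConfig = None


def replicate_fits(exp: ExperimentConfig, n: int, starts: int = 0,
                   compute_B: bool = True):
    """Fit M independent replicates of size n; returns (fits, failures).

    Replicate k uses seed base_seed + k for both data and optimizer.  Fits
    start at the true parameter (we are at the truth by construction of the
    experiment) plus ``starts`` extra random starts.  Failed fits are
    excluded and counted.
    """
    fits: list = []
    failures = 0
    for k in range(exp.M):
        seed = exp.base_seed + k
        sample = simulate_sample(exp.theta_true, exp.config, n, seed=seed)
        try:
            fit = fit_mle(sample, exp.config, starts=starts, seed=seed,
                          x0=exp.theta_true, polish=False,
                          compute_covariance=compute_B)
        except (RuntimeError, ValueError):
            failures += 1
            continue
        fits.append(fit)
    return fits, failures


def _wald_statistics(fits, theta0: Theta, n: int, matrix_choice: str,
                     D: Optional[np.ndarray] = None):
    """Statistics n * v' A v with A = B_n(theta_hat) or D^{-1}; non-PD
    matrices flag the replicate for exclusion (returned as NaN)."""
    stats_out = np.full(len(fits), np.nan)
    for k, fit in enumerate(fits):
        v = fit.theta_hat.vector - theta0.vector
        if matrix_choice == "B_n":
            A = fit.B_n
            if A is None:
                continue
        elif matrix_choice == "D_inv":
            A = np.linalg.inv(D)
        else:
            raise ValueError("matrix_choice must be 'B_n' or 'D_inv'")
        try:
            np.linalg.cholesky(A)  # PD check: sqrt(nA) must exist
        except np.linalg.LinAlgError:
            continue
        stats_out[k] = n * float(v @ A @ v)
    return stats_out


def coverage_from_fits(fits, exp: ExperimentConfig, n: int,
                       matrix_choice: str) -> pd.Series:
    """Acceptance rates at the experiment's chi-square levels."""
    thetas = np.array([f.theta_hat.vector for f in fits])
    D = np.cov(np.sqrt(n) * thetas, rowvar=False, ddof=1)
    s = _wald_statistics(fits, exp.theta_true, n, matrix_choice, D)
    s = s[np.isfinite(s)]
    out = {}
    for level in exp.chi2_levels:
        q = stats.chi2.ppf(level, exp.dof)
        out[level] = float(np.mean(s <= q)) if s.size else np.nan
    return pd.Series(out, name=matrix_choice)


def coverage_experiment(exp: ExperimentConfig,
                        matrix_choices=("D_inv", "B_n")) -> CoverageReport:
    """Full coverage table over exp.n_list and both matrix choices."""
    rows = []
    thetas, Ds, failures = {}, {}, {}
    for n in exp.n_list:
        fits, fail = replicate_fits(exp, n)
        failures[n] = fail + sum(f.B_n is None for f in fits)
        arr = np.array([f.theta_hat.vector for f in fits])
        thetas[n] = arr
        Ds[n] = np.cov(np.sqrt(n) * arr, rowvar=False, ddof=1)
        for mc in matrix_choices:
            ser = coverage_from_fits(fits, exp, n, mc)
            for level, rate in ser.items():
                rows.append({"n": n, "level": level, "matrix": mc, "rate": rate})
    rates = (pd.DataFrame(rows)
             .pivot_table(index=["n", "level"], columns="matrix", values="rate"))
    return CoverageReport(rates, thetas, Ds, failures, exp)


def bias_mse_curves(exp: ExperimentConfig, margin: str, n: int,
                    fits=None) -> pd.DataFrame:
    """Pointwise MSE (nx) and mean absolute error (bias) of the estimated
    marginal CDF of T or C over the time grid, across M replicate fits."""
    if margin not in ("T", "C"):
        raise ValueError("margin must be 'T' or 'C'")
    if fits is None:
        fits, _ = replicate_fits(exp, n, compute_B=False)
    grid = np.asarray(exp.grid)
    truth = marginal_cdf(margin, grid, exp.theta_true, exp.config)
    devs = np.array([
        marginal_cdf(margin, grid, f.theta_hat, exp.config) - truth
        for f in fits
    ])
    return pd.DataFrame({
        "t": grid,
        "nx": np.mean(devs ** 2, axis=0),
        "bias": np.mean(np.abs(devs), axis=0),
    })


# ---------------------------------------------------------------------------
# identifiability counterexamples


def mixture_identity_gap(grid, lam: float = 1.0, lam_p: float = 2.0 / 3.0,
                         b: float = 0.5, b_p: float = 0.25) -> float:
    """Max absolute gap between two Poisson-mixture series with geometric
    coefficients b^n and b'^n at intensities lam and lam'.

    With (lam, b) = (1, 1/2) and (lam', b') = (2/3, 1/4) both sides reduce
    analytically to e^{-t/2}: distinct parameters, identical observed-data
    density.  The series e^{-lam t} sum b^n (lam t)^n / n! = e^{-lam(1-b)t}
    is summed numerically to machine-negligible tail.
    """
    grid = np.asarray(grid, dtype=float)
    if (grid <= 0).any() or not np.isfinite(grid).all():
        raise ValueError("grid must be positive and finite")

    def mixture(lam_, b_):
        mu = lam_ * grid
        N = int(stats.poisson.ppf(1.0 - 1e-16, mu.max())) + 60
        n = np.arange(N + 1)
        terms = (n[None, :] * np.log(b_) - mu[:, None]
                 + n[None, :] * np.log(mu[:, None]) - special.gammaln(n + 1)[None, :])
        return np.exp(special.logsumexp(terms, axis=1))

    return float(np.max(np.abs(mixture(lam, b) - mixture(lam_p, b_p))))


def matched_binomial_p(p: float) -> float:
    """Solve for p' in (0,1) matching the first cumulative-jump coefficient
    of two binomial jump laws of different sizes (3 vs 4) at threshold 9:

        1 - p^9 = 1 - sum_{k=9}^{12} C(12,k) p'^k (1-p')^{12-k}.

    Two structurally different jump laws then induce identical censored-data
    densities: a genuine non-identifiable pair.  The solution is unique and
    increasing in p.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0,1)")
    target = p ** 9

    def f(pp):
        return stats.binom.sf(8, 12, pp) - target

    return float(optimize.brentq(f, 1e-12, 1.0 - 1e-12, xtol=1e-14))
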