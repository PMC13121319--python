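"""Maximum-likelihood estimation and sandwich asymptotics.

The mean log-likelihood of a censored sample is an average of
Poisson-mixture log densities; it is maximized over a compact box by a
bounded quasi-Newton search on transformed coordinates (log for the
intensity and rate-like parameters, logit for probabilities), with multiple
random starts and an optional simplex polish.  The asymptotic machinery
estimates

    A_n = mean Hessian of the log density,
    B_n = mean outer product of the scores,
    C_n = A_n^{-1} B_n A_n^{-1}    (robust / sandwich covariance),

with derivatives taken by central finite differences.  In a well-specified
model A = -B, so C_n and the model-based -A_n^{-1} agree asymptotically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .families import check_assumption
from .model import ModelConfig, Theta, outcome_log_density
from .simulate import CensoredSample

__all__ = ["FitResult", "loglik", "loglik_per_obs", "fit_mle",
           "info_matrices", "sandwich"]


# ---------------------------------------------------------------------------
# parameter-space transforms


def _to_working(vec: np.ndarray, transforms) -> np.ndarray:
    out = np.empty_like(vec)
    for i, tr in enumerate(transforms):
        if tr == "log":
            out[i] = math.log(vec[i])
        else:  # logit
            out[i] = math.log(vec[i] / (1.0 - vec[i]))
    return out


def _from_working(u: np.ndarray, transforms) -> np.ndarray:
    out = np.empty_like(u)
    for i, tr in enumerate(transforms):
        if tr == "log":
            out[i] = math.exp(u[i])
        else:
            out[i] = 1.0 / (1.0 + math.exp(-u[i]))
    return out


def _theta_from_vec(vec: np.ndarray, config: ModelConfig) -> Theta:
    return Theta.from_vector(vec, config.d_alpha, config.d_beta)


# ---------------------------------------------------------------------------
# likelihood


def loglik_per_obs(theta: Theta, sample: CensoredSample,
                   config: ModelConfig) -> np.ndarray:
    """Vector of log f_{(Y,Delta),theta}(y_i, delta_i), grouped by delta."""
    if sample.n == 0:
        raise ValueError("empty sample")
    if not np.isin(sample.delta, config.valid_deltas).all():
        raise ValueError(
            f"sample delta codes incompatible with Model {config.model_type}"
        )
    out = np.empty(sample.n)
    for d in np.unique(sample.delta):
        mask = sample.delta == d
        out[mask] = outcome_log_density(sample.y[mask], int(d), theta, config)
    return out


def loglik(theta: Theta, sample: CensoredSample, config: ModelConfig) -> float:
    """Mean log-likelihood (1/n) sum_i log f(y_i, delta_i); -inf if any
    observation has zero density under theta."""
    vals = loglik_per_obs(theta, sample, config)
    return float(np.mean(vals)) if np.isfinite(vals).all() else -np.inf


# ---------------------------------------------------------------------------
# fit


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit.

    ``se`` are sandwich standard errors sqrt(diag(C_n)/n); ``C_model`` is
    the model-based variant -A_n^{-1}.  ``starts`` records the best working
    point of each optimizer start.
    """

    theta_hat: Theta
    loglik: float
    converged: bool
    n_used: int
    n_obs: int
    A_n: Optional[np.ndarray] = None
    B_n: Optional[np.ndarray] = None
    C_n: Optional[np.ndarray] = None
    C_model: Optional[np.ndarray] = None
    se: Optional[np.ndarray] = None
    starts: list = field(default_factory=list)
    message: str = ""
    param_names: tuple = ()


def fit_mle(sample: CensoredSample, config: ModelConfig, starts: int = 5,
            seed=None, x0: Optional[Theta] = None, polish: bool = True,
            compute_covariance: bool = True) -> FitResult:
    """Maximize the mean log-likelihood over the compact parameter box.

    ``starts`` random initializations are drawn uniformly in the working
    (transformed) box; an explicit ``x0`` is used as an additional start.
    The best interior optimum is kept and, when ``polish`` is set, refined
    with a Nelder-Mead pass at tight tolerance so that exactly invariant
    reparametrizations map to each other to ~1e-8 in the working scale.
    """
    report = check_assumption(config.x_family, config.z_family,
                              config.x_threshold, config.z_threshold)
    if report.tag == "none":
        import warnings
        warnings.warn("configuration may not be identifiable: " + report.explanation)

    transforms = config.param_transforms()
    bounds = np.asarray(config.param_bounds(), dtype=float)
    lo_w = _to_working(bounds[:, 0], transforms)
    hi_w = _to_working(bounds[:, 1], transforms)
    rng = np.random.default_rng(seed)

    def neg_ll(u: np.ndarray) -> float:
        vec = _from_working(u, transforms)
        try:
            val = loglik(_theta_from_vec(vec, config), sample, config)
        except (ValueError, FloatingPointError):
            return 1e10
        return 1e10 if not np.isfinite(val) else -val

    start_points = []
    if x0 is not None:
        start_points.append(_to_working(x0.vector, transforms))
    for _ in range(starts):
        start_points.append(lo_w + rng.random(len(transforms)) * (hi_w - lo_w))
    if not start_points:
        raise ValueError("need at least one start")

    best = None
    records = []
    for u0 in start_points:
        res = optimize.minimize(
            neg_ll, u0, method="L-BFGS-B",
            bounds=list(zip(lo_w, hi_w)),
            options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
        )
        records.append({"x0": u0.copy(), "fun": float(res.fun),
                        "success": bool(res.success)})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or best.fun >= 1e9:
        raise RuntimeError("all optimizer starts failed to converge: "
                           + "; ".join(str(r) for r in records))

    u_hat = best.x
    if polish:
        res = optimize.minimize(
            neg_ll, u_hat, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 4000},
        )
        if np.isfinite(res.fun) and res.fun <= best.fun:
            u_hat = res.x
            best = res

    vec_hat = _from_working(u_hat, transforms)
    theta_hat = _theta_from_vec(vec_hat, config)
    fit = FitResult(
        theta_hat=theta_hat, loglik=-float(best.fun), converged=True,
        n_used=config.truncation.N, n_obs=sample.n, starts=records,
        message=str(getattr(best, "message", "")),
        param_names=config.param_names(),
    )
    if compute_covariance:
        try:
            A_n, B_n = info_matrices(theta_hat, sample, config)
            C_n, C_model = sandwich(A_n, B_n)
            fit.A_n, fit.B_n, fit.C_n, fit.C_model = A_n, B_n, C_n, C_model
            fit.se = np.sqrt(np.maximum(np.diag(C_n), 0.0) / sample.n)
        except (np.linalg.LinAlgError, ValueError) as exc:
            fit.message += f" [covariance unavailable: {exc}]"
    return fit


# ---------------------------------------------------------------------------
# asymptotic matrices


def _per_obs_ll_fn(sample: CensoredSample, config: ModelConfig):
    def fn(vec: np.ndarray) -> np.ndarray:
        return loglik_per_obs(_theta_from_vec(vec, config), sample, config)
    return fn


def info_matrices(theta: Theta, sample: CensoredSample, config: ModelConfig,
                  rel_step: float = 1e-4):
    """Empirical information matrices by central finite differences.

    A_n averages per-observation Hessians of the log density; B_n averages
    outer products of per-observation scores.  Steps are scaled per
    coordinate to the parameter magnitude.
    """
    fn = _per_obs_ll_fn(sample, config)
    vec0 = theta.vector
    p = vec0.size
    h = rel_step * np.maximum(np.abs(vec0), 0.1)

    base = fn(vec0)
    if not np.isfinite(base).all():
        bad = int(np.flatnonzero(~np.isfinite(base))[0])
        raise ValueError(f"log density not finite at observation {bad}")

    plus = np.empty((p, sample.n))
    minus = np.empty((p, sample.n))
    for j in range(p):
        e = np.zeros(p); e[j] = h[j]
        plus[j] = fn(vec0 + e)
        minus[j] = fn(vec0 - e)
    scores = (plus - minus) / (2.0 * h[:, None])  # (p, n)

    hess = np.empty((p, p, sample.n))
    for j in range(p):
        hess[j, j] = (plus[j] - 2.0 * base + minus[j]) / h[j] ** 2
    for j in range(p):
        for k in range(j + 1, p):
            ej = np.zeros(p); ej[j] = h[j]
            ek = np.zeros(p); ek[k] = h[k]
            mixed = (fn(vec0 + ej + ek) - fn(vec0 + ej - ek)
                     - fn(vec0 - ej + ek) + fn(vec0 - ej - ek)) / (4.0 * h[j] * h[k])
            hess[j, k] = hess[k, j] = mixed

    if not np.isfinite(scores).all() or not np.isfinite(hess).all():
        jj, *_ = np.nonzero(~np.isfinite(scores)) if not np.isfinite(scores).all() \
            else np.nonzero(~np.isfinite(hess))
        raise ValueError(f"non-finite derivative in coordinate {int(jj[0])}")

    A_n = hess.mean(axis=2)
    B_n = (scores[:, None, :] * scores[None, :, :]).mean(axis=2)
    A_n = 0.5 * (A_n + A_n.T)
    B_n = 0.5 * (B_n + B_n.T)
    return A_n, B_n


def sandwich(A_n: np.ndarray, B_n: np.ndarray, cond_cap: float = 1e12):
    """Robust covariance C_n = A_n^{-1} B_n A_n^{-1} and model-based -A_n^{-1}.

    Raises when A_n is numerically singular (the asymptotic-normality result
    requires a non-singular expected Hessian).
    """
    if np.linalg.cond(A_n) > cond_cap:
        raise np.linalg.LinAlgError(
            "A_n is numerically singular; the limiting covariance requires a "
            "non-singular expected Hessian"
        )
    A_inv = np.linalg.inv(A_n)
    C_n = A_inv @ B_n @ A_inv
    C_n = 0.5 * (C_n + C_n.T)
    C_model = -A_inv
    C_model = 0.5 * (C_model + C_model.T)
    return C_n, C_model
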