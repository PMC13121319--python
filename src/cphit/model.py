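"""Model functions of the dependent-censored hitting-time model.

Two nondecreasing compound Poisson processes share one Poisson clock of
intensity lambda; T and C are the first times the cumulative X- and Z-jumps
reach the thresholds x and z.  Every model function is a Poisson mixture

    sum_n  d_n * lambda * exp(-lambda t) * (lambda t)^n / n!

whose coefficients d_n are built from the two c-sequences
c_{n,X} = P(S_n^X < x) and c_{n,Z} = P(S_n^Z < z).  Series are truncated at
a policy order N and evaluated in log space (log-sum-exp), since
(lambda t)^n / n! overflows in linear space once lambda*t exceeds a few
tens.  A uniform bound on the truncation error of the log-density is
available through :func:`remainder_bound`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import special, stats

from .families import JumpFamily, check_assumption, coeff_sequence

__all__ = [
    "Theta",
    "TruncationPolicy",
    "ModelConfig",
    "RemainderBound",
    "prob_equal",
    "branch_mass",
    "singular_density",
    "joint_density_ac",
    "outcome_log_density",
    "hazard",
    "marginal_survival",
    "y_survival",
    "y_cdf",
    "remainder_bound",
]


@dataclass(frozen=True)
class Theta:
    """Full parameter vector theta = (lambda, alpha, beta).

    ``lam`` is the Poisson clock intensity (events per unit time); ``alpha``
    and ``beta`` are the free-parameter tuples of the X- and Z-jump
    families (possibly empty, e.g. for a known degenerate jump).
    """

    lam: float
    alpha: tuple = ()
    beta: tuple = ()

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("intensity lambda must be positive")
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.lam, *self.alpha, *self.beta])

    @property
    def dim(self) -> int:
        return 1 + len(self.alpha) + len(self.beta)

    @classmethod
    def from_vector(cls, vec, d_alpha: int, d_beta: int) -> "Theta":
        vec = np.asarray(vec, dtype=float)
        if vec.size != 1 + d_alpha + d_beta:
            raise ValueError("parameter vector has wrong length")
        return cls(float(vec[0]), tuple(vec[1 : 1 + d_alpha]), tuple(vec[1 + d_alpha :]))


@dataclass(frozen=True)
class TruncationPolicy:
    """Series order and the constants entering the truncation bound.

    ``N`` is the order of the partial sums used by the likelihood;
    ``lam_max`` must dominate every intensity considered and ``tau`` is the
    time horizon on which the bound is stated.
    """

    N: int = 30
    lam_max: float = 2.0
    tau: float = 20.0

    def __post_init__(self):
        if self.N < 1 or self.lam_max <= 0 or self.tau <= 0:
            raise ValueError("need N >= 1, lam_max > 0, tau > 0")


@dataclass(frozen=True)
class ModelConfig:
    """Structural configuration: jump families, thresholds, censoring model.

    ``x_family``/``z_family`` carry the family *shape* (and any fixed
    parameters); free parameters are supplied at evaluation time through a
    :class:`Theta`.  ``model_type`` is "I" (delta = 1{T<=C}) or "II"
    (delta in {0,1,2} distinguishing T>C, T<C and the tie T=C).
    """

    x_family: JumpFamily
    z_family: JumpFamily
    x_threshold: float
    z_threshold: float
    model_type: str = "I"
    truncation: TruncationPolicy = field(default_factory=TruncationPolicy)
    bounds: Optional[tuple] = None  # per-coordinate (lo, hi), lam first

    def __post_init__(self):
        if self.x_threshold <= 0 or self.z_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.model_type not in ("I", "II"):
            raise ValueError("model_type must be 'I' or 'II'")
        report = check_assumption(self.x_family, self.z_family,
                                  self.x_threshold, self.z_threshold)
        if report.tag == "H2.ii" and self.model_type == "I":
            raise ValueError(
                "both jump laws are discrete with atoms at zero (H2.ii): "
                "the intensity is not identifiable from Model I; use Model II"
            )

    @property
    def d_alpha(self) -> int:
        return len(self.x_family.free_param_names)

    @property
    def d_beta(self) -> int:
        return len(self.z_family.free_param_names)

    @property
    def dim(self) -> int:
        return 1 + self.d_alpha + self.d_beta

    @property
    def valid_deltas(self) -> tuple:
        return (0, 1) if self.model_type == "I" else (0, 1, 2)

    def families_at(self, theta: Theta):
        """Concrete jump families with theta's free parameters plugged in."""
        return (self.x_family.with_params(theta.alpha),
                self.z_family.with_params(theta.beta))

    def theta(self, lam: float) -> Theta:
        """Theta at intensity ``lam`` with the families' current parameters."""
        return Theta(lam, self.x_family.free_params, self.z_family.free_params)

    def coeffs_at(self, theta: Theta, N: int):
        """c-sequences of both margins up to index N (inclusive)."""
        fx, fz = self.families_at(theta)
        cx = coeff_sequence(fx, self.x_threshold, N).values
        cz = coeff_sequence(fz, self.z_threshold, N).values
        return cx, cz

    def param_bounds(self) -> tuple:
        """Compact box for (lam, alpha, beta); defaults are wide."""
        if self.bounds is not None:
            return self.bounds
        lam_bounds = ((0.01, 50.0),)
        return lam_bounds + self.x_family.default_bounds() + self.z_family.default_bounds()

    def param_transforms(self) -> tuple:
        return ("log",) + self.x_family.free_param_transforms + self.z_family.free_param_transforms

    def param_names(self) -> tuple:
        return (("lam",)
                + tuple(f"alpha.{n}" for n in self.x_family.free_param_names)
                + tuple(f"beta.{n}" for n in self.z_family.free_param_names))


# --------------------------------------------------------------------------
# series plumbing


def _branch_coeffs(cx: np.ndarray, cz: np.ndarray, model_type: str, delta: int) -> np.ndarray:
    """Mixture coefficients d_n for the outcome density branch (t, delta).

    ``cx``/``cz`` must have length N+2 so that the forward differences
    c_n - c_{n+1} are available up to order N.
    """
    dx = cx[:-1] - cx[1:]
    dz = cz[:-1] - cz[1:]
    if model_type == "I":
        if delta == 1:  # T <= C
            return dx * cz[:-1]
        if delta == 0:  # T > C
            return dz * cx[1:]
    else:
        if delta == 0:  # T > C
            return dz * cx[1:]
        if delta == 1:  # T < C
            return dx * cz[1:]
        if delta == 2:  # tie
            return dx * dz
    raise ValueError(f"delta={delta} invalid for Model {model_type}")


def _log_mixture(coefs: np.ndarray, lam: float, t: np.ndarray) -> np.ndarray:
    """log of sum_n coefs[n] * lam * e^{-lam t} (lam t)^n / n!, elementwise in t.

    Zero coefficients are skipped; the value is -inf where every term
    vanishes.  Stable for large lam*t via log-sum-exp.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.full(t.shape, -np.inf)
    pos = coefs > 0
    if not pos.any():
        return out
    n = np.flatnonzero(pos)
    logc = np.log(coefs[n])
    tpos = t > 0
    if tpos.any():
        lt = np.log(lam * t[tpos])[:, None]
        terms = logc[None, :] + n[None, :] * lt - special.gammaln(n + 1)[None, :]
        out[tpos] = math.log(lam) - lam * t[tpos] + special.logsumexp(terms, axis=1)
    if (~tpos).any() and coefs[0] > 0:
        out[~tpos] = math.log(lam) + math.log(coefs[0])
    return out


def _adaptive_N(lam: float, t_max: float, N_floor: int) -> int:
    """Order covering the Poisson(lam*t) bulk to ~1e-12 tail mass."""
    if t_max <= 0:
        return N_floor
    mu = lam * t_max
    return max(N_floor, int(stats.poisson.ppf(1.0 - 1e-12, mu)) + 2)


# --------------------------------------------------------------------------
# model functions


def prob_equal(theta: Theta, config: ModelConfig, N: Optional[int] = None) -> float:
    """P[T = C] = sum_n (c_{n,X} - c_{n+1,X})(c_{n,Z} - c_{n+1,Z}).

    Free of lambda: ties depend only on how many jumps each margin needs.
    Exact when either c-sequence hits zero at or before N; otherwise the
    omitted tail is at most min(c_{N+1,X}, c_{N+1,Z}).
    """
    if N is None:
        N = config.truncation.N
    cx, cz = config.coeffs_at(theta, N + 1)
    val = float(np.sum((cx[:-1] - cx[1:]) * (cz[:-1] - cz[1:])))
    return min(max(val, 0.0), 1.0)


def prob_equal_tail_bound(theta: Theta, config: ModelConfig, N: Optional[int] = None) -> float:
    """Upper bound on the tie-probability mass omitted past order N."""
    if N is None:
        N = config.truncation.N
    cx, cz = config.coeffs_at(theta, N + 1)
    return float(min(cx[-1], cz[-1]))


def branch_mass(delta: int, theta: Theta, config: ModelConfig,
                N: Optional[int] = None) -> float:
    """P[Delta = delta]: the integrated mass of one outcome branch.

    Each mixture term integrates to its coefficient, so the branch mass is
    simply the coefficient sum.
    """
    if N is None:
        N = config.truncation.N
    cx, cz = config.coeffs_at(theta, N + 1)
    coefs = _branch_coeffs(cx, cz, config.model_type, delta)
    return float(np.sum(coefs))


def singular_density(u, theta: Theta, config: ModelConfig,
                     N: Optional[int] = None) -> np.ndarray:
    """Density of the diagonal atom: f_s(u) = d/du P[T <= u, T = C].

    Integrates over [0, inf) to P[T = C] at the same truncation order.
    """
    if N is None:
        N = config.truncation.N
    cx, cz = config.coeffs_at(theta, N + 1)
    coefs = (cx[:-1] - cx[1:]) * (cz[:-1] - cz[1:])
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    if (u_arr < 0).any():
        raise ValueError("u must be nonnegative")
    out = np.exp(_log_mixture(coefs, theta.lam, u_arr))
    return out if np.ndim(u) else float(out[0])


def joint_density_ac(u: float, v: float, theta: Theta, config: ModelConfig,
                     N: Optional[int] = None) -> float:
    """Absolutely continuous part of the (T, C) joint density at (u, v), u != v.

    The double series runs over the total jump count n and the index j of
    the jump at which the first-crossing margin finishes; it is accumulated
    in log space.  The diagonal u == v is refused: the singular part lives
    there.
    """
    if u == v:
        raise ValueError("joint ac density is undefined on the diagonal u == v")
    if u < 0 or v < 0:
        raise ValueError("u and v must be nonnegative")
    if N is None:
        N = config.truncation.N
    cx, cz = config.coeffs_at(theta, N + 1)
    dx = cx[:-1] - cx[1:]
    dz = cz[:-1] - cz[1:]
    lam = theta.lam
    first, later = (u, v) if u < v else (v, u)
    # the margin that crosses first finishes at jump j; the other at jump n+1
    d_first, d_later = (dx, dz) if u < v else (dz, dx)
    n_idx, j_idx = np.meshgrid(np.arange(1, N + 1), np.arange(1, N + 1), indexing="ij")
    mask = j_idx <= n_idx
    n_i, j_i = n_idx[mask], j_idx[mask]
    coef = d_first[j_i - 1] * d_later[n_i]
    pos = coef > 0
    if not pos.any():
        return 0.0
    n_f = n_i[pos].astype(float)
    j_f = j_i[pos].astype(float)
    coef = coef[pos]
    log_terms = (
        np.log(coef)
        + 2.0 * math.log(lam)
        - lam * later
        + _pow_log(n_f - j_f, lam * (later - first))
        - special.gammaln(n_f - j_f + 1.0)
        + _pow_log(j_f - 1.0, lam * first)
        - special.gammaln(j_f)
    )
    finite = log_terms > -np.inf
    if not finite.any():
        return 0.0
    return float(np.exp(special.logsumexp(log_terms[finite])))


def _pow_log(power: np.ndarray, x: float) -> np.ndarray:
    """power * log(x) with the convention 0 * log(0) = 0 (x**0 == 1)."""
    if x > 0:
        return power * math.log(x)
    return np.where(power == 0, 0.0, -np.inf)


def outcome_log_density(t, delta: int, theta: Theta, config: ModelConfig,
                        N: Optional[int] = None) -> np.ndarray:
    """log f_{(Y,Delta)}(t, delta), the censored-outcome log density.

    Model I branches (delta in {0,1}) and Model II branches (delta in
    {0,1,2}) per the closed-form Poisson mixtures; -inf where the branch has
    zero mass at t.
    """
    if delta not in config.valid_deltas:
        raise ValueError(f"delta={delta} invalid for Model {config.model_type}")
    if N is None:
        N = config.truncation.N
    cx, cz = config.coeffs_at(theta, N + 1)
    coefs = _branch_coeffs(cx, cz, config.model_type, delta)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if (t_arr < 0).any():
        raise ValueError("t must be nonnegative")
    out = _log_mixture(coefs, theta.lam, t_arr)
    return out if np.ndim(t) else float(out[0])


def _log_survival_series(coefs: np.ndarray, lam: float, t: np.ndarray) -> np.ndarray:
    """log of e^{-lam t} sum_n coefs[n] (lam t)^n / n! (no leading lam)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.full(t.shape, -np.inf)
    pos = coefs > 0
    if not pos.any():
        return out
    n = np.flatnonzero(pos)
    logc = np.log(coefs[n])
    tpos = t > 0
    if tpos.any():
        lt = np.log(lam * t[tpos])[:, None]
        terms = logc[None, :] + n[None, :] * lt - special.gammaln(n + 1)[None, :]
        out[tpos] = -lam * t[tpos] + special.logsumexp(terms, axis=1)
    if (~tpos).any() and coefs[0] > 0:
        out[~tpos] = math.log(coefs[0])
    return out


def marginal_survival(which: str, t, theta: Theta, config: ModelConfig) -> np.ndarray:
    """Survival function of a latent margin: S_T(t) = e^{-lam t} sum c_{n,X}(lam t)^n/n!.

    The order is extended adaptively past the policy N to cover the
    Poisson(lam*t) bulk, so the value is accurate at any t (the c-sequences
    are closed-form and cheap to extend).
    """
    if which not in ("T", "C"):
        raise ValueError("which must be 'T' or 'C'")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if (t_arr < 0).any():
        raise ValueError("t must be nonnegative")
    N = _adaptive_N(theta.lam, float(t_arr.max(initial=0.0)), config.truncation.N)
    cx, cz = config.coeffs_at(theta, N)
    coefs = cx if which == "T" else cz
    out = np.exp(_log_survival_series(coefs, theta.lam, t_arr))
    return out if np.ndim(t) else float(out[0])


def marginal_cdf(which: str, t, theta: Theta, config: ModelConfig):
    return 1.0 - marginal_survival(which, t, theta, config)


def y_survival(t, theta: Theta, config: ModelConfig) -> np.ndarray:
    """Survival of the observed time Y = min(T, C):
    S_Y(t) = e^{-lam t} sum c_{n,X} c_{n,Z} (lam t)^n / n!  (adaptive order)."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if (t_arr < 0).any():
        raise ValueError("t must be nonnegative")
    N = _adaptive_N(theta.lam, float(t_arr.max(initial=0.0)), config.truncation.N)
    cx, cz = config.coeffs_at(theta, N)
    out = np.exp(_log_survival_series(cx * cz, theta.lam, t_arr))
    return out if np.ndim(t) else float(out[0])


def y_cdf(t, theta: Theta, config: ModelConfig):
    return 1.0 - y_survival(t, theta, config)


def hazard(t, theta: Theta, config: ModelConfig) -> np.ndarray:
    """Hazard of Y:  h(t) = lam * (1 - sum c_{n+1,X}c_{n+1,Z}(lam t)^n/n! /
                                       sum c_{n,X}c_{n,Z}(lam t)^n/n!).

    Lies in [0, lam]; as t grows it approaches lam*(1 - a) where a is the
    limit of the product coefficient ratio.  Both series are evaluated in
    log space at an adaptively extended order.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if (t_arr <= 0).any():
        raise ValueError("hazard requires t > 0")
    N = _adaptive_N(theta.lam, float(t_arr.max()), config.truncation.N)
    cx, cz = config.coeffs_at(theta, N + 1)
    num = cx[1:] * cz[1:]
    den = cx[:-1] * cz[:-1]
    log_num = _log_survival_series(num, theta.lam, t_arr)
    log_den = _log_survival_series(den, theta.lam, t_arr)
    if np.isinf(log_den).any():
        raise FloatingPointError("survival of Y underflowed to exact zero")
    ratio = np.exp(log_num - log_den)
    out = theta.lam * (1.0 - np.clip(ratio, 0.0, 1.0))
    return out if np.ndim(t) else float(out[0])


# --------------------------------------------------------------------------
# truncation error bound


@dataclass(frozen=True)
class RemainderBound:
    """Uniform bound on the log-density truncation error r_N on [0, tau].

    ``bound`` uses the exact Poisson tail sum; ``bound_loose`` replaces the
    tail by e^{lam_max * tau}.  ``per_j`` lists the bound candidate for each
    pivot index j; ``j_star`` minimizes it.
    """

    per_j: np.ndarray
    j_star: int
    bound: float
    bound_loose: float
    N: int
    lam_max: float
    tau: float


def remainder_bound(theta: Theta, config: ModelConfig,
                    policy: Optional[TruncationPolicy] = None,
                    window: int = 200) -> RemainderBound:
    """Bound the truncation error of the order-N log-density on [0, tau].

    For each pivot j <= N the bound candidate is

        j! / (lam_max tau)^j * b_{j,N} * sum_{n > N} (lam_max tau)^n / n!

    with b_{j,N} the larger of the two sup-ratios of omitted to retained
    mixture coefficients (uncensored and censored branches).  The sup over
    n > N is taken on a finite window extended until both numerator
    sequences are verifiably decreasing.  Returns infinity (with the per-j
    table) when a pivot denominator vanishes for every j.
    """
    if policy is None:
        policy = config.truncation
    N = policy.N
    lam_tau = policy.lam_max * policy.tau
    # extend the window until both numerator sequences decrease for a stretch
    K = window
    for _ in range(8):
        cx, cz = config.coeffs_at(theta, N + K + 2)
        u = (cx[:-1] - cx[1:]) * cz[:-1]   # uncensored-branch coefficients
        v = (cz[:-1] - cz[1:]) * cx[1:]    # censored-branch coefficients
        tail_u, tail_v = u[N + 1:], v[N + 1:]
        dec = 30
        if (np.diff(tail_u[-dec:]) <= 1e-300).all() and (np.diff(tail_v[-dec:]) <= 1e-300).all():
            break
        K *= 2
    sup_u = float(tail_u.max(initial=0.0))
    sup_v = float(tail_v.max(initial=0.0))
    j = np.arange(N + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        b_j = np.maximum(
            np.where(u[: N + 1] > 0, sup_u / u[: N + 1], np.inf),
            np.where(v[: N + 1] > 0, sup_v / v[: N + 1], np.inf),
        )
        if sup_u == 0.0 and sup_v == 0.0:
            b_j = np.zeros(N + 1)
        log_tail = lam_tau + stats.poisson.logsf(N, lam_tau)
        log_prefactor = special.gammaln(j + 1.0) - j * math.log(lam_tau)
        per_j = np.where(np.isinf(b_j), np.inf,
                         np.exp(log_prefactor + np.log(np.maximum(b_j, 1e-300)) + log_tail))
        per_j = np.where(b_j == 0.0, 0.0, per_j)
        per_j_loose = np.where(np.isinf(b_j), np.inf,
                               np.exp(log_prefactor + np.log(np.maximum(b_j, 1e-300)) + lam_tau))
        per_j_loose = np.where(b_j == 0.0, 0.0, per_j_loose)
    j_star = int(np.argmin(per_j))
    return RemainderBound(per_j, j_star, float(per_j[j_star]),
                          float(np.min(per_j_loose)), N, policy.lam_max, policy.tau)


def choose_truncation(theta: Theta, config: ModelConfig, tol: float = 1e-3,
                      N_grid=None) -> TruncationPolicy:
    """Smallest order N on a grid whose remainder bound is below ``tol``.

    Falls back to N = ceil(lam_max tau + 10 sqrt(lam_max tau)) when no grid
    order achieves the tolerance (the bound can be uninformative when the
    Poisson bulk at the horizon exceeds N).
    """
    pol = config.truncation
    if N_grid is None:
        N_grid = range(5, 200, 5)
    for N in N_grid:
        cand = TruncationPolicy(N, pol.lam_max, pol.tau)
        rb = remainder_bound(theta, replace(config, truncation=cand), cand)
        if rb.bound <= tol:
            return cand
    mu = pol.lam_max * pol.tau
    return TruncationPolicy(int(math.ceil(mu + 10.0 * math.sqrt(mu))), pol.lam_max, pol.tau)
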