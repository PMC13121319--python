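"""Exact simulation of the latent process and its censored outcomes.

Each subject carries one stream of exponential inter-arrival times (the
shared Poisson clock) and a pair of jump sequences; the hitting times T and
C are the arrival times of the first jumps at which the cumulative X- and
Z-sums reach their thresholds.  Ties T == C are decided by *jump-count
equality* (nu_x == nu_z), never by comparing floating-point times: the
diagonal atom is a structural event of the common clock, not a numeric
coincidence.

This module doubles as the synthetic-data generator for the whole test
suite; samples are reproducible from (seed, n, theta, config).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import ModelConfig, Theta

__all__ = ["LatentPaths", "CensoredSample", "simulate_latent", "to_outcomes",
           "simulate_sample"]

JUMP_CAP = 1_000_000  # per-subject guard against (near-)degenerate jump laws


@dataclass(frozen=True)
class LatentPaths:
    """Struct-of-arrays view of n latent subject paths.

    ``nu_x``/``nu_z`` are the (1-based) jump counts at which each margin
    first reaches its threshold; ``T``/``C`` are the corresponding arrival
    times (partial sums of the shared inter-arrival stream).
    """

    nu_x: np.ndarray
    nu_z: np.ndarray
    T: np.ndarray
    C: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.T.size


@dataclass(frozen=True)
class CensoredSample:
    """Observed sample (Y_i, Delta_i) under censoring Model I or II.

    Model I:  delta = 1{T <= C}.
    Model II: delta = 0 (T > C), 1 (T < C) or 2 (tie T == C).
    Latent hitting times may be retained for testing.
    """

    y: np.ndarray
    delta: np.ndarray
    model_type: str
    provenance: dict = field(default_factory=dict)
    t_latent: Optional[np.ndarray] = None
    c_latent: Optional[np.ndarray] = None

    def __post_init__(self):
        valid = (0, 1) if self.model_type == "I" else (0, 1, 2)
        if not np.isin(self.delta, valid).all():
            bad = int(np.flatnonzero(~np.isin(self.delta, valid))[0])
            raise ValueError(
                f"delta code {self.delta[bad]} at row {bad} invalid for "
                f"Model {self.model_type}"
            )
        if not (np.isfinite(self.y).all() and (self.y >= 0).all()):
            raise ValueError("y must be finite and nonnegative")

    @property
    def n(self) -> int:
        return self.y.size


def _config_fingerprint(theta: Theta, config: ModelConfig) -> str:
    blob = json.dumps({
        "lam": theta.lam, "alpha": theta.alpha, "beta": theta.beta,
        "x_family": (config.x_family.tag, config.x_family.params),
        "z_family": (config.z_family.tag, config.z_family.params),
        "x": config.x_threshold, "z": config.z_threshold,
        "model_type": config.model_type,
    }, default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate_latent(theta: Theta, config: ModelConfig, n: int,
                    seed=None) -> LatentPaths:
    """Draw n latent subject paths of the bivariate compound Poisson process.

    One shared inter-arrival stream per subject feeds both margins (the
    common clock).  Jumps are drawn in blocks and extended until both
    thresholds are crossed; a subject needing more than ``JUMP_CAP`` jumps
    raises (possible only when a jump law's zero mass is close to 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fx, fz = config.families_at(theta)
    if fx.mean <= 0 or fz.mean <= 0:
        raise ValueError("both jump families must have positive mean")
    rng = np.random.default_rng(seed)
    x_thr, z_thr = config.x_threshold, config.z_threshold

    # crude expected jump counts to size the first block
    guess = max(x_thr / fx.mean, z_thr / fz.mean)
    block = max(8, int(4.0 * guess + 20))

    nu_x = np.zeros(n, dtype=np.int64)
    nu_z = np.zeros(n, dtype=np.int64)
    T = np.zeros(n)
    C = np.zeros(n)
    active = np.arange(n)
    cum_x = np.zeros(n)
    cum_z = np.zeros(n)
    cum_t = np.zeros(n)
    jumps_used = np.zeros(n, dtype=np.int64)

    while active.size:
        m = active.size
        budget = JUMP_CAP - int(jumps_used[active].min())
        if budget <= 0:
            bad = int(active[np.argmin(jumps_used[active])])
            raise RuntimeError(
                f"subject {bad} exceeded the jump cap ({JUMP_CAP}); "
                "a jump law's zero mass may be too close to 1"
            )
        b = min(block, budget)
        E = rng.exponential(1.0 / theta.lam, (m, b))
        X = fx.sample(rng, (m, b))
        Z = fz.sample(rng, (m, b))
        ct = cum_t[active, None] + np.cumsum(E, axis=1)
        sx = cum_x[active, None] + np.cumsum(X, axis=1)
        sz = cum_z[active, None] + np.cumsum(Z, axis=1)

        hit_x = sx >= x_thr
        hit_z = sz >= z_thr
        for hit, nu, tc in ((hit_x, nu_x, T), (hit_z, nu_z, C)):
            rows = np.flatnonzero(hit.any(axis=1))
            idx = active[rows]
            fresh = rows[nu[idx] == 0]
            if fresh.size:
                col = hit[fresh].argmax(axis=1)
                subj = active[fresh]
                nu[subj] = jumps_used[subj] + col + 1
                tc[subj] = ct[fresh, col]

        jumps_used[active] += b
        cum_t[active] = ct[:, -1]
        cum_x[active] = sx[:, -1]
        cum_z[active] = sz[:, -1]
        done = (nu_x[active] > 0) & (nu_z[active] > 0)
        active = active[~done]

    prov = {"seed": seed, "n": n, "fingerprint": _config_fingerprint(theta, config)}
    return LatentPaths(nu_x, nu_z, T, C, prov)


def to_outcomes(paths: LatentPaths, model_type: str,
                keep_latent: bool = False) -> CensoredSample:
    """Reduce latent paths to the observed censored outcomes (Y, Delta).

    Ties are exact integer events (nu_x == nu_z).  Model I records
    delta = 1{T <= C}; Model II distinguishes strict orderings and the tie.
    """
    if model_type not in ("I", "II"):
        raise ValueError("model_type must be 'I' or 'II'")
    tie = paths.nu_x == paths.nu_z
    t_first = paths.nu_x < paths.nu_z
    y = np.where(t_first | tie, paths.T, paths.C)
    if model_type == "I":
        delta = (t_first | tie).astype(np.int64)
    else:
        delta = np.where(tie, 2, t_first.astype(np.int64))
    return CensoredSample(
        y=y, delta=delta, model_type=model_type,
        provenance=dict(paths.provenance, model_type=model_type),
        t_latent=paths.T if keep_latent else None,
        c_latent=paths.C if keep_latent else None,
    )


def simulate_sample(theta: Theta, config: ModelConfig, n: int, seed=None,
                    model_type: Optional[str] = None,
                    keep_latent: bool = False) -> CensoredSample:
    """Simulate a censored sample of size n in one call."""
    paths = simulate_latent(theta, config, n, seed)
    return to_outcomes(paths, model_type or config.model_type, keep_latent)
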