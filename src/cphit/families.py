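"""Jump-size distributions and their cumulative-sum coefficient sequences.

The latent model is driven by two nondecreasing compound Poisson processes
sharing one Poisson clock.  Everything observable about a jump-size law
``M`` enters the likelihood only through its coefficient sequence

    c_n = P(M_1 + ... + M_n < threshold),    c_0 = 1,

the probability that the n-fold sum of jumps stays *strictly* below the
crossing threshold.  This module represents the jump laws, computes their
c-sequences in closed form, classifies each law into the identifiability
classes F1/F2/F3, and provides the ratio-limit diagnostics that determine
which censoring model (I or II) identifies the intensity parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import special, stats

__all__ = [
    "JumpFamily",
    "CoeffSeq",
    "RatioDiagnostic",
    "AssumptionReport",
    "coeff_sequence",
    "classify_family",
    "ratio_limit_diagnostic",
    "check_assumption",
]

# family tags with a free (estimable) parametrisation and the transform used
# by the optimiser for each coordinate
_FREE_PARAMS = {
    "degenerate": (),
    "bernoulli": (("p", "logit"),),
    "binomial": (("p", "logit"),),
    "poisson": (("mean", "log"),),
    "exponential": (("rate", "log"),),
    "gamma": (("shape", "log"), ("rate", "log")),
    "discrete_lattice": (),
}

_DEFAULT_BOUNDS = {"logit": (1e-4, 1.0 - 1e-4), "log": (0.01, 50.0)}


@dataclass(frozen=True)
class JumpFamily:
    """A nonnegative jump-size law, one of a small set of parametric families.

    Instances are immutable and hashable so that coefficient sequences can be
    cached by value.  Use the class-method constructors; ``params`` is an
    ordered tuple of (name, value) pairs.
    """

    tag: str
    params: tuple

    # ---- constructors -------------------------------------------------
    @classmethod
    def degenerate(cls, value: float) -> "JumpFamily":
        if value <= 0:
            raise ValueError("degenerate jump must be positive (zero_mass < 1)")
        return cls("degenerate", (("value", float(value)),))

    @classmethod
    def bernoulli(cls, p: float) -> "JumpFamily":
        if not 0.0 < p < 1.0:
            raise ValueError(f"bernoulli p must be in (0,1), got {p}")
        return cls("bernoulli", (("p", float(p)),))

    @classmethod
    def binomial(cls, size: int, p: float) -> "JumpFamily":
        if size < 1 or not 0.0 < p < 1.0:
            raise ValueError("binomial needs size >= 1 and p in (0,1)")
        return cls("binomial", (("size", int(size)), ("p", float(p))))

    @classmethod
    def poisson(cls, mean: float) -> "JumpFamily":
        if mean <= 0:
            raise ValueError("poisson mean must be positive")
        return cls("poisson", (("mean", float(mean)),))

    @classmethod
    def exponential(cls, rate: float) -> "JumpFamily":
        if rate <= 0:
            raise ValueError("exponential rate must be positive")
        return cls("exponential", (("rate", float(rate)),))

    @classmethod
    def gamma(cls, shape: float, rate: float) -> "JumpFamily":
        if shape <= 0 or rate <= 0:
            raise ValueError("gamma needs positive shape and rate")
        return cls("gamma", (("shape", float(shape)), ("rate", float(rate))))

    @classmethod
    def lattice(cls, atoms, probs) -> "JumpFamily":
        atoms = tuple(float(a) for a in atoms)
        probs = tuple(float(p) for p in probs)
        if len(atoms) != len(probs) or not atoms:
            raise ValueError("atoms and probs must be nonempty, equal length")
        if any(a < 0 for a in atoms) or any(p < 0 for p in probs):
            raise ValueError("atoms and probs must be nonnegative")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError("probs must sum to 1")
        mass_at_zero = sum(p for a, p in zip(atoms, probs) if a == 0.0)
        if mass_at_zero >= 1.0 - 1e-15:
            raise ValueError("jump law must put positive mass off zero")
        return cls("discrete_lattice", (("atoms", atoms), ("probs", probs)))

    # ---- accessors ----------------------------------------------------
    def __getitem__(self, name):
        for k, v in self.params:
            if k == name:
                return v
        raise KeyError(name)

    @property
    def zero_mass(self) -> float:
        """P(one jump equals 0); must be < 1 for the model to be valid."""
        if self.tag == "degenerate":
            return 0.0
        if self.tag == "bernoulli":
            return 1.0 - self["p"]
        if self.tag == "binomial":
            return (1.0 - self["p"]) ** self["size"]
        if self.tag == "poisson":
            return math.exp(-self["mean"])
        if self.tag in ("exponential", "gamma"):
            return 0.0
        if self.tag == "discrete_lattice":
            return sum(p for a, p in zip(self["atoms"], self["probs"]) if a == 0.0)
        raise ValueError(self.tag)

    @property
    def support_min(self) -> float:
        """Essential minimum of one jump."""
        if self.tag == "degenerate":
            return self["value"]
        if self.tag == "discrete_lattice":
            return min(a for a, p in zip(self["atoms"], self["probs"]) if p > 0)
        return 0.0

    @property
    def mean(self) -> float:
        if self.tag == "degenerate":
            return self["value"]
        if self.tag == "bernoulli":
            return self["p"]
        if self.tag == "binomial":
            return self["size"] * self["p"]
        if self.tag == "poisson":
            return self["mean"]
        if self.tag == "exponential":
            return 1.0 / self["rate"]
        if self.tag == "gamma":
            return self["shape"] / self["rate"]
        if self.tag == "discrete_lattice":
            return sum(a * p for a, p in zip(self["atoms"], self["probs"]))
        raise ValueError(self.tag)

    # ---- free-parameter interface for inference -----------------------
    @property
    def free_param_names(self) -> tuple:
        return tuple(name for name, _ in _FREE_PARAMS[self.tag])

    @property
    def free_param_transforms(self) -> tuple:
        return tuple(tr for _, tr in _FREE_PARAMS[self.tag])

    @property
    def free_params(self) -> tuple:
        return tuple(self[name] for name in self.free_param_names)

    def default_bounds(self) -> tuple:
        return tuple(_DEFAULT_BOUNDS[tr] for tr in self.free_param_transforms)

    def with_params(self, values) -> "JumpFamily":
        """Return a copy with the free parameters replaced by ``values``."""
        names = self.free_param_names
        values = tuple(float(v) for v in values)
        if len(values) != len(names):
            raise ValueError(
                f"{self.tag} has {len(names)} free parameter(s), got {len(values)}"
            )
        new = dict(self.params)
        new.update(zip(names, values))
        fam = JumpFamily(self.tag, tuple(new.items()))
        fam._validate()
        return fam

    def _validate(self) -> None:
        rebuilt = {
            "degenerate": lambda: JumpFamily.degenerate(self["value"]),
            "bernoulli": lambda: JumpFamily.bernoulli(self["p"]),
            "binomial": lambda: JumpFamily.binomial(self["size"], self["p"]),
            "poisson": lambda: JumpFamily.poisson(self["mean"]),
            "exponential": lambda: JumpFamily.exponential(self["rate"]),
            "gamma": lambda: JumpFamily.gamma(self["shape"], self["rate"]),
            "discrete_lattice": lambda: JumpFamily.lattice(self["atoms"], self["probs"]),
        }[self.tag]()
        assert rebuilt == self

    # ---- sampling ------------------------------------------------------
    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.tag == "degenerate":
            return np.full(size, self["value"])
        if self.tag == "bernoulli":
            return (rng.random(size) < self["p"]).astype(float)
        if self.tag == "binomial":
            return rng.binomial(self["size"], self["p"], size).astype(float)
        if self.tag == "poisson":
            return rng.poisson(self["mean"], size).astype(float)
        if self.tag == "exponential":
            return rng.exponential(1.0 / self["rate"], size)
        if self.tag == "gamma":
            return rng.gamma(self["shape"], 1.0 / self["rate"], size)
        if self.tag == "discrete_lattice":
            atoms = np.asarray(self["atoms"])
            return atoms[rng.choice(len(atoms), size=size, p=np.asarray(self["probs"]))]
        raise ValueError(self.tag)

    def describe(self) -> str:
        inner = ", ".join(f"{k}={v}" for k, v in self.params)
        return f"{self.tag}({inner})"


@dataclass(frozen=True)
class CoeffSeq:
    """The sequence c_0..c_N of probabilities P(S_n < threshold).

    ``n_max_zero`` is the smallest index at which the sequence hits exactly
    zero (only possible for laws bounded away from zero), or None.
    """

    values: np.ndarray
    threshold: float
    family: JumpFamily
    n_max_zero: Optional[int] = field(default=None)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def N(self) -> int:
        return len(self.values) - 1


def _largest_lattice_point_below(threshold: float) -> int:
    """Largest integer strictly below threshold (threshold > 0)."""
    k = math.ceil(threshold) - 1
    if float(math.ceil(threshold)) == threshold:
        k = int(threshold) - 1
    return k


def _coeff_values(family: JumpFamily, threshold: float, N: int) -> np.ndarray:
    n = np.arange(N + 1)
    if family.tag == "degenerate":
        return (n * family["value"] < threshold).astype(float)
    if family.tag in ("bernoulli", "binomial", "poisson"):
        # integer-lattice sums: strict "<" means CDF at the largest integer
        # strictly below the threshold
        k = _largest_lattice_point_below(threshold)
        if k < 0:
            out = np.zeros(N + 1)
            out[0] = 1.0  # empty sum is 0 < threshold
            return out
        if family.tag == "bernoulli":
            vals = stats.binom.cdf(k, n, family["p"])
        elif family.tag == "binomial":
            vals = stats.binom.cdf(k, n * family["size"], family["p"])
        else:
            vals = stats.poisson.cdf(k, n * family["mean"])
        vals = np.asarray(vals, dtype=float)
        vals[0] = 1.0
        return vals
    if family.tag in ("exponential", "gamma"):
        shape1 = 1.0 if family.tag == "exponential" else family["shape"]
        # P(Gamma(n*shape1, rate) < x) = regularized lower incomplete gamma
        vals = special.gammainc(np.maximum(n * shape1, 1e-300), family["rate"] * threshold)
        vals = np.asarray(vals, dtype=float)
        vals[0] = 1.0
        return vals
    if family.tag == "discrete_lattice":
        return _lattice_convolution(family, threshold, N)
    raise ValueError(family.tag)


def _lattice_convolution(family: JumpFamily, threshold: float, N: int) -> np.ndarray:
    """Exact convolution of a finite atomic law, truncated at the threshold.

    Only support points strictly below the threshold are carried; everything
    at or above is absorbed (it can never return below, jumps being >= 0).
    """
    atoms = np.asarray(family["atoms"], dtype=float)
    probs = np.asarray(family["probs"], dtype=float)
    keep = probs > 0
    atoms, probs = atoms[keep], probs[keep]
    vals = np.zeros(N + 1)
    vals[0] = 1.0
    support = np.array([0.0])
    mass = np.array([1.0])
    for i in range(1, N + 1):
        if mass.size == 0:
            break
        new_support = (support[:, None] + atoms[None, :]).ravel()
        new_mass = (mass[:, None] * probs[None, :]).ravel()
        below = new_support < threshold
        new_support, new_mass = new_support[below], new_mass[below]
        # merge equal support points
        support, inv = np.unique(new_support, return_inverse=True)
        mass = np.zeros_like(support)
        np.add.at(mass, inv, new_mass)
        vals[i] = mass.sum()
    return vals


@lru_cache(maxsize=4096)
def _coeff_cached(family: JumpFamily, threshold: float, N: int):
    vals = _coeff_values(family, threshold, N)
    vals = np.clip(vals, 0.0, 1.0)
    vals.setflags(write=False)
    return vals


def coeff_sequence(family: JumpFamily, threshold: float, N: int) -> CoeffSeq:
    """Compute c_n = P(S_n < threshold) for n = 0..N in closed form.

    The inequality is strict; on lattice families it is honoured exactly by
    evaluating the CDF at the largest support point strictly below the
    threshold.  Results are cached by (family, threshold, N).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if N < 0:
        raise ValueError("N must be >= 0")
    vals = _coeff_cached(family, float(threshold), int(N))
    zeros = np.flatnonzero(vals == 0.0)
    n_max_zero = int(zeros[0]) if zeros.size else None
    return CoeffSeq(vals, float(threshold), family, n_max_zero)


def classify_family(family: JumpFamily) -> str:
    """Classify a jump law into the identifiability classes F1/F2/F3.

    F1: jumps almost surely bounded away from zero (the c-sequence hits an
    exact zero).  F2: absolutely continuous with mass near zero (the
    coefficient ratio c_{n+1}/c_n tends to 0).  F3: discrete with an atom at
    zero and a smallest positive atom (the ratio tends to the zero mass).
    """
    if family.tag == "degenerate":
        return "F1"
    if family.tag in ("exponential", "gamma"):
        return "F2"
    if family.tag in ("bernoulli", "binomial", "poisson"):
        return "F3"
    if family.tag == "discrete_lattice":
        if family.support_min > 0:
            return "F1"
        if family.zero_mass > 0:
            return "F3"
    return "unclassified"


@dataclass(frozen=True)
class RatioDiagnostic:
    """Empirical behaviour of the coefficient ratio c_{n+1}/c_n."""

    limit_estimate: float
    last_ratio: float
    n_max_zero: Optional[int]
    tail_slope: float  # coefficient b of the fitted trend a + b/n
    n_used: int

    @property
    def exact_zero(self) -> bool:
        return self.n_max_zero is not None


def ratio_limit_diagnostic(coeffs: CoeffSeq) -> RatioDiagnostic:
    """Estimate the limit of c_{n+1}/c_n from a computed sequence.

    The hazard of the observed time tends to lambda*(1 - a) where a is the
    limit of the product ratio; for an F1 law the sequence hits exact zero,
    for F2 the ratio tends to 0, for F3 it tends to the law's zero mass with
    an O(1/n) discrepancy.  This is a report, not an assertion of class
    membership: the fitted trend a + b/n over the tail of the ratio sequence
    is returned alongside the last computable ratio.
    """
    vals = coeffs.values
    if coeffs.n_max_zero is not None:
        k = coeffs.n_max_zero
        last = vals[k] / vals[k - 1] if k >= 1 else 0.0
        return RatioDiagnostic(0.0, float(last), k, 0.0, k)
    pos = vals > 0
    if not pos.all():  # positive prefix only (cannot happen without zeros)
        vals = vals[: np.flatnonzero(~pos)[0]]
    if len(vals) < 11:
        raise ValueError(
            "sequence too short to assess: need >= 10 consecutive positive "
            "ratios or an exact zero"
        )
    ratios = vals[1:] / vals[:-1]
    n = np.arange(1, len(vals))
    # fit ratio_n ~ a + b/n on the last half of the sequence
    tail = slice(len(ratios) // 2, None)
    X = np.column_stack([np.ones(n[tail].size), 1.0 / n[tail]])
    (a, b), *_ = np.linalg.lstsq(X, ratios[tail], rcond=None)
    return RatioDiagnostic(float(a), float(ratios[-1]), None, float(b), len(ratios))


@dataclass(frozen=True)
class AssumptionReport:
    """Which identifiability assumption a pair of jump laws satisfies."""

    tag: str  # H1 | H2.i | H2.ii | none
    required_model: str  # "I" (Model I suffices) or "II"
    x_class: str
    z_class: str
    n_max: Optional[int] = None  # under H1, the index past which the model is a finite sum
    explanation: str = ""


def check_assumption(
    x_family: JumpFamily,
    z_family: JumpFamily,
    x_threshold: Optional[float] = None,
    z_threshold: Optional[float] = None,
) -> AssumptionReport:
    """Determine the identifiability regime of a pair of jump laws.

    H1 (either law in F1): Model I identifies everything and the model is a
    finite sum past N_max = min{n : c_{n,X} = 0 or c_{n,Z} = 0}, reported
    when thresholds are supplied.  H2.i (either law in F2): Model I
    suffices.  H2.ii (both laws in F3): the hazard limit only pins down
    lambda*(1 - P[X1=0]P[Z1=0]), so Model II is required.
    """
    cx, cz = classify_family(x_family), classify_family(z_family)
    if "unclassified" in (cx, cz):
        return AssumptionReport(
            "none", "II", cx, cz,
            explanation="a family could not be classified into F1/F2/F3",
        )
    if "F1" in (cx, cz):
        n_max = None
        candidates = []
        if cx == "F1" and x_threshold is not None:
            candidates.append(math.ceil(x_threshold / x_family.support_min))
        if cz == "F1" and z_threshold is not None:
            candidates.append(math.ceil(z_threshold / z_family.support_min))
        if candidates:
            n_max = min(candidates)
        return AssumptionReport("H1", "I", cx, cz, n_max,
                                "a jump law is bounded away from zero")
    if "F2" in (cx, cz):
        return AssumptionReport("H2.i", "I", cx, cz, None,
                                "an absolutely continuous law drives the ratio to 0")
    return AssumptionReport(
        "H2.ii", "II", cx, cz, None,
        "both laws are discrete with atoms at zero: the tie indicator of "
        "Model II is needed to identify the intensity",
    )
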