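"""Coefficient sequences: closed forms vs brute force, classes, diagnostics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from cphit import (
    JumpFamily,
    check_assumption,
    classify_family,
    coeff_sequence,
    ratio_limit_diagnostic,
)


# ---------------------------------------------------------------------------
# independent oracles


def pmf_convolution_oracle(pmf0: np.ndarray, threshold: float, n: int) -> float:
    """P(S_n < threshold) for an integer-supported law by full pmf
    convolution (no truncation at the threshold)."""
    pmf = np.array([1.0])
    for _ in range(n):
        pmf = np.convolve(pmf, pmf0)
    k = math.ceil(threshold) - 1
    return float(pmf[: k + 1].sum())


def gamma_quadrature_oracle(shape: float, rate: float, threshold: float, n: int) -> float:
    """P(Gamma(n*shape, rate) < threshold) by adaptive quadrature of the
    density written from scratch."""
    a = n * shape

    def pdf(s):
        return math.exp(a * math.log(rate) + (a - 1) * math.log(s)
                        - rate * s - math.lgamma(a))

    val, err = integrate.quad(pdf, 0.0, threshold, limit=400,
                              epsabs=1e-13, epsrel=1e-13)
    assert err < 5e-11
    return val


# ---------------------------------------------------------------------------
# closed forms vs oracles


def test_degenerate_strictness():
    seq = coeff_sequence(JumpFamily.degenerate(1.0), 17.0, 17)
    assert seq.values[16] == 1.0 and seq.values[17] == 0.0
    assert seq.n_max_zero == 17


def test_c0_is_one_for_every_family():
    fams = [JumpFamily.degenerate(2.0), JumpFamily.bernoulli(0.36),
            JumpFamily.binomial(3, 0.4), JumpFamily.poisson(1.23),
            JumpFamily.exponential(0.71), JumpFamily.gamma(2.0, 1.5),
            JumpFamily.lattice((0.0, 0.5, 2.0), (0.2, 0.5, 0.3))]
    for fam in fams:
        assert coeff_sequence(fam, 7.0, 5).values[0] == 1.0


def test_exponential_c1_against_quadrature():
    seq = coeff_sequence(JumpFamily.exponential(0.71), 14.0, 2)
    val, _ = integrate.quad(lambda s: 0.71 * math.exp(-0.71 * s), 0.0, 14.0)
    assert seq.values[1] == pytest.approx(val, abs=1e-12)
    assert seq.values[1] == pytest.approx(1.0 - math.exp(-9.94), abs=1e-12)


def test_bernoulli_c10_by_exhaustive_enumeration():
    p = 0.36
    total = 0.0
    for bits in itertools.product((0, 1), repeat=10):
        if sum(bits) < 7:
            total += p ** sum(bits) * (1 - p) ** (10 - sum(bits))
    seq = coeff_sequence(JumpFamily.bernoulli(p), 7.0, 10)
    assert seq.values[10] == pytest.approx(total, abs=1e-12)


@pytest.mark.parametrize("fam,pmf0,threshold", [
    (JumpFamily.bernoulli(0.36), np.array([0.64, 0.36]), 7.0),
    (JumpFamily.binomial(3, 0.4), stats.binom.pmf(np.arange(4), 3, 0.4), 6.5),
    (JumpFamily.poisson(1.23), stats.poisson.pmf(np.arange(60), 1.23), 19.0),
])
def test_lattice_closed_forms_vs_pmf_convolution(fam, pmf0, threshold):
    seq = coeff_sequence(fam, threshold, 30)
    for n in range(31):
        assert seq.values[n] == pytest.approx(
            pmf_convolution_oracle(pmf0, threshold, n), abs=1e-10)


@pytest.mark.parametrize("fam,shape", [
    (JumpFamily.exponential(0.71), 1.0),
    (JumpFamily.gamma(1.7, 2.2), 1.7),
])
def test_continuous_closed_forms_vs_quadrature(fam, shape):
    rate = fam["rate"]
    seq = coeff_sequence(fam, 6.0, 30)
    for n in range(1, 31):
        assert seq.values[n] == pytest.approx(
            gamma_quadrature_oracle(shape, rate, 6.0, n), abs=1e-10)


def test_discrete_lattice_matches_integer_family():
    # a two-atom lattice encoding Bernoulli(0.36) must agree with the
    # dedicated closed form
    lat = JumpFamily.lattice((0.0, 1.0), (0.64, 0.36))
    ber = JumpFamily.bernoulli(0.36)
    np.testing.assert_allclose(coeff_sequence(lat, 7.0, 25).values,
                               coeff_sequence(ber, 7.0, 25).values, atol=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    tag=st.sampled_from(["bernoulli", "poisson", "exponential", "gamma", "degenerate"]),
    raw=st.tuples(st.floats(0.05, 0.95), st.floats(0.1, 5.0)),
    threshold=st.floats(0.5, 25.0),
)
def test_monotone_and_bounded(tag, raw, threshold):
    """c_{n+1} <= c_n and every value lies in [0, 1], for random families."""
    p, r = raw
    fam = {
        "bernoulli": lambda: JumpFamily.bernoulli(p),
        "poisson": lambda: JumpFamily.poisson(r),
        "exponential": lambda: JumpFamily.exponential(r),
        "gamma": lambda: JumpFamily.gamma(0.5 + p, r),
        "degenerate": lambda: JumpFamily.degenerate(r),
    }[tag]()
    vals = coeff_sequence(fam, threshold, 40).values
    assert (np.diff(vals) <= 1e-12).all()
    assert ((vals >= 0) & (vals <= 1)).all()


def test_f1_zero_at_ceiling_of_threshold_over_minimum():
    fam = JumpFamily.lattice((0.5, 2.0), (0.6, 0.4))
    seq = coeff_sequence(fam, 4.0, 20)
    assert seq.n_max_zero == math.ceil(4.0 / 0.5)
    assert (seq.values[8:] == 0.0).all()


def test_exponential_product_invariance():
    # only alpha*x enters: (rate a, threshold x) == (rate ka, threshold x/k)
    for k in (0.5, 2.0, 7.3):
        s1 = coeff_sequence(JumpFamily.exponential(0.71), 14.0, 30).values
        s2 = coeff_sequence(JumpFamily.exponential(0.71 * k), 14.0 / k, 30).values
        np.testing.assert_allclose(s1, s2, atol=1e-13)


# ---------------------------------------------------------------------------
# classification and diagnostics


@pytest.mark.parametrize("fam,expected", [
    (JumpFamily.degenerate(1.0), "F1"),
    (JumpFamily.lattice((0.5, 1.0), (0.5, 0.5)), "F1"),
    (JumpFamily.exponential(0.71), "F2"),
    (JumpFamily.gamma(2.0, 1.0), "F2"),
    (JumpFamily.bernoulli(0.36), "F3"),
    (JumpFamily.binomial(4, 0.2), "F3"),
    (JumpFamily.poisson(1.23), "F3"),
    (JumpFamily.lattice((0.0, 2.0), (0.3, 0.7)), "F3"),
])
def test_classification(fam, expected):
    assert classify_family(fam) == expected


def test_ratio_limit_f2_tends_to_zero():
    seq = coeff_sequence(JumpFamily.exponential(0.71), 14.0, 200)
    diag = ratio_limit_diagnostic(seq)
    assert abs(diag.limit_estimate) < 1e-3


def test_ratio_limit_f3_tends_to_zero_mass():
    fam = JumpFamily.poisson(1.23)
    seq = coeff_sequence(fam, 19.0, 400)
    diag = ratio_limit_diagnostic(seq)
    assert diag.limit_estimate == pytest.approx(math.exp(-1.23), abs=5e-2)
    # the discrepancy shrinks like 1/n: the raw ratio at n=100 is farther
    # from the limit than at n=399
    r = seq.values[1:] / seq.values[:-1]
    assert abs(r[399 - 1] - fam.zero_mass) < abs(r[100] - fam.zero_mass)


def test_ratio_limit_f1_exact_zero():
    seq = coeff_sequence(JumpFamily.degenerate(1.0), 17.0, 40)
    diag = ratio_limit_diagnostic(seq)
    assert diag.exact_zero and diag.n_max_zero == 17 and diag.limit_estimate == 0.0


def test_ratio_limit_too_short():
    with pytest.raises(ValueError, match="too short"):
        ratio_limit_diagnostic(coeff_sequence(JumpFamily.exponential(1.0), 5.0, 5))


@pytest.mark.parametrize("xf,zf,tag,model", [
    (JumpFamily.bernoulli(0.36), JumpFamily.degenerate(1.0), "H1", "I"),
    (JumpFamily.exponential(0.71), JumpFamily.exponential(2.04), "H2.i", "I"),
    (JumpFamily.bernoulli(0.36), JumpFamily.poisson(1.23), "H2.ii", "II"),
])
def test_assumption_regimes(xf, zf, tag, model):
    report = check_assumption(xf, zf)
    assert report.tag == tag and report.required_model == model


def test_assumption_h1_reports_finite_sum_order():
    report = check_assumption(JumpFamily.bernoulli(0.36), JumpFamily.degenerate(1.0),
                              x_threshold=7.0, z_threshold=17.0)
    assert report.n_max == 17


# ---------------------------------------------------------------------------
# validation


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        JumpFamily.bernoulli(1.0)
    with pytest.raises(ValueError):
        JumpFamily.exponential(-1.0)
    with pytest.raises(ValueError):
        JumpFamily.lattice((0.0,), (1.0,))  # all mass at zero
    with pytest.raises(ValueError):
        coeff_sequence(JumpFamily.poisson(1.0), -2.0, 5)
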