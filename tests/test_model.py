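"""Model functions: closed forms, internal consistency, truncation bound."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate, stats

from cphit import (
    JumpFamily,
    ModelConfig,
    Theta,
    TruncationPolicy,
    branch_mass,
    hazard,
    joint_density_ac,
    marginal_survival,
    outcome_log_density,
    prob_equal,
    remainder_bound,
    singular_density,
    y_survival,
)


# ---------------------------------------------------------------------------
# tie probability


def test_prob_equal_certain_tie():
    fam = JumpFamily.degenerate(1.0)
    cfg = ModelConfig(fam, fam, 2.0, 2.0, "I", TruncationPolicy(N=5))
    assert prob_equal(Theta(1.0), cfg) == 1.0


def test_prob_equal_single_term():
    # Z crosses at the very first jump: a tie requires X to cross then too
    cfg = ModelConfig(JumpFamily.bernoulli(0.3), JumpFamily.degenerate(1.0),
                      1.0, 1.0, "I", TruncationPolicy(N=5))
    assert prob_equal(Theta(1.0, (0.3,), ()), cfg) == pytest.approx(0.3, abs=1e-14)


def test_prob_equal_case_a_is_single_binomial_difference(case_a):
    theta, cfg = case_a
    c16 = stats.binom.cdf(6, 16, 0.36)
    c17 = stats.binom.cdf(6, 17, 0.36)
    assert prob_equal(theta, cfg) == pytest.approx(c16 - c17, abs=1e-14)


def test_prob_equal_zero_iff_certain_ordering():
    # Z always crosses at jump 1, X needs three jumps: C < T almost surely
    cfg = ModelConfig(JumpFamily.degenerate(1.0), JumpFamily.degenerate(1.0),
                      3.0, 1.0, "I", TruncationPolicy(N=5))
    assert prob_equal(Theta(1.0), cfg) == 0.0


def test_prob_equal_does_not_depend_on_lambda(case_b):
    _, cfg = case_b
    assert prob_equal(Theta(0.3, (0.71,), (2.04,)), cfg) == \
        prob_equal(Theta(5.0, (0.71,), (2.04,)), cfg)


# ---------------------------------------------------------------------------
# densities


def test_singular_density_erlang_closed_form(erlang_model):
    theta, cfg = erlang_model
    u = np.array([0.0, 0.7, 2.3, 8.0])
    expected = theta.lam ** 2 * u * np.exp(-theta.lam * u)
    np.testing.assert_allclose(singular_density(u, theta, cfg), expected, atol=1e-14)


def test_singular_density_integrates_to_tie_probability(case_b):
    theta, cfg = case_b
    val, _ = integrate.quad(lambda u: singular_density(u, theta, cfg), 0, 120,
                            limit=300)
    assert val == pytest.approx(prob_equal(theta, cfg), abs=1e-8)


def test_joint_ac_symmetry(case_b):
    theta, cfg = case_b
    swapped_theta = Theta(theta.lam, theta.beta, theta.alpha)
    swapped_cfg = ModelConfig(cfg.z_family, cfg.x_family, cfg.z_threshold,
                              cfg.x_threshold, "I", cfg.truncation)
    for (u, v) in [(1.0, 2.0), (0.3, 5.5), (4.0, 0.1)]:
        assert joint_density_ac(u, v, theta, cfg) == pytest.approx(
            joint_density_ac(v, u, swapped_theta, swapped_cfg), rel=1e-12)


def test_joint_ac_refuses_diagonal(case_b):
    theta, cfg = case_b
    with pytest.raises(ValueError, match="diagonal"):
        joint_density_ac(1.5, 1.5, theta, cfg)


def test_joint_ac_triangles_match_branch_masses(case_a):
    """Integrating the off-diagonal density over each triangle recovers
    P(T<C) and P(T>C)."""
    theta, cfg = case_a
    f = lambda u, v: joint_density_ac(u, v, theta, cfg, N=60)
    upper, _ = integrate.dblquad(lambda v, u: f(u, v), 0, 90, lambda u: u, 90,
                                 epsabs=1e-7)
    p_lt = branch_mass(1, theta, cfg, N=100) - prob_equal(theta, cfg, N=100)
    assert upper == pytest.approx(p_lt, abs=1e-5)


def test_outcome_density_erlang_branches(erlang_model):
    theta, cfg = erlang_model
    t = 2.3
    assert outcome_log_density(t, 1, theta, cfg) == pytest.approx(
        math.log(theta.lam ** 2 * t * math.exp(-theta.lam * t)), abs=1e-12)
    assert outcome_log_density(t, 0, theta, cfg) == -np.inf


def test_model_ii_branches_sum_to_model_i(case_a):
    theta, cfg = case_a
    cfg2 = replace(cfg, model_type="II")
    t = np.array([0.0, 0.5, 3.0, 9.0, 18.0])
    total = sum(np.exp(outcome_log_density(t, d, theta, cfg2)) for d in (1, 2))
    np.testing.assert_allclose(
        total, np.exp(outcome_log_density(t, 1, theta, cfg)), atol=1e-15)


def test_case_a_density_is_exact_finite_sum(case_a):
    """The degenerate Z margin kills every coefficient past n=17, so the
    truncated evaluator equals a direct linear-space finite sum."""
    theta, cfg = case_a
    lam, p = theta.lam, theta.alpha[0]
    t, delta = 5.0, 0
    cx = stats.binom.cdf(6, np.arange(19), p)
    cz = (np.arange(19) < 17).astype(float)
    coefs = (cz[:-1] - cz[1:]) * cx[1:]
    direct = sum(c * lam * math.exp(-lam * t) * (lam * t) ** n / math.factorial(n)
                 for n, c in enumerate(coefs))
    assert math.exp(outcome_log_density(t, delta, theta, cfg)) == \
        pytest.approx(direct, abs=1e-10)


def test_invalid_delta_rejected(case_a):
    theta, cfg = case_a
    with pytest.raises(ValueError, match="delta"):
        outcome_log_density(1.0, 2, theta, cfg)


def test_outcome_density_normalizes(case_b, case_c):
    for theta, cfg in (case_b, case_c):
        total = sum(
            integrate.quad(lambda t: math.exp(outcome_log_density(t, d, theta, cfg, N=200)),
                           0, 120, limit=300)[0]
            for d in cfg.valid_deltas)
        assert total == pytest.approx(1.0, abs=1e-4)


def test_exponential_rescaling_leaves_density_invariant(case_b):
    """(x -> x/k, alpha -> k*alpha) and (z -> z/m, beta -> m*beta) leave the
    outcome density unchanged: only alpha*x and beta*z enter."""
    theta, cfg = case_b
    k, m = 3.0, 0.25
    cfg2 = replace(cfg, x_threshold=cfg.x_threshold / k, z_threshold=cfg.z_threshold / m)
    theta2 = Theta(theta.lam, (theta.alpha[0] * k,), (theta.beta[0] * m,))
    t = np.linspace(0.1, 20.0, 25)
    for d in (0, 1):
        np.testing.assert_allclose(outcome_log_density(t, d, theta, cfg),
                                   outcome_log_density(t, d, theta2, cfg2),
                                   atol=1e-12)


# ---------------------------------------------------------------------------
# hazard and survival


def test_hazard_erlang_closed_form(erlang_model):
    theta, cfg = erlang_model
    t = np.array([0.2, 1.0, 4.0, 30.0])
    np.testing.assert_allclose(hazard(t, theta, cfg),
                               theta.lam ** 2 * t / (1 + theta.lam * t), rtol=1e-12)


def test_hazard_limit_is_lambda_under_h2i(case_b):
    """With absolutely continuous jumps the hazard of Y climbs to lambda;
    the coefficient ratio decays like 1/n, so the approach is slow in t."""
    theta, cfg = case_b
    t = np.array([50.0, 500.0, 5000.0, 20000.0])
    h = hazard(t, theta, cfg)
    assert (np.diff(h) > 0).all() and (h <= theta.lam).all()
    assert h[-1] == pytest.approx(theta.lam, abs=1e-2)


def test_hazard_consistent_with_density_over_survival(case_b):
    theta, cfg = case_b
    t = np.linspace(0.5, 15.0, 20)
    f_y = sum(np.exp(outcome_log_density(t, d, theta, cfg, N=120)) for d in (0, 1))
    np.testing.assert_allclose(hazard(t, theta, cfg), f_y / y_survival(t, theta, cfg),
                               atol=1e-8)


def test_hazard_bounded_by_lambda(case_a, case_b, case_c):
    t = np.linspace(0.1, 40.0, 50)
    for theta, cfg in (case_a, case_b, case_c):
        h = hazard(t, theta, cfg)
        assert ((h >= 0) & (h <= theta.lam + 1e-12)).all()


def test_marginal_survival_erlang(erlang_model):
    theta, cfg = erlang_model
    t = np.array([0.0, 1.2, 6.0])
    np.testing.assert_allclose(marginal_survival("T", t, theta, cfg),
                               np.exp(-theta.lam * t) * (1 + theta.lam * t),
                               rtol=1e-12)


def test_marginal_survival_monotone_from_one(case_c):
    theta, cfg = case_c
    t = np.linspace(0.0, 40.0, 100)
    s = marginal_survival("C", t, theta, cfg)
    assert s[0] == 1.0 and (np.diff(s) <= 1e-12).all()


# ---------------------------------------------------------------------------
# truncation remainder


def test_remainder_zero_when_series_terminates(case_a):
    theta, cfg = case_a
    rb = remainder_bound(theta, cfg)
    assert rb.bound == 0.0


def test_remainder_nonincreasing_in_N(case_b):
    theta, cfg = case_b
    bounds = []
    for N in range(20, 41, 5):
        cfgN = replace(cfg, truncation=TruncationPolicy(N, 2.0, 20.0))
        bounds.append(remainder_bound(theta, cfgN).bound)
    assert all(b2 <= b1 * (1 + 1e-12) for b1, b2 in zip(bounds, bounds[1:]))


def test_remainder_case_b_pivot_value(case_b):
    """The j=18 candidate at N=25, lam_max=2, tau=20 agrees with an
    independent high-precision evaluation of the pivot formula."""
    theta, cfg = case_b
    rb = remainder_bound(theta, cfg)
    # independent evaluation of the j=18 candidate
    from cphit.families import coeff_sequence
    K = 3000
    cx = coeff_sequence(cfg.x_family, cfg.x_threshold, K + 1).values
    cz = coeff_sequence(cfg.z_family, cfg.z_threshold, K + 1).values
    u = (cx[:-1] - cx[1:]) * cz[:-1]
    v = (cz[:-1] - cz[1:]) * cx[1:]
    b18 = max(u[26:].max() / u[18], v[26:].max() / v[18])
    lam_tau = 40.0
    tail = math.exp(lam_tau) * stats.poisson.sf(25, lam_tau)
    expected = math.exp(math.lgamma(19) - 18 * math.log(lam_tau)) * b18 * tail
    assert np.isfinite(rb.per_j[18]) and rb.per_j[18] > 0
    assert rb.per_j[18] == pytest.approx(expected, rel=1e-6)
    assert rb.bound <= rb.bound_loose
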