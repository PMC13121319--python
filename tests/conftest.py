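import numpy as np
import pytest

from cphit import JumpFamily, ModelConfig, Theta, TruncationPolicy, reference_case


@pytest.fixture(scope="session")
def case_a():
    return reference_case("a")


@pytest.fixture(scope="session")
def case_b():
    return reference_case("b")


@pytest.fixture(scope="session")
def case_c():
    return reference_case("c")


@pytest.fixture(scope="session")
def erlang_model():
    """Both jumps degenerate at 1 with thresholds 1.5: T = C = E1 + E2, so
    every model function has an Erlang(2) closed form."""
    fam = JumpFamily.degenerate(1.0)
    config = ModelConfig(fam, fam, 1.5, 1.5, "I", TruncationPolicy(N=5))
    return Theta(0.9), config


def ks_distance(sorted_sample: np.ndarray, cdf_values: np.ndarray) -> float:
    """Two-sided Kolmogorov-Smirnov distance of a sorted sample against
    model CDF values evaluated at the sample points."""
    n = sorted_sample.size
    hi = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    return max(float(np.max(np.abs(hi - cdf_values))),
               float(np.max(np.abs(cdf_values - lo))))
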