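import numpy as np
import pytest

from psmpairs import ScenarioSpec, calibrate_scenario


def brute_force_greedy(logit_ps, Z, caliper, order):
    """Step-by-step replay of the greedy matching rule by exhaustive scan.

    Independent oracle: for each treated subject in the given order, scan
    every unmatched control, take the minimal absolute logit-PS distance
    (ties to the lower control index) and pair when within the caliper.
    """
    treated = np.flatnonzero(Z == 1)
    available = set(np.flatnonzero(Z == 0))
    pairs = []
    for t in treated[order]:
        best, best_d = None, np.inf
        for ctrl in sorted(available):
            d = abs(logit_ps[t] - logit_ps[ctrl])
            if d < best_d:
                best, best_d = ctrl, d
        if best is not None and best_d <= caliper:
            pairs.append((t, best))
            available.remove(best)
    return pairs


@pytest.fixture
def greedy_oracle():
    return brute_force_greedy


@pytest.fixture
def rng():
    return np.random.default_rng(20110221)


@pytest.fixture(scope="session")
def bernoulli_weak_null():
    """Calibrated independent-Bernoulli, weak-selection null cell.

    Calibrated once per session at a reduced sample size; shared by the
    harness and matching tests that need a realistic confounded cohort.
    """
    spec = ScenarioSpec("independent_bernoulli", "weak", 0.29, 0.0)
    coeffs = calibrate_scenario(spec, seed=11, m=200_000)
    return spec, coeffs


@pytest.fixture(scope="session")
def normal_strong_null():
    """Calibrated independent-normal, strong-selection null cell."""
    spec = ScenarioSpec("independent_normal", "strong", 0.29, 0.0)
    coeffs = calibrate_scenario(spec, seed=11, m=200_000)
    return spec, coeffs
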