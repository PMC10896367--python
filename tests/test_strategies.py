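import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matchsim.environments import ChoiceSituation, UtilityFunction, sample_situation
from matchsim.strategies import (
    StrategySpec,
    greedy_step,
    initial_allocation,
    matching_step,
    relative_utilities,
    run_strategy,
    sample_worth,
)


def test_initial_allocation_equal_is_exact():
    assert initial_allocation(4, "equal") == pytest.approx([0.25] * 4, abs=0)
    with pytest.raises(ValueError):
        initial_allocation(3, "sorted")
    with pytest.raises(ValueError):
        initial_allocation(1, "equal")


def test_random_initial_allocation_uniform_on_simplex(rng):
    draws = np.array([initial_allocation(3, "random", rng) for _ in range(10_000)])
    assert np.all(draws >= 0)
    assert draws.sum(axis=1) == pytest.approx(np.ones(len(draws)), abs=1e-12)
    # per-coordinate mean of the flat Dirichlet is 1/N; check within 3 s.e.
    se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
    assert np.all(np.abs(draws.mean(axis=0) - 1 / 3) < 3 * se)


def test_sample_worth_linear_options(two_linear):
    worth = sample_worth(two_linear, [0.5, 0.5])
    assert worth == pytest.approx([0.4, 0.2])
    assert sample_worth(two_linear, [1.0, 0.0])[1] == 0.0
    with pytest.raises(ValueError):
        sample_worth(two_linear, [0.5, 0.3, 0.2])


@pytest.mark.parametrize(
    "utilities, beta, expected",
    [
        ((0.4, 0.2), 1.0, (2 / 3, 1 / 3)),
        ((0.4, 0.2), 0.0, (0.5, 0.5)),
        ((0.4, 0.2), 20.0, (2**20 / (2**20 + 1), 1 / (2**20 + 1))),
    ],
)
def test_relative_utilities_analytic(utilities, beta, expected):
    assert relative_utilities(utilities, beta) == pytest.approx(expected, rel=1e-12)


def test_relative_utilities_edge_cases():
    with pytest.raises(ValueError):
        relative_utilities([-0.1, 0.5])
    with pytest.warns(UserWarning):
        out = relative_utilities([0.0, 0.0, 0.0])
    assert out == pytest.approx([1 / 3] * 3)
    # beta >> 1 must not underflow for small utilities
    tiny = relative_utilities([1e-8, 2e-8], 20.0)
    assert tiny[1] > 0.999999


def test_matching_step_hand_example(two_linear):
    """Worked 2-option linear case: 83.3% after one step, 90% after two."""
    e1 = matching_step(two_linear, [0.5, 0.5])
    assert e1 == pytest.approx([2 / 3, 1 / 3])
    assert two_linear.total_gain(e1) == pytest.approx(2 / 3, rel=1e-12)  # 83.3% of 0.8
    e2 = matching_step(two_linear, e1)
    assert e2 == pytest.approx([0.8, 0.2])
    assert two_linear.total_gain(e2) == pytest.approx(0.72)  # 90% of 0.8


def test_matching_fixed_point_for_identical_options():
    s = ChoiceSituation(tuple(UtilityFunction("hyperbolic", 0.5, 0.3) for _ in range(4)))
    e = matching_step(s, np.full(4, 0.25))
    assert e == pytest.approx([0.25] * 4, abs=1e-12)


def test_greedy_step_and_ties(two_linear):
    assert greedy_step(two_linear, [0.5, 0.5]) == pytest.approx([1.0, 0.0])
    tied = ChoiceSituation(tuple(UtilityFunction("power", 0.6, 1.0) for _ in range(3)))
    assert greedy_step(tied, np.full(3, 1 / 3)) == pytest.approx([1 / 3] * 3)


def test_run_strategy_trace_accounting(two_linear):
    trace = run_strategy(two_linear, "matching", 2, [0.5, 0.5])
    assert trace.strategy_label == "matching"
    assert trace.gains == pytest.approx([0.6, 2 / 3, 0.72])
    assert trace.allocations.shape == (3, 2)
    greedy = run_strategy(two_linear, "greedy", 4, [0.5, 0.5])
    assert np.all(greedy.gains[1:] == greedy.gains[1])  # idempotent after step 1


def test_strategy_spec_labels():
    assert StrategySpec("matching", 1.0).label == "matching"
    assert StrategySpec("matching", 0.0).label == "indifferent"
    assert StrategySpec("matching", 1.2).label == "generalized"
    assert StrategySpec("greedy").label == "greedy"
    with pytest.raises(ValueError):
        StrategySpec("softmax")


@settings(max_examples=100, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 10))
def test_allocations_stay_on_simplex(seed, n):
    """Conservation: every produced allocation sums to 1 with no negatives."""
    rng = np.random.default_rng(seed)
    s = sample_situation(n, rng)
    init = initial_allocation(n, "random", rng)
    for rule in ("matching", "greedy"):
        trace = run_strategy(s, rule, 3, init)
        assert np.all(trace.allocations >= 0)
        assert trace.allocations.sum(axis=1) == pytest.approx(
            np.ones(4), abs=1e-12
        )


@settings(max_examples=100, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_beta_monotonicity(seed):
    """The share of the best option is nondecreasing in beta."""
    rng = np.random.default_rng(seed)
    u = rng.random(5) + 1e-6
    best = int(np.argmax(u))
    shares = [relative_utilities(u, b)[best] for b in (0.0, 0.5, 1.0, 2.0, 5.0, 20.0)]
    assert np.all(np.diff(shares) >= -1e-12)


def test_beta_limits_reproduce_indifference_and_greed(rng):
    s = sample_situation(6, np.random.default_rng(55))
    e0 = initial_allocation(6, "random", rng)
    assert matching_step(s, e0, beta=0.0) == pytest.approx([1 / 6] * 6)
    worth = np.sort(sample_worth(s, e0))[::-1]
    # the beta=20 deviation from greedy is governed by the top-two ratio
    gap = (worth[1] / worth[0]) ** 20
    assert matching_step(s, e0, beta=20.0) == pytest.approx(
        greedy_step(s, e0), abs=max(1e-5, 5 * gap)
    )
    # with a clear 2:1 top-two ratio the greedy limit is reached at 1e-5
    assert relative_utilities([0.4, 0.2, 0.1], 20.0) == pytest.approx(
        [1.0, 0.0, 0.0], abs=1e-5
    )


def test_melioration_converges_to_power_fixed_point():
    """For power-only options with common alpha < 1, iterated matching
    converges to the analytic maximizer e_i proportional to U_m^(1/(1-alpha))."""
    alpha = 0.5
    um = np.array([0.9, 0.4, 0.1])
    s = ChoiceSituation(tuple(UtilityFunction("power", u, alpha) for u in um))
    target = um ** (1 / (1 - alpha))
    target = target / target.sum()
    e = np.full(3, 1 / 3)
    for _ in range(200):
        e = matching_step(s, e)
    assert e == pytest.approx(target, abs=1e-6)
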