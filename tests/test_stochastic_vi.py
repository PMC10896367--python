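import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize

from matchsim.stochastic_vi import (
    DiscountingParams,
    VISituation,
    estimate_utilities,
    expected_gain,
    generate_vi_grid,
    run_vi_strategy,
    sample_vi_situation,
    simulate_window,
    solve_vi_optimum,
    vi_expected_rate,
    vi_grid_to_frame,
    WindowEvents,
)


def test_discount_kernel_integrates_to_one():
    p = DiscountingParams(T=400.0)
    assert p.gamma == pytest.approx(3.0 / 400.0)
    val, _ = quad(lambda t: p.A * np.exp(-p.gamma * t), 0.0, p.T)
    assert val == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize(
    "r, e, expected",
    [(0.5, 0.5, 0.25), (0.7, 0.0, 0.0), (0.0, 0.0, 0.0)],
)
def test_vi_expected_rate_closed_form(r, e, expected):
    assert vi_expected_rate(r, e) == pytest.approx(expected)
    assert vi_expected_rate(r, e) == vi_expected_rate(e, r)  # symmetric
    with pytest.raises(ValueError):
        vi_expected_rate(-0.1, 0.5)


def test_simulate_window_basic_laws(rng):
    p = DiscountingParams()
    s = VISituation(np.array([0.5, 0.3]))
    ev = simulate_window(s, [1.0, 0.0], p, rng)
    assert len(ev.harvest_times[1]) == 0  # zero effort -> zero harvests
    # expected bait count over one window is r*T
    counts = [len(simulate_window(s, [0.5, 0.5], p, rng).bait_times[0]) for _ in range(200)]
    mean, se = np.mean(counts), np.std(counts, ddof=1) / np.sqrt(200)
    assert abs(mean - 0.5 * p.T) < 4 * se
    # a collected reward requires a pending bait before the harvest
    ev = simulate_window(s, [0.5, 0.5], p, rng)
    for i in range(2):
        assert np.all(np.isin(ev.reward_times[i], ev.harvest_times[i]))


def test_collection_rate_matches_alternating_renewal(rng):
    """Empirical reward-collection rate approaches r*e/(r+e)."""
    p = DiscountingParams()
    s = VISituation(np.array([0.5, 0.2]))
    alloc = np.array([0.5, 0.5])
    baited = s.fresh_baited()
    counts = []
    for _ in range(300):
        ev = simulate_window(s, alloc, p, rng, baited)
        baited = ev.baited_end
        counts.append([len(t) / p.T for t in ev.reward_times])
    counts = np.array(counts)
    target = vi_expected_rate(s.rates, alloc)
    se = counts.std(axis=0, ddof=1) / np.sqrt(len(counts))
    assert np.all(np.abs(counts.mean(axis=0) - target) < 3 * se)


def test_estimate_utilities_values_and_consistency(rng):
    p = DiscountingParams()
    empty = WindowEvents([np.array([])] * 2, [np.array([])] * 2, [np.array([])] * 2)
    assert estimate_utilities(empty, p) == pytest.approx([0.0, 0.0])
    one = WindowEvents(
        [np.array([])], [np.array([])], [np.array([p.T])]
    )
    assert estimate_utilities(one, p)[0] == pytest.approx(p.A)  # e^0 = 1
    # unbiased rate estimate under a held allocation
    s = VISituation(np.array([0.6, 0.3]))
    alloc = np.array([0.4, 0.6])
    baited = s.fresh_baited()
    ests = []
    for _ in range(400):
        ev = simulate_window(s, alloc, p, rng, baited)
        baited = ev.baited_end
        ests.append(estimate_utilities(ev, p))
    ests = np.array(ests)
    target = vi_expected_rate(s.rates, alloc)
    se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
    assert np.all(np.abs(ests.mean(axis=0) - target) < 3 * se)


def test_vi_optimum_against_grid_search_and_probes(rng):
    s = VISituation(np.array([0.8, 0.25]))
    opt = solve_vi_optimum(s)
    e1 = np.linspace(0.0, 1.0, 100_001)
    grid_best = (vi_expected_rate(s.rates[0], e1) + vi_expected_rate(s.rates[1], 1 - e1)).max()
    assert opt.gain_star == pytest.approx(grid_best, abs=1e-6)
    # symmetric rates -> equal split
    sym = VISituation(np.array([0.4, 0.4]))
    assert solve_vi_optimum(sym).e_star == pytest.approx([0.5, 0.5])
    # never beaten by random simplex probes
    s10 = sample_vi_situation(10, rng)
    opt10 = solve_vi_optimum(s10)
    probes = rng.dirichlet(np.ones(10), size=1000)
    gains = np.array([expected_gain(s10, p_) for p_ in probes])
    assert np.all(gains <= opt10.gain_star + 1e-12)


def test_vi_optimum_against_constrained_solver():
    """Independent route: scipy SLSQP on the expected-rate objective."""
    s = VISituation(np.array([0.9, 0.5, 0.1, 0.3]))
    res = minimize(
        lambda e: -float(np.sum(vi_expected_rate(s.rates, np.clip(e, 0, None)))),
        np.full(4, 0.25),
        method="SLSQP",
        bounds=[(0, 1)] * 4,
        constraints=[{"type": "eq", "fun": lambda e: e.sum() - 1}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    opt = solve_vi_optimum(s)
    assert -res.fun == pytest.approx(opt.gain_star, abs=1e-8)
    assert res.x == pytest.approx(opt.e_star, abs=1e-4)


def test_noise_free_matching_converges_near_vi_optimum():
    """Iterating e ~ expected income is melioration on a hyperbolic
    (diminishing-returns) contingency; it must land near the optimum."""
    rng = np.random.default_rng(31)
    for _ in range(20):
        s = sample_vi_situation(int(rng.integers(2, 11)), rng)
        opt = solve_vi_optimum(s)
        e = rng.dirichlet(np.ones(s.n))
        for _ in range(10):
            inc = vi_expected_rate(s.rates, e)
            e = inc / inc.sum()
        assert expected_gain(s, e) / opt.gain_star >= 0.95


def test_run_vi_strategy_trace_and_determinism():
    p = DiscountingParams()
    s = VISituation(np.array([0.7, 0.2, 0.4]), situation_id="vi-test")
    init = np.array([0.2, 0.5, 0.3])
    t1 = run_vi_strategy(s, "matching", 3, init, np.random.default_rng(5), p)
    t2 = run_vi_strategy(s, "matching", 3, init, np.random.default_rng(5), p)
    assert t1.gains == pytest.approx(t2.gains, abs=0)
    assert t1.allocations.shape == (4, 3)
    assert t1.gains[0] == pytest.approx(expected_gain(s, init))
    assert np.all(t1.allocations >= 0)
    assert t1.allocations.sum(axis=1) == pytest.approx(np.ones(4), abs=1e-12)
    g = run_vi_strategy(s, "greedy", 2, init, np.random.default_rng(5), p)
    assert np.all(np.isclose(g.allocations[1:].max(axis=1), 1.0))


def test_vi_maximization_budget_accounting():
    p = DiscountingParams(T=100.0)
    s = VISituation(np.array([0.6, 0.3]))
    trace = run_vi_strategy(s, "maximization", 20, np.array([0.5, 0.5]),
                            np.random.default_rng(2), p)
    assert len(trace.gains) == 21
    assert trace.strategy_label == "maximization"


def test_vi_grid_generation_and_serialization():
    grid = generate_vi_grid(3, n_range=[2, 5], master_seed=8)
    assert len(grid) == 6
    assert all(0 < r < 1 for s in grid for r in s.rates)
    again = generate_vi_grid(3, n_range=[2, 5], master_seed=8)
    assert all(np.array_equal(a.rates, b.rates) for a, b in zip(grid, again))
    frame = vi_grid_to_frame(grid)
    assert len(frame) == sum(s.n for s in grid)
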