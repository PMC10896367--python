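"""Concurrent variable-interval (VI) schedules with Poisson baiting.

In a VI schedule a binary reward is armed ("baited") on option i at the
events of a Poisson process with rate r_i, and held until the next
harvest response collects it; further baits on an already-baited option
are ignored.  Harvest responses on option i are themselves Poisson at
the rate of the effort e_i devoted to that option.  Holding a baited
reward makes income saturate in response rate: the long-run collection
rate is the alternating-renewal expression

    rate(r, e) = r * e / (r + e)        (mean cycle = 1/r + 1/e),

which is hyperbolic in e, i.e. a stochastic diminishing-returns
contingency.

The decision-maker never observes the rates.  Over a window of length T
it integrates the binary rewards it collected with an exponentially
discounting kernel A*exp(-gamma*t), t = time elapsed since the reward,
gamma = 3/T, with A chosen so the kernel integrates to one over the
window -- making the estimate an unbiased reward-rate estimate under a
constant collection rate.  Each option evaluation operates on one fresh
window; the baited state carries across consecutive windows of a
situation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .environments import DEFAULT_N_RANGE, situation_rng
from .maximization import OptimumResult, _project_to_simplex
from .strategies import StrategySpec, StrategyTrace, relative_utilities


@dataclass(frozen=True)
class DiscountingParams:
    """Exponential-discounting reward integration over a window of length T."""

    T: float = 400.0

    @property
    def gamma(self) -> float:
        """Learning rate, tied to the integration period: gamma = 3/T."""
        return 3.0 / self.T

    @property
    def A(self) -> float:
        """Normalizer making the kernel integrate to one over [0, T]."""
        g = self.gamma
        return g / (1.0 - np.exp(-g * self.T))


@dataclass
class VISituation:
    """N variable-interval options with Poisson baiting rates r_i in (0, 1)."""

    rates: np.ndarray
    situation_id: str = ""
    rng_seed: tuple[int, int] | int | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.rates) < 2:
            raise ValueError("a VI situation needs at least 2 options")
        if np.any(self.rates <= 0) or np.any(self.rates >= 1):
            raise ValueError("reward rates must lie in (0, 1)")

    @property
    def n(self) -> int:
        return len(self.rates)

    def fresh_baited(self) -> np.ndarray:
        return np.zeros(self.n, dtype=bool)


@dataclass
class WindowEvents:
    """Per-option event times within one window [0, T]."""

    bait_times: list[np.ndarray]
    harvest_times: list[np.ndarray]
    reward_times: list[np.ndarray]  # harvest events that collected a reward
    baited_end: np.ndarray = field(default=None)  # schedule state at window end


def _poisson_times(rate: float, T: float, rng: np.random.Generator) -> np.ndarray:
    k = rng.poisson(rate * T) if rate > 0 else 0
    return np.sort(rng.uniform(0.0, T, size=k))


def simulate_window(
    situation: VISituation,
    allocation,
    params: DiscountingParams,
    rng: np.random.Generator,
    baited: np.ndarray | None = None,
) -> WindowEvents:
    """Event-driven simulation of one window under a fixed allocation.

    Bait events latch the option (one pending reward; extra baits are
    ignored); a harvest event on a baited option collects the reward and
    clears the latch.  ``baited`` is the latch state entering the window;
    the state at the window end is returned in ``WindowEvents.baited_end``.
    """
    e = np.asarray(allocation, dtype=float)
    if e.shape != (situation.n,):
        raise ValueError("allocation length does not match the situation")
    state = situation.fresh_baited() if baited is None else np.asarray(baited, bool)
    bait_times, harvest_times, reward_times = [], [], []
    baited_end = np.empty(situation.n, dtype=bool)
    for i in range(situation.n):
        baits = _poisson_times(situation.rates[i], params.T, rng)
        harvests = _poisson_times(e[i], params.T, rng)
        # A latch set before the window behaves like a bait at time 0-.
        pending = np.concatenate(([-1.0], baits)) if state[i] else baits
        # First harvest strictly after each bait; baits sharing that harvest
        # land on an already-latched option and are ignored, so the collected
        # rewards are exactly the unique first-harvest indices.
        first_harvest = np.searchsorted(harvests, pending, side="left")
        collected_idx = np.unique(first_harvest[first_harvest < len(harvests)])
        bait_times.append(baits)
        harvest_times.append(harvests)
        reward_times.append(harvests[collected_idx])
        baited_end[i] = bool(np.any(first_harvest == len(harvests)))
    return WindowEvents(bait_times, harvest_times, reward_times, baited_end)


def estimate_utilities(events: WindowEvents, params: DiscountingParams) -> np.ndarray:
    """Discounted reward-rate estimate per option from one window.

    U_hat_i = sum over collected rewards of A*exp(-gamma*(T - t_r)); the
    most recent rewards weigh the most, and a constant collection rate rho
    yields E[U_hat] = rho.
    """
    g, A, T = params.gamma, params.A, params.T
    return np.array(
        [A * np.exp(-g * (T - t)).sum() for t in events.reward_times]
    )


def vi_expected_rate(r, e):
    """Long-run reward-collection rate r*e/(r+e); 0 when both rates are 0."""
    r = np.asarray(r, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(r < 0) or np.any(e < 0):
        raise ValueError("rates must be nonnegative")
    denom = r + e
    out = np.divide(r * e, denom, out=np.zeros_like(denom), where=denom > 0)
    return float(out) if out.ndim == 0 else out


def expected_gain(situation: VISituation, allocation) -> float:
    """Expected total collection rate of an allocation."""
    return float(np.sum(vi_expected_rate(situation.rates, allocation)))


def solve_vi_optimum(situation: VISituation) -> OptimumResult:
    """Analytic maximizer of the expected collection rate on the simplex.

    Stationarity requires the marginal rate r_i^2/(r_i + e_i)^2 to be
    equal across options; since the marginal at e_i = 0 equals 1 for
    every option, all options are interior and e*_i = r_i / sum_j r_j,
    giving gain* = S/(S+1) with S = sum_j r_j.
    """
    S = float(situation.rates.sum())
    e_star = situation.rates / S
    return OptimumResult(
        e_star=e_star,
        gain_star=S / (S + 1.0),
        converged=True,
        n_evaluations_used=0,
    )


def sample_vi_situation(
    n_options: int,
    rng: np.random.Generator,
    situation_id: str = "",
    rng_seed=None,
) -> VISituation:
    if n_options < 2:
        raise ValueError("n_options must be at least 2")
    # rates ~ Uniform(0,1); nudge off the measure-zero boundary r = 0
    rates = np.maximum(rng.random(n_options), 1e-12)
    return VISituation(rates, situation_id=situation_id, rng_seed=rng_seed)


def generate_vi_grid(
    reps_per_n: int,
    n_range: Iterable[int] = DEFAULT_N_RANGE,
    master_seed: int = 0,
) -> list[VISituation]:
    """Randomized VI grid: ``reps_per_n`` rate vectors per option count."""
    if reps_per_n < 1:
        raise ValueError("reps_per_n must be at least 1")
    grid = []
    for index, (n, rep) in enumerate(itertools.product(n_range, range(reps_per_n))):
        rng = situation_rng(master_seed, index)
        grid.append(
            sample_vi_situation(
                n,
                rng,
                situation_id=f"vi{master_seed}-n{n}-r{rep}",
                rng_seed=(master_seed, index),
            )
        )
    return grid


def vi_grid_to_frame(grid: list[VISituation]) -> pd.DataFrame:
    rows = []
    for s in grid:
        seed = "" if s.rng_seed is None else ":".join(map(str, np.atleast_1d(s.rng_seed)))
        for j, r in enumerate(s.rates):
            rows.append(
                {"situation_id": s.situation_id, "N": s.n, "option_index": j,
                 "rate": r, "seed": seed}
            )
    return pd.DataFrame(rows)


def run_vi_strategy(
    situation: VISituation,
    rule: StrategySpec | str,
    n_evaluations: int,
    init,
    rng: np.random.Generator,
    params: DiscountingParams = DiscountingParams(),
) -> StrategyTrace:
    """Run a strategy in the stochastic environment.

    Per evaluation: simulate one window under the current allocation,
    estimate option worth by exponential discounting, then reallocate.
    ``gains[k]`` is the *expected* collection rate of the allocation after
    k evaluations (harvest noise enters the decision through the estimate,
    not the score); ``gains[0]`` scores the initial allocation.

    For ``rule='maximization'`` the constrained optimizer receives one
    noisy objective value (realized rewards per unit time) per window,
    finite-difference gradient queries included, for ``n_evaluations``
    windows in total.
    """
    if isinstance(rule, str) and rule == "maximization":
        return _run_vi_maximization(situation, n_evaluations, init, rng, params)
    if isinstance(rule, str):
        rule = StrategySpec(rule=rule)
    if n_evaluations < 1:
        raise ValueError("n_evaluations must be at least 1")
    e = np.asarray(init, dtype=float)
    baited = situation.fresh_baited()
    allocations = [e]
    gains = [expected_gain(situation, e)]
    for _ in range(n_evaluations):
        events = simulate_window(situation, e, params, rng, baited)
        baited = events.baited_end
        worth = estimate_utilities(events, params)
        if rule.rule == "greedy":
            best = worth == worth.max()
            e = best / best.sum()
        else:
            e = relative_utilities(worth, rule.beta)
        allocations.append(e)
        gains.append(expected_gain(situation, e))
    return StrategyTrace(np.array(allocations), np.array(gains), rule.label)


class _WindowBudgetExhausted(Exception):
    pass


def _run_vi_maximization(situation, n_windows, init, rng, params):
    from scipy.optimize import minimize

    baited = situation.fresh_baited()
    allocations = [np.asarray(init, dtype=float)]
    gains = [expected_gain(situation, init)]

    def neg_income(x):
        nonlocal baited
        p = _project_to_simplex(np.asarray(x, dtype=float))
        events = simulate_window(situation, p, params, rng, baited)
        baited = events.baited_end
        realized = sum(len(t) for t in events.reward_times) / params.T
        allocations.append(p)
        gains.append(expected_gain(situation, p))
        if len(gains) > n_windows:
            raise _WindowBudgetExhausted
        return -realized

    # a noisy objective makes the optimizer terminate early; keep
    # restarting from the latest iterate until the window budget is spent
    try:
        while len(gains) <= n_windows:
            minimize(
                neg_income,
                allocations[-1],
                method="SLSQP",
                bounds=[(0.0, 1.0)] * situation.n,
                constraints=[{"type": "eq", "fun": lambda e: e.sum() - 1.0}],
                # wide finite-difference step: differences must straddle the
                # harvest noise of single windows to carry gradient signal
                options={"ftol": 1e-12, "maxiter": 10_000, "eps": 0.05},
            )
    except _WindowBudgetExhausted:
        pass
    return StrategyTrace(np.array(allocations), np.array(gains), "maximization")
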