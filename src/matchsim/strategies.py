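"""Effort-allocation rules: matching, generalized matching, greedy.

A decision-maker distributes a unit effort budget across N options (a
point on the N-simplex).  One "option evaluation" is a single sampling
pass: the worth U_i(e_i) of every option is queried at the current
allocation, after which effort is reallocated.

Strict matching sets the new relative effort equal to the relative
utility, e_i = u_i with u_i = U_i / sum_n U_n.  Generalized matching
exponentiates the utilities first, u_i = U_i**beta / sum_n U_n**beta:
beta < 1 is undermatching (toward indifference), beta > 1 overmatching,
and the beta >> 1 limit is the greedy rule (all effort on the option
that appeared richest).  Repeated application of the matching rule,
e_next = u(e_prev), is melioration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .environments import ChoiceSituation

INIT_MODES = ("equal", "random")


@dataclass(frozen=True)
class StrategySpec:
    """Reallocation rule: ``matching`` (with exponent beta) or ``greedy``."""

    rule: str = "matching"
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.rule not in ("matching", "greedy"):
            raise ValueError(f"unknown strategy rule {self.rule!r}")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")

    @property
    def label(self) -> str:
        if self.rule == "greedy":
            return "greedy"
        if self.beta == 0:
            return "indifferent"
        return "matching" if self.beta == 1 else "generalized"


@dataclass
class StrategyTrace:
    """Allocations and gains over evaluations k = 0..K (k=0 is the init)."""

    allocations: np.ndarray  # (K+1, N)
    gains: np.ndarray  # (K+1,)
    strategy_label: str

    def __post_init__(self) -> None:
        assert len(self.gains) == len(self.allocations)


def initial_allocation(
    n_options: int, mode: str = "equal", rng: np.random.Generator | None = None
) -> np.ndarray:
    """Initial sampling allocation: exactly equal, or uniform on the simplex.

    "Entirely random" initial effort is read as the flat Dirichlet, the
    maximum-entropy distribution on the simplex, symmetric in the options.
    """
    if n_options < 2:
        raise ValueError("n_options must be at least 2")
    if mode == "equal":
        return np.full(n_options, 1.0 / n_options)
    if mode == "random":
        if rng is None:
            raise ValueError("random initial allocation requires an rng")
        return rng.dirichlet(np.ones(n_options))
    raise ValueError(f"unknown initial-allocation mode {mode!r}")


def sample_worth(situation: ChoiceSituation, allocation) -> np.ndarray:
    """One evaluation of the options: U_i(e_i) at the current allocation."""
    e = np.asarray(allocation, dtype=float)
    if e.shape != (situation.n,):
        raise ValueError("allocation length does not match the situation")
    return situation.utilities(e)


def relative_utilities(utilities, beta: float = 1.0) -> np.ndarray:
    """Divisively normalized utilities u_i = U_i**beta / sum_n U_n**beta.

    beta = 0 is the indifference limit (equal shares).  If every sampled
    utility is zero the normalization is undefined; equal shares are
    returned with a warning.
    """
    u = np.asarray(utilities, dtype=float)
    if np.any(u < 0):
        raise ValueError("utilities must be nonnegative")
    n = len(u)
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    if beta == 0:
        return np.full(n, 1.0 / n)
    top = u.max()
    if top == 0:
        warnings.warn("all sampled utilities are zero; falling back to equal shares")
        return np.full(n, 1.0 / n)
    w = (u / top) ** beta  # rescale before powering so beta >> 1 cannot underflow
    return w / w.sum()


def matching_step(
    situation: ChoiceSituation, e_prev, beta: float = 1.0
) -> np.ndarray:
    """One melioration step: e_next = u(e_prev); consumes one evaluation."""
    return relative_utilities(sample_worth(situation, e_prev), beta)


def greedy_step(situation: ChoiceSituation, e_prev) -> np.ndarray:
    """All effort on the sampled-richest option (ties split equally)."""
    worth = sample_worth(situation, e_prev)
    best = worth == worth.max()
    return best / best.sum()


def run_strategy(
    situation: ChoiceSituation,
    rule: StrategySpec | str,
    n_evaluations: int,
    init,
) -> StrategyTrace:
    """Apply a rule for ``n_evaluations`` steps from ``init``.

    ``gains[k]`` is the total utility of the allocation after k rule
    applications; ``gains[0]`` is the gain of the initial allocation.
    """
    if isinstance(rule, str):
        rule = StrategySpec(rule=rule)
    if n_evaluations < 1:
        raise ValueError("n_evaluations must be at least 1")
    e = np.asarray(init, dtype=float)
    allocations = [e]
    gains = [situation.total_gain(e)]
    for _ in range(n_evaluations):
        if rule.rule == "greedy":
            e = greedy_step(situation, e)
        else:
            e = matching_step(situation, e, rule.beta)
        allocations.append(e)
        gains.append(situation.total_gain(e))
    return StrategyTrace(np.array(allocations), np.array(gains), rule.label)
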