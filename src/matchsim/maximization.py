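"""Constrained reward maximization on the effort simplex.

The maximizer solves  max sum_n U_n(E_n)  s.t.  sum_n E_n = 1, E_n >= 0.
Every sampled utility family is concave and increasing on [0, 1], so the
optimum is global; its gain is the 100% denominator against which every
strategy's performance is normalized.

The budgeted variant counts decision time: each query of the situation's
utility functions at one candidate allocation -- including queries the
optimizer spends on finite-difference derivative estimation -- is one
"option evaluation" (one visit to every patch).  It records the best
feasible gain found after each evaluation, which is what the matching
strategy's single-evaluation performance is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

DEFAULT_EVALUATION_CAP = 10_000


@dataclass
class OptimumResult:
    e_star: np.ndarray
    gain_star: float
    converged: bool
    n_evaluations_used: int


@dataclass
class MaximizationTrace:
    """Entry k-1 is the best feasible gain found after k option evaluations."""

    best_gain_by_evaluation: np.ndarray


class _BudgetExhausted(Exception):
    pass


def _project_to_simplex(e: np.ndarray) -> np.ndarray:
    p = np.clip(e, 0.0, None)
    s = p.sum()
    if s == 0:
        return np.full(len(p), 1.0 / len(p))
    return p / s


def solve_optimum(situation, tol: float = 1e-12) -> OptimumResult:
    """Converged simplex-constrained maximum of the total gain.

    Sequential least-squares (SLSQP) with analytic gradients from an
    equal-allocation start; concavity makes the solution global.
    """
    n = situation.n
    x0 = np.full(n, 1.0 / n)

    def neg_gain(e):
        return -situation.total_gain(np.clip(e, 0.0, None))

    def neg_grad(e):
        return -situation.marginal_utilities(np.clip(e, 0.0, None))

    res = minimize(
        neg_gain,
        x0,
        jac=neg_grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda e: e.sum() - 1.0,
                      "jac": lambda e: np.ones(n)}],
        options={"ftol": tol, "maxiter": 1000},
    )
    e_star = _project_to_simplex(res.x)
    return OptimumResult(
        e_star=e_star,
        gain_star=situation.total_gain(e_star),
        converged=bool(res.success),
        n_evaluations_used=int(res.nfev),
    )


def budgeted_maximize(
    situation, init, max_evaluations: int = DEFAULT_EVALUATION_CAP
) -> MaximizationTrace:
    """Run the constrained maximizer under an evaluation budget.

    Gradients are estimated by forward differences so that derivative
    queries consume evaluations exactly like any other candidate query.
    The trace stores, after each evaluation, the gain of the best
    simplex-feasible allocation seen so far (off-simplex finite-difference
    probes are projected before scoring).
    """
    if max_evaluations < 1:
        raise ValueError("max_evaluations must be at least 1")
    n = situation.n
    best = -np.inf
    trace: list[float] = []

    def neg_gain(e):
        nonlocal best
        feasible_gain = situation.total_gain(_project_to_simplex(e))
        best = max(best, feasible_gain)
        trace.append(best)
        if len(trace) >= max_evaluations:
            raise _BudgetExhausted
        return -situation.total_gain(np.clip(e, 0.0, None))

    try:
        minimize(
            neg_gain,
            np.asarray(init, dtype=float),
            method="SLSQP",
            bounds=[(0.0, 1.0)] * n,
            constraints=[{"type": "eq", "fun": lambda e: e.sum() - 1.0,
                          "jac": lambda e: np.ones(n)}],
            options={"ftol": 1e-12, "maxiter": 1000},
        )
    except _BudgetExhausted:
        pass
    return MaximizationTrace(best_gain_by_evaluation=np.array(trace))


def evaluations_to_reach(trace: MaximizationTrace, target_gain: float) -> int | None:
    """Smallest evaluation count whose best-so-far gain reaches the target.

    Counts are 1-based (entry 0 of the trace is reached after one
    evaluation).  Returns None if the target is never reached within the
    recorded budget.
    """
    if target_gain < 0:
        raise ValueError("target gain must be nonnegative")
    hits = np.nonzero(trace.best_gain_by_evaluation >= target_gain)[0]
    if len(hits) == 0:
        return None
    return int(hits[0]) + 1
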