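"""Experiment grid orchestration: normalization, sweeps, ANOVA, summaries.

Every strategy's gain is first converted to a percentage of the
situation's own converged constrained optimum, then averaged across
situations; raw gains are never averaged across situations because the
magnitudes U_m differ between them.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import environments, maximization, stochastic_vi, strategies
from .environments import ALPHA_GRID, ChoiceSituation, generate_grid
from .maximization import budgeted_maximize, evaluations_to_reach, solve_optimum
from .stochastic_vi import (
    DiscountingParams,
    expected_gain,
    generate_vi_grid,
    run_vi_strategy,
    solve_vi_optimum,
)
from .strategies import StrategySpec, initial_allocation, run_strategy, sample_worth

log = logging.getLogger("matchsim")

DEFAULT_BETA_GRID = tuple(np.round(np.arange(0.0, 3.01, 0.1), 1)) + (5.0, 10.0, 20.0)


@dataclass
class AnovaResult:
    """Two-way fixed-effects ANOVA: evaluation number I x init distribution D."""

    table: pd.DataFrame
    f_iteration: float
    f_mode: float
    f_interaction: float
    p_iteration: float
    p_mode: float
    p_interaction: float
    df_iteration: int
    df_mode: int
    df_interaction: int
    df_resid: int
    n_obs: int


def normalize_gain(gain, optimum):
    """Gain as percent of the situation's maximum, clipped to [0, 100+1e-6]."""
    optimum = np.asarray(optimum, dtype=float)
    if np.any(optimum <= 0):
        raise ValueError("optimum must be positive")
    pct = 100.0 * np.asarray(gain, dtype=float) / optimum
    out = np.clip(pct, 0.0, 100.0 + 1e-6)
    return float(out) if out.ndim == 0 else out


def summarize(frame: pd.DataFrame, by: Sequence[str], value: str = "pct") -> pd.DataFrame:
    """Mean and s.e.m. (= sd/sqrt(n), sd with n-1 denominator) per group."""
    if frame.empty:
        raise ValueError("cannot summarize an empty table")
    g = frame.groupby(list(by), sort=True, observed=True)[value]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n_situations="count")
    out["sem"] = (out.pop("sd") / np.sqrt(out["n_situations"])).fillna(0.0)
    return out.reset_index()[list(by) + ["mean", "sem", "n_situations"]]


def solve_grid_optima(
    situations: Sequence[ChoiceSituation],
) -> tuple[np.ndarray, list[int]]:
    """Per-situation optimum gains; non-converged solves are flagged for exclusion."""
    gains = np.empty(len(situations))
    excluded = []
    for i, s in enumerate(situations):
        opt = solve_optimum(s)
        gains[i] = opt.gain_star
        if not opt.converged:
            excluded.append(i)
    if excluded:
        log.warning("excluding %d non-converged situations", len(excluded))
    return gains, excluded


def _keep(situations, optima, excluded):
    if not excluded:
        return list(situations), optima
    mask = np.ones(len(situations), dtype=bool)
    mask[excluded] = False
    return [s for s, k in zip(situations, mask) if k], optima[mask]


def run_convergence_experiment(
    situations: Sequence[ChoiceSituation],
    max_evaluations: int = 200,
    n_matching_evaluations: int = 4,
    optima: np.ndarray | None = None,
) -> dict:
    """Matching vs budgeted maximization over evaluation count.

    Both start from the equal allocation.  Reports per-evaluation mean
    normalized gain for each strategy and the mean number of evaluations
    the maximizer needs to reach matching's single-evaluation gain.
    """
    if optima is None:
        optima, excluded = solve_grid_optima(situations)
        situations, optima = _keep(situations, optima, excluded)
    rows = []
    crossings = []
    n_unreached = 0
    max_curves = np.empty((len(situations), max_evaluations))
    for i, (s, opt) in enumerate(zip(situations, optima)):
        init = initial_allocation(s.n, "equal")
        trace = run_strategy(s, "matching", n_matching_evaluations, init)
        for k, gain in enumerate(trace.gains):
            rows.append(
                {"situation_id": s.situation_id, "N": s.n, "strategy": "matching",
                 "evaluation": k, "pct": normalize_gain(gain, opt)}
            )
        mtrace = budgeted_maximize(s, init, max_evaluations)
        curve = mtrace.best_gain_by_evaluation
        # a converged optimizer holds its best allocation for the rest of the budget
        padded = np.concatenate([curve, np.full(max_evaluations - len(curve), curve[-1])])
        max_curves[i] = normalize_gain(padded, opt)
        k_cross = evaluations_to_reach(mtrace, trace.gains[1])
        if k_cross is None:
            n_unreached += 1
        else:
            crossings.append(k_cross)
    match_df = pd.DataFrame(rows)
    n_sit = len(situations)
    max_sem = (
        max_curves.std(axis=0, ddof=1) / np.sqrt(n_sit) if n_sit > 1 else np.zeros(max_evaluations)
    )
    max_df = pd.DataFrame(
        {
            "strategy": "maximization",
            "evaluation": np.arange(1, max_evaluations + 1),
            "mean": max_curves.mean(axis=0),
            "sem": max_sem,
            "n_situations": n_sit,
        }
    )
    summary = pd.concat(
        [summarize(match_df, ["strategy", "evaluation"]), max_df], ignore_index=True
    )
    return {
        "summary": summary,
        "mean_evaluations_to_match": float(np.mean(crossings)) if crossings else np.nan,
        "n_unreached": n_unreached,
        "per_situation_matching": match_df,
    }


def run_beta_sweep(
    situations: Sequence[ChoiceSituation],
    beta_grid: Iterable[float] = DEFAULT_BETA_GRID,
    optima: np.ndarray | None = None,
) -> pd.DataFrame:
    """Single-evaluation generalized matching per exponent beta (equal init)."""
    if optima is None:
        optima, excluded = solve_grid_optima(situations)
        situations, optima = _keep(situations, optima, excluded)
    beta_grid = list(beta_grid)
    rows = []
    for s, opt in zip(situations, optima):
        worth = sample_worth(s, initial_allocation(s.n, "equal"))
        for beta in beta_grid:
            e = strategies.relative_utilities(worth, beta)
            rows.append(
                {"situation_id": s.situation_id, "N": s.n, "beta": beta,
                 "pct": normalize_gain(s.total_gain(e), opt)}
            )
    return summarize(pd.DataFrame(rows), ["beta"])


def melioration_table(
    situations: Sequence[ChoiceSituation],
    optima: np.ndarray,
    n_iterations: int,
    init_mode: str,
    seed: int = 0,
    rule: StrategySpec | str = "matching",
) -> pd.DataFrame:
    """Long table of normalized gains per situation and evaluation 0..K.

    For random initial sampling, the simplex draw for situation i is taken
    from the child stream (seed, i), so repeated calls with the same seed
    pair the draws across strategies and experiments.
    """
    rows = []
    for i, (s, opt) in enumerate(zip(situations, optima)):
        rng = environments.situation_rng(seed, i)
        init = initial_allocation(s.n, init_mode, rng)
        trace = run_strategy(s, rule, n_iterations, init)
        label = trace.strategy_label
        for k, gain in enumerate(trace.gains):
            rows.append(
                {"situation_id": s.situation_id, "N": s.n, "strategy": label,
                 "init_mode": init_mode, "evaluation": k,
                 "pct": normalize_gain(gain, opt)}
            )
    return pd.DataFrame(rows)


def anova_init_mode(raw: pd.DataFrame) -> AnovaResult:
    """Two-way ANOVA on normalized gain: iteration (I) x init mode (D)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = raw[raw["evaluation"] >= 1]
    model = ols("pct ~ C(evaluation) * C(init_mode)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    it, md = "C(evaluation)", "C(init_mode)"
    inter = f"{it}:{md}"
    return AnovaResult(
        table=table,
        f_iteration=float(table.loc[it, "F"]),
        f_mode=float(table.loc[md, "F"]),
        f_interaction=float(table.loc[inter, "F"]),
        p_iteration=float(table.loc[it, "PR(>F)"]),
        p_mode=float(table.loc[md, "PR(>F)"]),
        p_interaction=float(table.loc[inter, "PR(>F)"]),
        df_iteration=int(table.loc[it, "df"]),
        df_mode=int(table.loc[md, "df"]),
        df_interaction=int(table.loc[inter, "df"]),
        df_resid=int(table.loc["Residual", "df"]),
        n_obs=len(df),
    )


def run_initmode_experiment(
    situations: Sequence[ChoiceSituation],
    n_iterations: int = 4,
    seed: int = 0,
    optima: np.ndarray | None = None,
) -> dict:
    """Melioration over 1..K evaluations under equal vs random initial sampling."""
    if optima is None:
        optima, excluded = solve_grid_optima(situations)
        situations, optima = _keep(situations, optima, excluded)
    raw = pd.concat(
        [
            melioration_table(situations, optima, n_iterations, "equal", seed),
            melioration_table(situations, optima, n_iterations, "random", seed),
        ],
        ignore_index=True,
    )
    steps = raw[raw["evaluation"] >= 1]
    return {
        "summary": summarize(steps, ["init_mode", "evaluation"]),
        "anova": anova_init_mode(raw),
        "raw": raw,
    }


def _exp_decay(n, a, b, c):
    return a + b * np.exp(-c * n)


def fit_exponential_decay(ns: np.ndarray, means: np.ndarray) -> dict:
    """Least-squares fit gain(N) = a + b*exp(-c*N).

    The reported "decay per option" is the mean absolute successive
    difference of the fitted curve over the N grid -- a descriptive
    summary of how fast performance falls as options are added.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    span = means.max() - means.min()
    p0 = (means[-1], (means[0] - means[-1]) * np.exp(0.3 * ns[0]), 0.3)
    try:
        popt, _ = curve_fit(_exp_decay, ns, means, p0=p0, maxfev=20_000)
    except RuntimeError:
        return {"converged": False, "a": np.nan, "b": np.nan, "c": np.nan,
                "decay_per_option": np.nan, "span": span}
    fitted = _exp_decay(ns, *popt)
    decay = float(np.mean(np.abs(np.diff(fitted))))
    return {"converged": True, "a": popt[0], "b": popt[1], "c": popt[2],
            "decay_per_option": decay, "span": span}


def run_per_n_experiment(
    situations: Sequence[ChoiceSituation],
    optima: np.ndarray | None = None,
    seed: int = 0,
    init_modes: Sequence[str] = ("equal", "random"),
) -> dict:
    """Single-evaluation matching and greedy gain per option count N.

    Gains are pooled over the initial-sampling modes (equal and random by
    default, with paired random draws), since the per-N comparison is about
    the option count, not the sampling mode.
    """
    if optima is None:
        optima, excluded = solve_grid_optima(situations)
        situations, optima = _keep(situations, optima, excluded)
    parts = []
    for mode in init_modes:
        for rule in ("matching", "greedy"):
            tab = melioration_table(situations, optima, 1, mode, seed, rule=rule)
            parts.append(tab[tab["evaluation"] == 1])
    summary = summarize(pd.concat(parts, ignore_index=True), ["strategy", "N"])
    fits = {}
    for label, g in summary.groupby("strategy"):
        fits[label] = fit_exponential_decay(g["N"].to_numpy(), g["mean"].to_numpy())
    return {"summary": summary, "fits": fits}


def run_alpha_sweep(
    reps_per_n: int = 1000,
    seed: int = 0,
    families: Sequence[str] = ("power",),
    alphas: Sequence[float] = ALPHA_GRID,
    n_iterations: int = 4,
    init_mode: str = "random",
) -> pd.DataFrame:
    """Performance vs the diminishing-marginal-utility level alpha.

    Generates a dedicated grid per alpha (family restricted to ``families``;
    the power-only setting spans the full range from strongly diminishing,
    alpha = 0.1, to linear non-diminishing returns, alpha = 1.0) and runs
    melioration plus the greedy rule from the same per-situation random
    initial allocation.
    """
    rows = []
    for j, alpha in enumerate(alphas):
        grid_seed = _child_seed(seed, (0, j))
        grid = generate_grid(
            reps_per_n, master_seed=grid_seed, families=families, alpha=alpha
        )
        optima, excluded = solve_grid_optima(grid)
        grid, optima = _keep(grid, optima, excluded)
        init_seed = _child_seed(seed, (1, j))
        match = melioration_table(
            grid, optima, n_iterations, init_mode, init_seed, rule="matching"
        )
        greedy = melioration_table(
            grid, optima, 1, init_mode, init_seed, rule="greedy"
        )
        for df in (match, greedy[greedy["evaluation"] == 1]):
            df = df[df["evaluation"] >= 1].copy()
            df["alpha"] = alpha
            rows.append(df)
        log.info("alpha sweep: alpha=%.1f done", alpha)
    raw = pd.concat(rows, ignore_index=True)
    return summarize(raw, ["strategy", "alpha", "evaluation"])


def run_vi_experiment(
    reps_per_n: int = 1000,
    seed: int = 0,
    n_eval_matching: int = 10,
    max_windows: int = 250,
    include_maximization: bool = True,
    params: DiscountingParams = DiscountingParams(),
) -> dict:
    """Strategies on the randomized variable-interval grid.

    All strategies in one situation share the same random initial
    allocation and identically seeded schedule streams, so their first
    estimation window is literally the same sample.  Gains are expected
    collection rates as percent of the analytic VI optimum.
    """
    grid = generate_vi_grid(reps_per_n, master_seed=_child_seed(seed, (2,)))
    rows = []
    for i, s in enumerate(grid):
        opt = solve_vi_optimum(s).gain_star
        init_rng = environments.situation_rng(_child_seed(seed, (3,)), i)
        init = initial_allocation(s.n, "random", init_rng)
        sched_seed = np.random.SeedSequence(_child_seed(seed, (4,)), spawn_key=(i,))
        runs = {
            "matching": run_vi_strategy(
                s, "matching", n_eval_matching, init,
                np.random.default_rng(sched_seed), params
            ),
            "greedy": run_vi_strategy(
                s, "greedy", 1, init, np.random.default_rng(sched_seed), params
            ),
        }
        if include_maximization:
            runs["maximization"] = run_vi_strategy(
                s, "maximization", max_windows, init,
                np.random.default_rng(sched_seed), params
            )
        for label, trace in runs.items():
            for k, gain in enumerate(trace.gains):
                rows.append(
                    {"situation_id": s.situation_id, "N": s.n, "strategy": label,
                     "evaluation": k, "pct": normalize_gain(gain, opt)}
                )
        if (i + 1) % 1000 == 0:
            log.info("VI experiment: %d/%d situations", i + 1, len(grid))
    raw = pd.DataFrame(rows)
    return {"summary": summarize(raw, ["strategy", "evaluation"]), "raw": raw}


def _child_seed(seed: int, key: tuple[int, ...] | tuple[int]) -> int:
    """Deterministic sub-seed below 2**31 for a named branch of the master seed."""
    key = key if isinstance(key, tuple) else (key,)
    ss = np.random.SeedSequence(seed, spawn_key=key)
    return int(ss.generate_state(1)[0] % np.int64(2**31))


def load_config(path: str | Path) -> dict:
    """Flat key-value experiment config from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text) or {}
    return json.loads(text)


def write_manifest(out_dir: str | Path, config: dict) -> Path:
    """Record the run configuration and library versions next to the outputs."""
    import scipy

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
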