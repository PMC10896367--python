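#!/usr/bin/env python
"""Strategies on concurrent variable-interval schedules.

Simulates the randomized VI grid (Poisson baiting, window length T=400,
exponential-discounting worth estimation), running matching for several
evaluations, greedy, and the noisy budgeted maximizer, all from the
same random initial allocation per situation.  The default scale is
reduced (100 replicates per N) because the 250-window maximizer
dominates the cost; raise --reps-per-n for the full grid.

Writes vi_summary.csv.
"""

import logging
import sys
from pathlib import Path

import click

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import add_config, finish

from matchsim.experiments import run_vi_experiment

logging.basicConfig(level=logging.INFO, stream=sys.stderr)


@click.command()
@click.option("--reps-per-n", default=100, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--iterations", default=10, show_default=True,
              help="matching evaluations (windows)")
@click.option("--max-windows", default=250, show_default=True,
              help="window budget for the noisy maximizer")
@click.option("--skip-maximization", is_flag=True, default=False)
@click.option("--out", default="results", show_default=True, type=Path)
@click.option("--config", default=None, type=Path, help="JSON/YAML overrides")
def main(reps_per_n, seed, iterations, max_windows, skip_maximization, out, config):
    cfg = add_config(locals(), config)
    res = run_vi_experiment(
        reps_per_n=cfg["reps_per_n"],
        seed=cfg["seed"],
        n_eval_matching=cfg["iterations"],
        max_windows=cfg["max_windows"],
        include_maximization=not cfg["skip_maximization"],
    )
    s = res["summary"].set_index(["strategy", "evaluation"])
    click.echo(
        f"matching: {s.loc[('matching', 1), 'mean']:.1f}% after one evaluation, "
        f"{s.loc[('matching', cfg['iterations']), 'mean']:.1f}% after "
        f"{cfg['iterations']}"
    )
    click.echo(f"greedy:   {s.loc[('greedy', 1), 'mean']:.1f}%")
    if not cfg["skip_maximization"]:
        mk = s.loc["maximization"]["mean"]
        click.echo(
            f"maximizer: {mk.loc[1]:.1f}% after one window, "
            f"{mk.iloc[-1]:.1f}% after {cfg['max_windows']}"
        )
    finish(out, cfg, vi_summary=res["summary"])


if __name__ == "__main__":
    main()
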