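# matchsim — how well, and how fast, does the matching law decide?

Humans and animals rarely optimize. Instead of maximizing total utility,
they overwhelmingly allocate behavior in proportion to the worth of their
options — the *matching law*: relative effort equals relative utility,

```
e_i = u_i,      e_i = E_i / Σ_n E_n,      u_i = U_i / Σ_n U_n .
```

`matchsim` is a simulation study of why that heuristic is so widespread.
It generates large randomized families of utility–effort choice
environments, runs matching, generalized matching, greedy choice and
constrained reward maximization on them, and scores every strategy as a
percentage of the situation's true constrained optimum. The central
result it reproduces: **matching harvests roughly 90% of the maximum
possible gain after a single evaluation of the options**, while an
explicit constrained maximizer needs an order of magnitude more option
evaluations to do as well. Matching is not just good — it is *efficient*.

The package is aimed at computational behavioral ecologists, decision
scientists, and anyone studying melioration, operant choice, or
divisive-normalization decision rules.

## What is simulated

* **Environments** (`matchsim.environments`): N = 2…10 options, each with
  a random contingency `U(E)` drawn from four concave families — power
  `U_m E^α`, logistic `U_m(2/(1+e^{−E/α})−1)`, hyperbolic `U_m E/(E+α)`,
  logarithmic `U_m ln(E+1)/ln(1/α+1)` — with magnitude `U_m ~ U(0,1)` and
  saturation `α ∈ {0.1,…,1.0}`; 1000 replicates per N (9000 situations).
* **Strategies** (`matchsim.strategies`): strict matching (β = 1),
  generalized matching `u_i = U_i^β/Σ U_n^β` (undermatching β < 1,
  overmatching β > 1), the greedy limit (all effort on the
  sampled-richest option), and iterated melioration
  `e_next = u(e_prev)`.
* **Maximization** (`matchsim.maximization`): the simplex-constrained
  optimum of `Σ U_n(E_n)` (the 100% denominator), plus a budgeted
  maximizer that counts every candidate-allocation query — derivative
  estimation included — as one option evaluation.
* **Stochastic environments** (`matchsim.stochastic_vi`): concurrent
  variable-interval schedules; rewards are baited by Poisson processes at
  rates `r_i ~ U(0,1)` and held until harvested, harvest responses are
  Poisson at the effort rates, and worth is estimated by exponentially
  discounted reward integration (`γ = 3/T`, `T = 400`).
* **Experiments** (`matchsim.experiments`): normalization, β sweep,
  init-mode ANOVA, per-N analysis with exponential fits, α sweep, and
  the VI experiment.

## Worked example

```python
import numpy as np
from matchsim import (sample_situation, solve_optimum, initial_allocation,
                      run_strategy, normalize_gain)

s = sample_situation(3, np.random.default_rng(42))
opt = solve_optimum(s)
trace = run_strategy(s, "matching", 4, initial_allocation(s.n, "equal"))
for k, g in enumerate(trace.gains):
    print(f"evaluation {k}: allocation {np.round(trace.allocations[k], 3)} "
          f"gain {g:.4f} = {normalize_gain(g, opt.gain_star):.1f}% of optimum")
```

prints

```
evaluation 0: allocation [0.333 0.333 0.333] gain 0.7238 = 79.9% of optimum
evaluation 1: allocation [0.685 0.283 0.033] gain 0.8905 = 98.3% of optimum
evaluation 2: allocation [0.798 0.199 0.003] gain 0.8962 = 99.0% of optimum
evaluation 3: allocation [0.856 0.144 0.   ] gain 0.8899 = 98.3% of optimum
evaluation 4: allocation [0.893 0.107 0.   ] gain 0.8837 = 97.6% of optimum
```

One evaluation of this three-option situation (a power, a logarithmic and
a hyperbolic contingency) lifts the equal-sampling allocation from 79.9%
to 98.3% of the constrained optimum (0.9056); further melioration steps
hover near the matching fixed point, which for mixed families is close to
but not exactly the maximizer.

## The analysis

Numbered drivers under `analysis/` reproduce each experiment and write
tidy CSV tables plus a run manifest under `results/`:

| script | question it answers |
| --- | --- |
| `01_convergence.py` | matching vs the budgeted maximizer over evaluations |
| `02_beta_sweep.py` | gain as a function of the matching exponent β |
| `03_init_mode_anova.py` | equal vs random initial sampling, two-way ANOVA |
| `04_per_n.py` | performance per option count, exponential decay fits |
| `05_alpha_sweep.py` | effect of the level of diminishing returns α |
| `06_stochastic_vi.py` | variable-interval schedules with noisy estimation |

Each accepts `--reps-per-n`, `--seed`, `--iterations`, `--out` and an
optional `--config` (flat JSON/YAML). For example:

```bash
python analysis/02_beta_sweep.py --reps-per-n 1000 --seed 0 --out results
# strict matching (beta=1): 90.2%; beta=1.2: 90.5%; curve peaks at beta=1.3 (90.5%)
# extremes lose: indifference 78.2%, beta=20 73.2%
```

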