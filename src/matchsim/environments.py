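"""Randomized utility-effort choice environments.

A choice situation consists of N options, each with its own contingency
U(E) between invested effort E and harvested utility U.  Four function
families are used, all anchored at the origin (U(0) = 0), strictly
increasing, and concave on the unit effort interval:

    power        U(E) = U_m * E**alpha
    logistic     U(E) = U_m * (2 / (1 + exp(-E/alpha)) - 1)
    hyperbolic   U(E) = U_m * E / (E + alpha)
    logarithmic  U(E) = U_m * ln(E + 1) / ln(1/alpha + 1)

``U_m`` scales the magnitude of the contingency and ``alpha`` controls the
level of diminishing marginal utility (small alpha = strong saturation;
for the power family alpha = 1 is linear, i.e. no diminishing returns).

The randomization scheme samples, independently per option, the family
uniformly from the four kinds, U_m ~ Uniform[0, 1), and alpha uniformly
from the discrete grid {0.1, 0.2, ..., 1.0}.  A grid of situations covers
N = 2..10 options with a fixed number of replicates per N.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FAMILIES = ("power", "logistic", "hyperbolic", "logarithmic")
ALPHA_GRID = tuple(round(0.1 * k, 1) for k in range(1, 11))
DEFAULT_N_RANGE = tuple(range(2, 11))

_POWER, _LOGISTIC, _HYPERBOLIC, _LOGARITHMIC = range(4)
_FAMILY_CODE = {name: code for code, name in enumerate(FAMILIES)}


@dataclass(frozen=True)
class UtilityFunction:
    """One option's utility-effort contingency."""

    family: str
    magnitude: float  # U_m, gain scale
    saturation: float  # alpha, diminishing-returns level

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown utility family {self.family!r}")
        if not self.magnitude > 0:
            raise ValueError("magnitude U_m must be positive")
        if not self.saturation > 0:
            raise ValueError("saturation alpha must be positive")

    def __call__(self, effort):
        return eval_utility(self, effort)


def eval_utility(fn: UtilityFunction, effort):
    """Evaluate U(E) for one option; vectorized over ``effort``.

    Raises ValueError for negative effort.
    """
    e = np.asarray(effort, dtype=float)
    if np.any(e < 0):
        raise ValueError("effort must be nonnegative")
    um, a = fn.magnitude, fn.saturation
    code = _FAMILY_CODE[fn.family]
    out = _eval_family(code, um, a, e)
    return float(out) if np.isscalar(effort) or e.ndim == 0 else out


def _eval_family(code: int, um: float, a: float, e: np.ndarray) -> np.ndarray:
    if code == _POWER:
        return um * e**a
    if code == _LOGISTIC:
        return um * (2.0 / (1.0 + np.exp(-e / a)) - 1.0)
    if code == _HYPERBOLIC:
        return um * e / (e + a)
    return um * np.log(e + 1.0) / np.log(1.0 / a + 1.0)


def _eval_family_derivative(code: int, um: float, a: float, e: np.ndarray) -> np.ndarray:
    # power with alpha < 1 has an unbounded derivative at E = 0; a tiny floor
    # keeps the gradient finite for the optimizer.
    if code == _POWER:
        return um * a * np.maximum(e, 1e-12) ** (a - 1.0)
    if code == _LOGISTIC:
        z = np.exp(-e / a)
        return um * 2.0 * z / (a * (1.0 + z) ** 2)
    if code == _HYPERBOLIC:
        return um * a / (e + a) ** 2
    return um / ((e + 1.0) * np.log(1.0 / a + 1.0))


@dataclass
class ChoiceSituation:
    """A set of N utility functions constituting one decision problem."""

    options: tuple[UtilityFunction, ...]
    situation_id: str = ""
    rng_seed: tuple[int, int] | int | None = None

    _codes: np.ndarray = field(init=False, repr=False, compare=False)
    _um: np.ndarray = field(init=False, repr=False, compare=False)
    _alpha: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.options = tuple(self.options)
        if len(self.options) < 2:
            raise ValueError("a choice situation needs at least 2 options")
        self._codes = np.array([_FAMILY_CODE[o.family] for o in self.options])
        self._um = np.array([o.magnitude for o in self.options])
        self._alpha = np.array([o.saturation for o in self.options])

    @property
    def n(self) -> int:
        return len(self.options)

    def utilities(self, efforts) -> np.ndarray:
        """Per-option utilities U_i(e_i) for an effort vector."""
        e = np.asarray(efforts, dtype=float)
        if e.shape != (self.n,):
            raise ValueError(f"effort vector must have length {self.n}")
        if np.any(e < 0):
            raise ValueError("effort must be nonnegative")
        out = np.empty(self.n)
        for code in np.unique(self._codes):
            m = self._codes == code
            out[m] = _eval_family(int(code), self._um[m], self._alpha[m], e[m])
        return out

    def total_gain(self, efforts) -> float:
        """Total utility sum_i U_i(e_i)."""
        return float(self.utilities(efforts).sum())

    def marginal_utilities(self, efforts) -> np.ndarray:
        """Per-option derivatives dU_i/dE at the given efforts."""
        e = np.asarray(efforts, dtype=float)
        out = np.empty(self.n)
        for code in np.unique(self._codes):
            m = self._codes == code
            out[m] = _eval_family_derivative(
                int(code), self._um[m], self._alpha[m], e[m]
            )
        return out


def sample_situation(
    n_options: int,
    rng: np.random.Generator,
    situation_id: str = "",
    rng_seed=None,
    families: Sequence[str] = FAMILIES,
    alpha: float | None = None,
) -> ChoiceSituation:
    """Draw one randomized choice situation.

    Per option: family uniform over ``families``, U_m ~ Uniform[0, 1),
    alpha uniform over the discrete grid (or fixed when ``alpha`` is given,
    as in the diminishing-returns sweep).
    """
    if n_options < 2:
        raise ValueError("n_options must be at least 2")
    fam_idx = rng.integers(len(families), size=n_options)
    um = rng.random(n_options)
    if alpha is None:
        alphas = [ALPHA_GRID[k] for k in rng.integers(len(ALPHA_GRID), size=n_options)]
    else:
        alphas = [alpha] * n_options
    # U_m = 0 would make an option's utility identically zero; the draw is
    # continuous so clip away the measure-zero boundary.
    um = np.maximum(um, 1e-12)
    options = tuple(
        UtilityFunction(families[f], float(u), float(a))
        for f, u, a in zip(fam_idx, um, alphas)
    )
    return ChoiceSituation(options, situation_id=situation_id, rng_seed=rng_seed)


def situation_rng(master_seed: int, index: int) -> np.random.Generator:
    """Child random stream for situation ``index`` under ``master_seed``.

    Counter-based spawning: any single situation is re-creatable in
    isolation without generating the rest of the grid.
    """
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(index,))
    )


def generate_grid(
    reps_per_n: int,
    n_range: Iterable[int] = DEFAULT_N_RANGE,
    master_seed: int = 0,
    families: Sequence[str] = FAMILIES,
    alpha: float | None = None,
) -> list[ChoiceSituation]:
    """Randomized grid of situations: ``reps_per_n`` replicates per N."""
    if reps_per_n < 1:
        raise ValueError("reps_per_n must be at least 1")
    situations = []
    for index, (n, rep) in enumerate(itertools.product(n_range, range(reps_per_n))):
        rng = situation_rng(master_seed, index)
        situations.append(
            sample_situation(
                n,
                rng,
                situation_id=f"s{master_seed}-n{n}-r{rep}",
                rng_seed=(master_seed, index),
                families=families,
                alpha=alpha,
            )
        )
    return situations


def grid_to_frame(situations: Sequence[ChoiceSituation]) -> pd.DataFrame:
    """Flatten a grid to one row per option (CSV/JSON friendly)."""
    rows = []
    for s in situations:
        seed = "" if s.rng_seed is None else ":".join(map(str, np.atleast_1d(s.rng_seed)))
        for j, o in enumerate(s.options):
            rows.append(
                {
                    "situation_id": s.situation_id,
                    "N": s.n,
                    "option_index": j,
                    "family": o.family,
                    "U_m": o.magnitude,
                    "alpha": o.saturation,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def frame_to_situations(frame: pd.DataFrame) -> list[ChoiceSituation]:
    """Inverse of :func:`grid_to_frame` (option order preserved)."""
    situations = []
    for sid, g in frame.groupby("situation_id", sort=False):
        g = g.sort_values("option_index")
        options = tuple(
            UtilityFunction(r.family, float(r.U_m), float(r.alpha))
            for r in g.itertuples()
        )
        seed = g["seed"].iloc[0]
        rng_seed = tuple(int(x) for x in str(seed).split(":")) if seed else None
        situations.append(ChoiceSituation(options, situation_id=sid, rng_seed=rng_seed))
    return situations
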