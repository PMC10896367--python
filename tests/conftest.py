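import numpy as np
import pytest

from matchsim.environments import ChoiceSituation, UtilityFunction, generate_grid


@pytest.fixture(scope="session")
def two_linear():
    """Two linear options (power, alpha=1) with U_m = 0.8 and 0.4.

    Hand-solvable: worth at equal allocation is (0.4, 0.2); one matching
    step gives e = (2/3, 1/3) and gain 2/3; the optimum is the corner
    (1, 0) with gain 0.8.
    """
    return ChoiceSituation(
        (
            UtilityFunction("power", 0.8, 1.0),
            UtilityFunction("power", 0.4, 1.0),
        ),
        situation_id="two-linear",
    )


@pytest.fixture(scope="session")
def small_grid():
    """Reduced randomized grid: 20 replicates per N = 2..10."""
    return generate_grid(20, master_seed=101)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
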