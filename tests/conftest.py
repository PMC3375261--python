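import numpy as np
import pytest

from gogrow import LatticeGeometry, ModelRates


@pytest.fixture
def baseline_rates() -> ModelRates:
    """Canonical parameter set: cell-cycle time unit, motile and long-lived."""
    return ModelRates(alpha=1.0, nu=5.0, mu=0.01, k_p=1.0, k_m=2.0)


@pytest.fixture
def small_1d() -> LatticeGeometry:
    return LatticeGeometry(d=1, L=21)


def assert_counts_match_grid(traj, grid):
    """Grid recount equals the trajectory's cached final counts."""
    n_p = int(np.count_nonzero(grid == 1))
    n_m = int(np.count_nonzero(grid == 2))
    assert traj.n_p[-1] == n_p
    assert traj.n_m[-1] == n_m
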