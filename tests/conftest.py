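import numpy as np
import pytest

from tumorca import ModelParams, init_state


@pytest.fixture
def table1_params():
    """The reference parameterization (defaults of ModelParams)."""
    return ModelParams()


def random_state(seed, n_rows=20, n_cols=20, density=0.3, params=None, rng_seed=None):
    """A random occupancy state whose current list is sorted row-major,
    as both engines require for exact comparison."""
    params = params or ModelParams()
    rng = np.random.default_rng(seed)
    occupied = np.argwhere(rng.random((n_rows, n_cols)) < density)
    seeds = [tuple(map(int, rc)) for rc in occupied]
    state = init_state(
        n_rows, n_cols, seeds, params, seed if rng_seed is None else rng_seed
    )
    state.current_list.sort(key=lambda c: (c.row, c.col))
    return state


def state_signature(state):
    """Hashable full-state summary: occupancy bytes + sorted cell tuples."""
    cells = tuple(sorted((c.row, c.col, c.ph) for c in state.current_list))
    return state.lattice.occupancy.tobytes(), cells
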