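import numpy as np
import pytest

import nichevar as nv


@pytest.fixture(scope="session")
def climate20():
    """Small current-climate stack shared across tests."""
    return nv.gen_climate(nv.GridSpec(20, 20, 25.0), n_vars=5, seed=11)


@pytest.fixture(scope="session")
def species20(climate20):
    """One bell-niche virtual species on the shared landscape."""
    return nv.make_species(
        climate20, "sp1", {"v1": ("bell", 0.0, 0.8), "v2": ("bell", 0.2, 0.9)}, 0.15
    )


@pytest.fixture(scope="session")
def mini_result():
    """A reduced but complete factorial experiment, reused by several tests."""
    cfg = nv.ExperimentConfig(n_rows=20, n_cols=20, n_species=4, n_repeats=3)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return nv.run_experiment(cfg, seed=7)


def stack_from_values(values, cell_size=25.0):
    """Build a ClimateStack directly from a (n_vars, rows, cols) array."""
    values = np.asarray(values, dtype=float)
    grid = nv.GridSpec(values.shape[1], values.shape[2], cell_size)
    names = [f"v{i + 1}" for i in range(values.shape[0])]
    return nv.ClimateStack(grid, names, values)
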