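import numpy as np
import pytest

import allokin as ak
from allokin.reference import WT_M7GUO_TRUTH


@pytest.fixture(scope="session")
def wt_truth() -> ak.ISParams:
    """Canonical strongly negatively-cooperative truth (Km2 = 4.0 mM,
    Vmax2 = 8.2 U/mg exactly)."""
    return ak.ISParams(**WT_M7GUO_TRUTH)


@pytest.fixture(scope="session")
def wt_grid(wt_truth) -> np.ndarray:
    return ak.make_concentration_grid(wt_truth.Km1, wt_truth.Km2, 16)


@pytest.fixture(scope="session")
def noiseless_is_dataset(wt_truth, wt_grid) -> ak.VelocityDataset:
    return ak.simulate_velocity_dataset(
        "IS", wt_truth, wt_grid, ak.NoiseSpec(mode="relative", cv=0.0, n_rep=1, seed=0)
    )


@pytest.fixture(scope="session")
def noiseless_mm_dataset() -> ak.VelocityDataset:
    grid = np.logspace(-1, 2, 12)
    return ak.simulate_velocity_dataset(
        "MM",
        ak.MMParams(Km=1.0, Vmax=10.0),
        grid,
        ak.NoiseSpec(mode="relative", cv=0.0, n_rep=1, seed=0),
    )
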