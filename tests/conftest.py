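import numpy as np
import pandas as pd
import pytest

from mfyeval.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default 23-herd / 541-cow synthetic dataset, shared read-only."""
    return simulate_dataset(SimulationConfig(seed=20230713))


@pytest.fixture()
def tiny_tables():
    """Three-cow, two-herd hand-checkable dataset."""
    cows = pd.DataFrame(
        {
            "cow_id": ["c1", "c2", "c3"],
            "herd_id": ["A", "A", "B"],
            "parity_raw": [1, 3, 2],
            "an_parity": [1, 2, 2],
            "an_bw": [550.0, 672.0, 700.0],
            "an_bcs": [2.5, 2.5, 3.0],
            "an_daylact": [50.0, 202.0, 120.0],
            "milk_yield": [25.0, 29.1, 35.0],
            "fat_pct": [4.0, 4.26, 3.8],
            "protein_pct": [3.2, 3.3, 3.1],
            "lactose_pct": [4.6, 4.6, 4.5],
            "observed_mfy_g": [1000.0, 1239.66, 1330.0],
            "mp_g": [2300.0, 2500.0, 2800.0],
            "dmi_obs": [21.0, 24.0, 26.0],
        }
    )
    diets = pd.DataFrame(
        {
            "herd_id": ["A", "B"],
            "dt_fndf": [25.0, 30.0],
            "dt_adf": [23.6, 21.0],
            "dt_ndf": [38.8, 36.0],
            "fa_pct_dm": [2.5, 3.0],
            "dig_c160_pct_dm": [0.29, 0.30],
            "dig_c183_pct_dm": [0.38, 0.40],
            "ile_pct_mp": [5.98, 6.00],
            "met_pct_mp": [2.21, 2.20],
            "forndf48_ndf": [53.4, 50.0],
        }
    )
    return cows, diets


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
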