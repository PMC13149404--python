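import numpy as np
import pandas as pd
import pytest

from ildbench import ILDDataset, SimCondition, simulate_dataset


@pytest.fixture(scope="session")
def toy_dataset() -> ILDDataset:
    """Two clusters {0, 2} and {4, 6} on a single item.

    Hand-computable moments: S_PW = 2, S_B = 16, grand mean 3,
    ICC1 = 14/18.
    """
    df = pd.DataFrame({
        "person": [1, 1, 2, 2],
        "occasion": [1, 2, 1, 2],
        "item1": [0.0, 2.0, 4.0, 6.0],
    })
    return ILDDataset(df)


@pytest.fixture(scope="session")
def small_sim() -> ILDDataset:
    """A small simulated dataset shared across read-only tests."""
    return simulate_dataset(SimCondition(20, 10, 1.0, "none", "low", seed=7))


def random_spd(rng: np.random.Generator, p: int, ridge: float = 0.5):
    a = rng.standard_normal((p, p))
    return a @ a.T / p + ridge * np.eye(p)


def random_psd(rng: np.random.Generator, p: int, scale: float = 0.5):
    a = rng.standard_normal((p, p)) * scale
    return a @ a.T / p
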