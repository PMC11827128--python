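import numpy as np
import pytest

from catgrm.grm import ItemBank, ItemParameters
from catgrm.synth import SyntheticConfig, generate_dataset


@pytest.fixture
def std_item() -> ItemParameters:
    """The canonical worked-example item: a = 1, thresholds (-1, 0, 1, 2)."""
    return ItemParameters("std", 1.0, np.array([-1.0, 0.0, 1.0, 2.0]))


@pytest.fixture
def toy_bank() -> ItemBank:
    items = (
        ItemParameters("i1", 1.0, np.array([-1.5, -0.5, 0.5, 1.5])),
        ItemParameters("i2", 1.8, np.array([-2.0, -1.0, 0.0, 1.0])),
        ItemParameters("i3", 2.5, np.array([-0.8, -0.2, 0.4, 1.2])),
        ItemParameters("i4", 1.2, np.array([-1.0, 0.0, 0.8, 2.2])),
        ItemParameters("i5", 0.7, np.array([-2.5, -1.0, 0.5, 2.0])),
    )
    return ItemBank(items)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_dataset():
    """One clean study-scale dataset (n=600, 20 items), shared across tests."""
    return generate_dataset(SyntheticConfig(n_items=20, seed=0))


def random_item(rng: np.random.Generator, k: int = 5, item_id: str = "r") -> ItemParameters:
    a = rng.uniform(0.5, 3.0)
    b = np.sort(rng.normal(0, 1.2, k - 1))
    while np.any(np.diff(b) < 0.05):
        b = np.sort(rng.normal(0, 1.2, k - 1))
    return ItemParameters(item_id, a, b)
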