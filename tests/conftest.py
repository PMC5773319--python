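import numpy as np
import pytest

from minarea import (
    IslandRecord,
    OrdinalDataset,
    SyntheticConfig,
    fixture_83,
    generate,
    to_ordinal_dataset,
)


@pytest.fixture(scope="session")
def fixture_records():
    return fixture_83()


@pytest.fixture(scope="session")
def rattle_data(fixture_records):
    return to_ordinal_dataset(fixture_records, "rattlesnakes")


@pytest.fixture(scope="session")
def colubrid_data(fixture_records):
    return to_ordinal_dataset(fixture_records, "colubrids")


@pytest.fixture(scope="session")
def toy12():
    """A small, fixed 12-island dataset with a clear area signal."""
    x_area = np.array(
        [-1.2, -0.8, -0.5, -0.3, -0.1, 0.1, 0.3, 0.6, 0.9, 1.2, 1.6, 2.0]
    )
    y = np.array([0, 0, 0, 0, 1, 0, 1, 1, 2, 1, 2, 2])
    return OrdinalDataset(
        x_area=x_area,
        x_isolation=np.zeros(12),
        y=y,
        group="rattlesnakes",
    )


@pytest.fixture
def hand_records():
    return [
        IslandRecord("alpha", 1.0, 2.0, 0, 1, age=10.0),
        IslandRecord("bravo", 12.5, 0.5, 1, 0),
        IslandRecord("charlie", 150.0, 8.0, 3, 5, age=500.0),
    ]


def synthetic_dataset(
    n, theta=(0.0, 2.0), beta_area=1.5, seed=0, group="rattlesnakes", **kw
):
    config = SyntheticConfig(
        n=n, theta_true=theta, beta_area_true=beta_area, seed=seed, **kw
    )
    return to_ordinal_dataset(generate(config), group)
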