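import numpy as np
import pytest

from myconest.data_model import CountTable, PairedDesign, SampleMetadata
from myconest.synthetic import SimulationParams, simulate_dataset


def random_table(rng: np.random.Generator, n_otus=6, n_samples=4, high=50) -> CountTable:
    counts = rng.integers(0, high, size=(n_otus, n_samples))
    return CountTable(
        [f"OTU{i}" for i in range(n_otus)],
        [f"S{j}" for j in range(n_samples)],
        counts,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    return CountTable(
        ["OTU1", "OTU2", "OTU3"],
        ["S1", "S2"],
        np.array([[3, 0], [1, 2], [0, 5]]),
    )


@pytest.fixture
def tiny_paired():
    """Two plants x two treatments, hand-countable values."""
    table = CountTable(
        ["OTU1", "OTU2", "OTU3"],
        ["P1-I", "P1-D", "P2-I", "P2-D"],
        np.array(
            [
                [10, 10, 4, 4],  # identical in every pair
                [10, 100, 0, 10],  # gains under disturbance
                [5, 0, 7, 0],  # disturbed-only losses
            ]
        ),
    )
    design = PairedDesign({"P1": ("P1-I", "P1-D"), "P2": ("P2-I", "P2-D")})
    return table, design


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_dataset(SimulationParams(seed=1))


def make_metadata(sample_id, plant_id, treatment, habitat="grassland", elevation=640.0,
                  year=2015, **kw):
    return SampleMetadata(
        sample_id=sample_id,
        plant_id=plant_id,
        treatment=treatment,
        habitat=habitat,
        elevation=elevation,
        collection_year=year,
        **kw,
    )
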