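import numpy as np
import pytest

from corescope.containers import CountTable, SampleMetadata
from corescope.synthetic_data import generate_dataset, small_spec

import pandas as pd


@pytest.fixture
def toy_table() -> CountTable:
    """3 samples x 4 OTUs, by hand."""
    counts = np.array(
        [
            [5, 0, 3, 2],
            [1, 1, 0, 8],
            [0, 4, 4, 2],
        ]
    )
    return CountTable(["S1", "S2", "S3"], ["OTU_1", "OTU_2", "OTU_3", "OTU_4"],
                      counts)


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3"],
                "reactor": ["BF", "BF", "MK"],
                "unit": ["U-1", "U-1", "U-2"],
                "category": ["farm", "farm", "bio-waste"],
                "reactor_role": ["Fd", "Fd", "Pd"],
                "timepoint": [1, 2, 1],
                "pH": [7.8, 7.9, None],
            }
        )
    )


@pytest.fixture(scope="session")
def synth_small():
    """One small synthetic dataset shared across tests (read-only)."""
    return generate_dataset(small_spec(seed=11))


def random_table(rng: np.random.Generator, n_samples: int = 5,
                 n_otus: int = 12, high: int = 40) -> CountTable:
    counts = rng.integers(0, high, size=(n_samples, n_otus))
    # guarantee no all-zero sample
    for i in range(n_samples):
        if counts[i].sum() == 0:
            counts[i, rng.integers(n_otus)] = 1
    return CountTable(
        [f"S{i}" for i in range(n_samples)],
        [f"OTU_{j}" for j in range(n_otus)],
        counts,
    )
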