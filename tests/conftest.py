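import numpy as np
import pandas as pd
import pytest

from fosnet.counts import AnimalMeta, CountTable


@pytest.fixture
def toy_table():
    """3 animals x 4 regions with explicit totals."""
    counts = pd.DataFrame(
        {
            "R1": [2, 5, 7],
            "R2": [3, 1, 0],
            "R3": [5, 4, 9],
            "R4": [0, 2, 4],
        },
        index=["a1", "a2", "a3"],
    )
    counts.index.name = "animal_id"
    return CountTable(counts, totals=pd.Series([10, 12, 20], index=counts.index),
                      totals_from="column")


@pytest.fixture
def toy_meta():
    frame = pd.DataFrame(
        {"group": ["treat", "treat", "ctrl"], "batch": ["b1", "b1", "b1"]},
        index=["a1", "a2", "a3"],
    )
    frame.index.name = "animal_id"
    return AnimalMeta(frame)


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
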