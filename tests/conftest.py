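import numpy as np
import pandas as pd
import pytest

from riveredna.readtable import MOTUReadTable


@pytest.fixture
def toy_table() -> MOTUReadTable:
    """Three sites, three MOTUs, with PCR detections out of 24 replicates."""
    reads = pd.DataFrame(
        {
            "motuA": [120, 40, 0],
            "motuB": [4, 2, 3],
            "motuC": [76, 158, 197],
        },
        index=["S1", "S2", "S3"],
    )
    pcr = pd.DataFrame(
        {
            "motuA": [20, 9, 0],
            "motuB": [2, 1, 1],
            "motuC": [18, 23, 24],
        },
        index=["S1", "S2", "S3"],
    )
    km = pd.Series([0.0, 10.0, 25.0], index=["S1", "S2", "S3"])
    return MOTUReadTable(reads=reads, pcr_positive=pcr, km=km, pcr_replicates=24)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
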