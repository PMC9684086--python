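import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from crowdome.io import AbundanceTable, MetadataTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_abundance():
    data = pd.DataFrame(
        {
            "Lactobacillus_crispatus": [0.6, 0.2, 0.49],
            "Lactobacillus_iners": [0.4, 0.7, 0.31],
            "Gardnerella_vaginalis": [0.0, 0.1, 0.20],
        },
        index=["s1", "s2", "s3"],
    )
    return AbundanceTable(data)


@pytest.fixture
def random_abundance(rng):
    raw = rng.dirichlet(np.ones(8), size=20)
    data = pd.DataFrame(raw, index=[f"s{i}" for i in range(20)],
                        columns=[f"Taxon_{j}" for j in range(8)])
    return AbundanceTable(data)


@pytest.fixture
def mixed_metadata():
    data = pd.DataFrame(
        {
            "age": [25.0, 30.0, 35.0, 28.0],
            "parity": [0.0, 1.0, 2.0, 1.0],
            "smoker": [0.0, 1.0, 0.0, np.nan],
            "region": ["north", "south", "north", "east"],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    kinds = {"age": "continuous", "parity": "ordinal", "smoker": "binary", "region": "nominal"}
    return MetadataTable(data, kinds)
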