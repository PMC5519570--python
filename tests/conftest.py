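import numpy as np
import pandas as pd
import pytest

from microems.core import AbundanceTable, IncidenceMatrix


def make_incidence(values) -> IncidenceMatrix:
    values = np.asarray(values)
    return IncidenceMatrix(
        values,
        [f"s{i}" for i in range(values.shape[0])],
        [f"o{j}" for j in range(values.shape[1])],
    )


@pytest.fixture
def small_table() -> AbundanceTable:
    counts = pd.DataFrame(
        [[50, 50, 0], [70, 20, 10], [100, 0, 0]],
        index=["a1", "a2", "w1"],
        columns=["otuA", "otuB", "otuC"],
    )
    return AbundanceTable(counts, {"otuA": "k__Bacteria; p__Proteobacteria"})


@pytest.fixture
def small_metadata() -> pd.DataFrame:
    md = pd.DataFrame(
        {
            "sample_id": ["a1", "a2", "w1"],
            "population": ["pop1", "pop1", "pop1"],
            "deme": ["deme1", "deme1", "deme1"],
            "sample_type": ["animal", "animal", "water"],
            "latitude": [38.0, 38.01, 38.0],
            "longitude": [-86.0, -86.0, -86.0],
            "elevation": [400.0, 401.0, 400.0],
            "forest_cover": [60.0, 61.0, 60.0],
        }
    )
    return md.set_index("sample_id", drop=False)
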