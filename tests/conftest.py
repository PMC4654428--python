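import numpy as np
import pandas as pd
import pytest

from rdsoil import community


@pytest.fixture
def small_table():
    """4 samples x 4 OTUs, two soils x two treatments, hand-sized counts."""
    counts = pd.DataFrame(
        [[10, 5, 3, 2], [8, 6, 4, 2], [1, 9, 5, 5], [2, 8, 6, 4]],
        index=["KleCon_1", "KleCon_2", "KleH50_1", "KleH50_2"],
        columns=["Otu1", "Otu2", "Otu3", "Otu4"],
    )
    taxonomy = pd.DataFrame(
        [
            ["Bacteria", "PhyA", "c1", "o1", "f1", "GenX"],
            ["Bacteria", "PhyA", "c1", "o1", "f1", "GenX"],
            ["Bacteria", "PhyB", "c2", "o2", "f2", "GenY"],
            ["Bacteria", "PhyB", "c2", "o2", "f2", "unclassified"],
        ],
        index=counts.columns,
        columns=list(community.LEVELS),
    )
    metadata = pd.DataFrame(
        {
            "soil": ["Kle", "Kle", "Kle", "Kle"],
            "treatment": ["Con", "Con", "H50", "H50"],
            "replicate": [1, 2, 1, 2],
        },
        index=counts.index,
    )
    return community.OtuTable(counts, taxonomy, metadata)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
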