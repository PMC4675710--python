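import numpy as np
import pandas as pd
import pytest

from microdyn.abundance import KOCatalog
from microdyn.table_io import CountTable, NormalizedAbundanceTable, default_design


@pytest.fixture
def design():
    return default_design()


@pytest.fixture
def small_catalog():
    """Two-marker reduced panel plus two pathway KOs sharing a pathway."""
    return KOCatalog(
        median_length={"mkA": 300, "mkB": 600, "K00001": 500, "K00002": 250},
        pathways={
            "mkA": frozenset(),
            "mkB": frozenset(),
            "K00001": frozenset({"map00010", "map00020"}),
            "K00002": frozenset({"map00010"}),
        },
        prokaryote_flag={"map00010": True, "map00020": True},
    )


@pytest.fixture
def counts_3x2():
    df = pd.DataFrame(
        [[1, 2], [3, 4], [5, 6]],
        index=["f1", "f2", "f3"],
        columns=["s1", "s2"],
    )
    return CountTable(df, feature_kind="otu")


def make_abundance(rows, index, columns, kind="pathway"):
    return NormalizedAbundanceTable(
        pd.DataFrame(np.asarray(rows, dtype=float), index=index, columns=columns),
        feature_kind=kind,
    )
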