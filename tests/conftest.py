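import numpy as np
import pandas as pd
import pytest

from microassembly.tables import OTUTable


def make_table(counts, sample_ids=None, otu_ids=None) -> OTUTable:
    counts = np.asarray(counts)
    n, m = counts.shape
    return OTUTable(pd.DataFrame(
        counts,
        index=sample_ids or [f"S{i}" for i in range(n)],
        columns=otu_ids or [f"O{j}" for j in range(m)]))


@pytest.fixture
def small_table() -> OTUTable:
    return make_table([[10, 0, 5, 2],
                       [0, 10, 5, 1],
                       [3, 3, 3, 3]])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
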