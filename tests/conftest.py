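from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chillseq.expression import CountTable


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture
def toy_table() -> CountTable:
    """Small hand-made count table over the four conditions."""
    counts = pd.DataFrame(
        {
            "NC": [100, 20, 0, 5, 400],
            "CA": [400, 20, 50, 5, 100],
            "CCA": [100, 20, 0, 5, 400],
            "CS": [400, 25, 60, 0, 90],
        },
        index=[f"g{i}" for i in range(1, 6)],
    )
    totals = pd.Series({"NC": 1e6, "CA": 1e6, "CCA": 1e6, "CS": 1e6})
    return CountTable(counts=counts, totals=totals)
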