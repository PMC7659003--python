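import numpy as np
import pandas as pd
import pytest

from micronet.abundance import AbundanceTable


def make_table(values, condition="C", dates=None, units="counts", taxa=None):
    """Small-table helper: values is (n_taxa, n_samples)."""
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    taxa = taxa or [f"T{i}" for i in range(n)]
    dates = dates or list(range(1, t + 1))
    cols = [f"{condition}{d}" for d in dates]
    meta = pd.DataFrame({"condition": condition, "date_index": dates}, index=cols)
    return AbundanceTable(pd.DataFrame(values, index=taxa, columns=cols), meta, units)


@pytest.fixture
def paired_tables():
    """A tiny paired C/B dataset with 4 taxa over 7 dates."""
    rng = np.random.default_rng(42)
    base = rng.uniform(1, 10, size=(4, 7))
    c = make_table(base, "C")
    b = make_table(base * rng.uniform(0.8, 1.2, size=(4, 7)), "B")
    return c, b
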