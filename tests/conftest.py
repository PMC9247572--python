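import numpy as np
import pandas as pd
import pytest

from microdrivers.asv_tables import STATE_COL, CountTable


def make_table(counts, states=None, sample_ids=None, asv_ids=None, extra_meta=None):
    """Build a CountTable from a raw array with minimal metadata."""
    counts = np.asarray(counts)
    n_asv, n_samp = counts.shape
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(n_samp)]
    asv_ids = asv_ids or [f"A{i + 1}" for i in range(n_asv)]
    states = states or ["BT"] * (n_samp // 2) + ["AT"] * (n_samp - n_samp // 2)
    meta = pd.DataFrame({STATE_COL: states}, index=sample_ids)
    if extra_meta:
        for k, v in extra_meta.items():
            meta[k] = v
    return CountTable(
        counts=pd.DataFrame(counts, index=asv_ids, columns=sample_ids),
        metadata=meta,
    )


@pytest.fixture
def small_table():
    rng = np.random.default_rng(42)
    return make_table(rng.integers(0, 200, size=(30, 12)))
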