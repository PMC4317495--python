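import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def small_design() -> pd.DataFrame:
    rows = []
    for cond in ("active", "inactive"):
        for b in ("b1", "b2"):
            for t in ("t1", "t2"):
                rows.append((f"{cond}_{b}_{t}", cond, b, t, 1000))
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "bio_rep", "tech_rep", "total_spectra"]
    )


@pytest.fixture
def small_counts(small_design) -> pd.DataFrame:
    rng = np.random.default_rng(7)
    data = rng.integers(0, 30, size=(6, len(small_design)))
    return pd.DataFrame(
        data,
        index=pd.Index([f"P{i}" for i in range(6)], name="accession"),
        columns=small_design["sample_id"],
    )


@pytest.fixture
def small_meta(small_counts) -> pd.DataFrame:
    return pd.DataFrame(
        {"mw_kda": [50.0, 100.0, 20.0, 250.0, 75.0, 10.0]}, index=small_counts.index
    )


@pytest.fixture
def unit_square():
    return [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]
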