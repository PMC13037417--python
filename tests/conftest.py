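import numpy as np
import pandas as pd
import pytest

from mirvalid.diffexpr import CountMatrix
from mirvalid.qpcrquant import CtTable


@pytest.fixture
def toy_counts() -> CountMatrix:
    """4 miRNAs x 4 samples, hand-sized so normalization is checkable."""
    counts = pd.DataFrame(
        {
            "s1": [100, 200, 50, 10],
            "s2": [110, 190, 55, 12],
            "s3": [400, 820, 210, 38],
            "s4": [95, 205, 48, 11],
        },
        index=["miR-a", "miR-b", "miR-c", "miR-d"],
    )
    groups = pd.Series(
        ["case", "case", "control", "control"], index=counts.columns
    )
    return CountMatrix(counts=counts, groups=groups)


@pytest.fixture
def toy_de() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "base_mean": [100.0, 80.0, 60.0, 40.0, 20.0, 10.0],
            "log2fc": [2.5, -1.8, 0.10, -0.05, 0.5, 0.0],
            "p": [1e-6, 1e-4, 0.6, 0.8, 0.2, 0.9],
            "fdr": [6e-6, 3e-4, 0.8, 0.9, 0.4, 0.9],
            "call": ["up", "down", "ns", "ns", "ns", "ns"],
        },
        index=["miR-up", "miR-dn", "miR-s1", "miR-s2", "miR-s3", "miR-s4"],
    )


def make_ct_table(rows) -> CtTable:
    """rows: iterable of (sample, group, assay, ct, undetermined)."""
    return CtTable(
        pd.DataFrame(
            rows,
            columns=["sample_id", "group", "assay_id", "ct", "undetermined"],
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
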