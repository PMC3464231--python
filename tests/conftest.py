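import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ing4nfkb import ExpressionCohort, PunchTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_cohort():
    """3 genes x 4 samples with clinical annotation."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [5.0, 5.0, 5.0, 9.0],
         [0.0, 10.0, 0.0, 10.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"])
    clinical = pd.DataFrame(
        {"time": [1.0, 2.0, 3.0, 4.0],
         "event": [True, True, False, True]},
        index=["s1", "s2", "s3", "s4"])
    return ExpressionCohort(values=values, clinical=clinical)


@pytest.fixture
def punch_table():
    rows = [
        ("T1", "ING4", "p1", 2), ("T1", "ING4", "p2", 3),
        ("T2", "ING4", "p1", 3), ("T2", "ING4", "p2", 3),
        ("T2", "ING4", "p3", 3),
        ("T3", "ING4", "p1", 1), ("T3", "ING4", "p2", np.nan),
        ("T3", "ING4", "p3", 2),
        ("T1", "pP65", "p1", 0), ("T1", "pP65", "p2", 1),
        ("T2", "pP65", "p1", 0), ("T2", "pP65", "p2", 0),
        ("T2", "pP65", "p3", 1),
        ("T3", "pP65", "p1", 3), ("T3", "pP65", "p2", 2),
        ("T3", "pP65", "p3", 3),
    ]
    return PunchTable(pd.DataFrame(
        rows, columns=["tumor_id", "marker", "punch_id", "score"]))


def calls_from_counts(n_low: int, n_high: int, prefix: str) -> pd.Series:
    """Reconstruct per-tumor low/high calls from published group counts."""
    ids = [f"{prefix}{i}" for i in range(n_low + n_high)]
    return pd.Series(["low"] * n_low + ["high"] * n_high, index=ids)
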