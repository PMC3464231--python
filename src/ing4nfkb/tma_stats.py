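"""Tissue-microarray IHC score aggregation and association statistics.

A tumor contributes two or three 0.6 mm punches per marker; each punch
gets an ordinal nuclear-staining score 0..3 from the pathologist. The
tumor-level score is the arithmetic mean over evaluable punches, and the
tumor is called marker-low when the mean is < 1.5 and marker-high at
>= 1.5. Calls for two markers (or a call against a pathology annotation)
are cross-tabulated and tested with Fisher's exact test.

The exact test is the two-sided point-probability version: sum the
hypergeometric probabilities, at fixed margins, of every table no more
probable than the observed one (with a small relative tolerance so exact
rational ties are not split by float rounding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import PunchTable, ValidationError

__all__ = [
    "ContingencyTable2x2",
    "aggregate_punches",
    "dichotomize",
    "crosstab",
    "fisher_exact_2x2",
    "percent",
    "field_count_average",
    "invasion_fold",
]


def percent(numerator: float, denominator: float) -> int:
    """Display percentage, rounded half away from zero (77/227 -> 34)."""
    if denominator == 0:
        raise ValidationError("percentage of empty group")
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] with row/column labels.

    Rows are levels of marker A, columns levels of marker B; ``a`` is the
    (row0, col0) cell.
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple = ("high", "low")
    col_labels: tuple = ("high", "low")

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValidationError("counts must be non-negative integers")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def row_percent(self) -> pd.DataFrame:
        """Within-row percentages, rounded to nearest integer for display."""
        rows = []
        for (x, y) in ((self.a, self.b), (self.c, self.d)):
            n = x + y
            rows.append([percent(x, n), percent(y, n)])
        return pd.DataFrame(rows, index=list(self.row_labels),
                            columns=list(self.col_labels))

    def p_value(self) -> float:
        return fisher_exact_2x2(self)


def aggregate_punches(punches: PunchTable, marker: str) -> pd.DataFrame:
    """Per-tumor mean IHC score for one marker.

    Missing (non-evaluable) punches are dropped; tumors with zero
    evaluable punches are reported with ``n_punches = 0`` and NaN score
    so downstream analyses can exclude them per-marker rather than
    listwise.
    """
    r = punches.records
    sel = r[r["marker"].str.lower() == marker.lower()]
    if sel.empty:
        raise ValidationError(f"marker {marker!r} not in punch table")
    grp = sel.groupby("tumor_id")["score"]
    out = pd.DataFrame({
        "mean_score": grp.mean(),
        "n_punches": grp.count().astype(int),
    })
    out.index.name = "tumor_id"
    return out


def dichotomize(scores, cutoff: float = 1.5) -> pd.Series:
    """Call low/high per tumor: low iff mean score < cutoff (1.5 -> high).

    ``scores`` is the frame from :func:`aggregate_punches` or a plain
    Series of mean scores. Non-evaluable tumors (NaN score) are dropped.
    """
    s = scores["mean_score"] if isinstance(scores, pd.DataFrame) else scores
    s = s.dropna()
    return pd.Series(np.where(s >= cutoff, "high", "low"),
                     index=s.index, name="call")


def crosstab(calls_a: pd.Series, calls_b: pd.Series,
             order=("high", "low")) -> ContingencyTable2x2:
    """2x2 cross-tabulation of two call series sharing tumor ids.

    Tumors missing either call are excluded, so each pairwise analysis
    uses its own maximal n.
    """
    common = calls_a.index.intersection(calls_b.index)
    if len(common) == 0:
        raise ValidationError("no tumors with both calls")
    a = calls_a.loc[common]
    b = calls_b.loc[common]
    counts = [[int(((a == ra) & (b == cb)).sum()) for cb in order]
              for ra in order]
    return ContingencyTable2x2(a=counts[0][0], b=counts[0][1],
                               c=counts[1][0], d=counts[1][1],
                               row_labels=tuple(order),
                               col_labels=tuple(order))


def fisher_exact_2x2(table, rel_tol: float = 1e-9) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Enumerates the hypergeometric distribution over all tables with the
    observed margins and sums the probabilities of tables whose point
    probability is <= that of the observed table (within ``rel_tol``
    relatively, to keep exact rational ties together despite float
    rounding).
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = table
    n = a + b + c + d
    if n == 0:
        raise ValidationError("all-zero contingency table")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + rel_tol)].sum())
    # the full support sums to 1 only up to float rounding
    return 1.0 if p >= 1.0 - 1e-9 else p


def field_count_average(counts_per_image, min_images: int = 4) -> float:
    """Mean cell count over field images (invasion-assay readout)."""
    counts = list(counts_per_image)
    if len(counts) < min_images:
        raise ValidationError(
            f"need >= {min_images} field images, got {len(counts)}")
    return float(np.mean(counts))


def invasion_fold(counts_a, counts_b, min_images: int = 4) -> float:
    """Fold difference in invasion: ratio of field-count means (A / B)."""
    return (field_count_average(counts_a, min_images)
            / field_count_average(counts_b, min_images))
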