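"""Readers, writers and validated in-memory containers for the tabular
formats the pipeline touches.

Three containers back the whole analysis:

* :class:`ExpressionCohort` — a genes x samples expression matrix with
  optional per-sample survival annotation (time, event),
* :class:`CtTable` — long-format qPCR cycle-threshold measurements,
* :class:`PunchTable` — punch-level ordinal IHC scores (0..3) from a
  tissue microarray.

All tables are UTF-8 and tab-delimited by default (``sep=","`` accepted
everywhere). Gene symbols are case-preserved but matched
case-insensitively. A small local-file-only reader for the GEO SOFT GDS
dialect is included; it never touches the network.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionCohort",
    "CtTable",
    "PunchTable",
    "read_expression_table",
    "write_expression_table",
    "read_clinical_table",
    "read_soft_gds",
    "read_ct_table",
    "read_punch_table",
    "write_results",
]


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class ExpressionCohort:
    """Genes x samples expression matrix with optional clinical annotation.

    Parameters
    ----------
    values : pandas.DataFrame
        Dense numeric matrix, index = gene symbols, columns = sample ids.
        Scale is whatever the source dataset uses (linear or log); the
        scoring machinery only relies on within-gene ranks.
    clinical : pandas.DataFrame, optional
        Indexed by sample id with columns ``time`` (non-negative float,
        unit as given by the cohort) and ``event`` (bool, 1 = recurrence
        or death). Clinical samples must be a subset of the matrix samples.
    """

    values: pd.DataFrame
    clinical: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        _check(v.index.is_unique, "duplicate gene ids in expression matrix")
        _check(v.columns.is_unique, "duplicate sample ids in expression matrix")
        lowered = pd.Index([str(g).lower() for g in v.index])
        _check(lowered.is_unique,
               "gene ids collide under case-insensitive matching")
        bad = v.columns[~v.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
        _check(len(bad) == 0, f"non-numeric expression columns: {list(bad)}")
        self._lower_index = {g.lower(): g for g in map(str, v.index)}
        if self.clinical is not None:
            c = self.clinical
            _check(c.index.is_unique, "duplicate sample ids in clinical table")
            missing = c.index.difference(v.columns)
            _check(missing.empty,
                   f"clinical samples absent from matrix: {list(missing)}")
            _check({"time", "event"} <= set(c.columns),
                   "clinical table needs 'time' and 'event' columns")
            _check((c["time"] >= 0).all(), "negative survival time")
            self.clinical = c.assign(event=c["event"].astype(bool))

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def resolve_gene(self, gene: str) -> str:
        """Map a symbol to the matrix row label, case-insensitively."""
        try:
            return self._lower_index[gene.lower()]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in cohort") from None

    def expression(self, gene: str) -> pd.Series:
        """Expression of one gene across all samples."""
        return self.values.loc[self.resolve_gene(gene)]


@dataclass
class CtTable:
    """Long-format qPCR Ct measurements.

    Columns: ``sample``, ``gene``, ``condition``, ``replicate``, ``ct``.
    Ct values are finite cycle numbers > 0. A designated reference gene
    (default GAPDH) must be measured in every condition it is asked to
    normalize.
    """

    records: pd.DataFrame
    reference_gene: str = "GAPDH"

    REQUIRED = ("sample", "gene", "condition", "replicate", "ct")

    def __post_init__(self) -> None:
        r = self.records
        _check(set(self.REQUIRED) <= set(r.columns),
               f"Ct table needs columns {self.REQUIRED}")
        ct = pd.to_numeric(r["ct"], errors="coerce")
        _check(ct.notna().all() and np.isfinite(ct).all(),
               "non-finite Ct values")
        _check((ct > 0).all(), "Ct values must be > 0")
        self.records = r.assign(ct=ct.astype(float))

    def mean_ct(self, gene: str, condition: str) -> float:
        """Replicate-averaged Ct for one gene in one condition."""
        r = self.records
        sel = r[(r["gene"].str.lower() == gene.lower())
                & (r["condition"] == condition)]
        if sel.empty:
            raise ValidationError(
                f"no Ct measurements for gene {gene!r} in condition "
                f"{condition!r}")
        return float(sel["ct"].mean())


@dataclass
class PunchTable:
    """Punch-level ordinal IHC scores from a tissue microarray.

    Columns: ``tumor_id``, ``marker``, ``punch_id``, ``score``. Scores are
    integers in {0,1,2,3}; an empty cell marks a non-evaluable punch
    (folded/lost core), which is dropped during aggregation.
    """

    records: pd.DataFrame

    REQUIRED = ("tumor_id", "marker", "punch_id", "score")

    def __post_init__(self) -> None:
        r = self.records
        _check(set(self.REQUIRED) <= set(r.columns),
               f"punch table needs columns {self.REQUIRED}")
        s = pd.to_numeric(r["score"], errors="coerce")
        bad = s.dropna()[~s.dropna().isin([0, 1, 2, 3])]
        _check(bad.empty,
               f"punch scores outside 0..3 at rows {list(bad.index)}")
        self.records = r.assign(score=s)
        counts = self.records.dropna(subset=["score"]) \
            .groupby(["tumor_id", "marker"]).size()
        if (counts > 3).any():
            raise ValidationError("more than 3 evaluable punches for a "
                                  "tumor-marker pair")

    def markers(self) -> list[str]:
        return sorted(self.records["marker"].unique())


# ---------------------------------------------------------------------------
# expression matrix I/O


def read_expression_table(path, clinical_path=None, sep: str = "\t",
                          impute_missing: bool = False) -> ExpressionCohort:
    """Read a genes-in-rows expression matrix (first column = gene ids).

    Non-numeric cells are rejected with a row/column report; with
    ``impute_missing=True`` empty cells are filled with the per-gene
    median instead (imputed cells then sit at the median and score 0
    under the <=-median rule).
    """
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False)
    df.index = df.index.map(str)
    if not df.index.is_unique:
        dups = df.index[df.index.duplicated()].unique()
        raise ValidationError(f"duplicate gene ids: {list(dups)}")
    numeric = df.apply(lambda c: pd.to_numeric(
        c.where(c.str.strip() != "", other=np.nan), errors="coerce"))
    blank = df.apply(lambda c: c.str.strip() == "")
    bad = numeric.isna() & ~blank
    if bad.any().any():
        cells = [f"gene {df.index[i]!r} / sample {df.columns[j]!r}"
                 for i, j in zip(*np.where(bad.values))]
        raise ValidationError("non-numeric expression cells: "
                              + "; ".join(cells[:10]))
    if numeric.isna().any().any():
        if not impute_missing:
            n = int(numeric.isna().sum().sum())
            raise ValidationError(
                f"{n} missing expression cells (pass impute_missing=True "
                "to fill with per-gene medians)")
        med = numeric.median(axis=1)
        numeric = numeric.apply(lambda col: col.fillna(med))
    numeric = numeric.astype(float)
    clinical = read_clinical_table(clinical_path, sep=sep) \
        if clinical_path is not None else None
    return ExpressionCohort(values=numeric, clinical=clinical)


def read_clinical_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read per-sample survival annotation (sample, time, event)."""
    c = pd.read_csv(path, sep=sep)
    _check({"sample", "time", "event"} <= set(c.columns),
           "clinical table needs columns sample, time, event")
    c = c.set_index("sample")
    c.index = c.index.map(str)
    return c


def write_expression_table(cohort: ExpressionCohort, path,
                           clinical_path=None, sep: str = "\t") -> None:
    cohort.values.to_csv(path, sep=sep, float_format="%.10g",
                         index_label="gene")
    if clinical_path is not None and cohort.clinical is not None:
        out = cohort.clinical.copy()
        out["event"] = out["event"].astype(int)
        out.to_csv(clinical_path, sep=sep, index_label="sample",
                   float_format="%.10g")


# ---------------------------------------------------------------------------
# GEO SOFT (GDS dialect), local files only


def read_soft_gds(path, collapse: str = "max_mean") -> ExpressionCohort:
    """Parse a local GDS SOFT file into an :class:`ExpressionCohort`.

    The dataset table between ``!dataset_table_begin`` and
    ``!dataset_table_end`` is read; gene symbols come from the
    ``IDENTIFIER`` column. When several probes map to one symbol the
    probe with the highest mean expression is kept (``collapse=
    "max_mean"``, the common signature-scoring convention); ``collapse=
    "mean"`` averages probes instead. No network access, ever.
    """
    with open(path, "rt", encoding="utf-8", errors="replace") as fh:
        lines = fh.read().splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.strip().lower() == "!dataset_table_begin")
        end = next(i for i, l in enumerate(lines)
                   if l.strip().lower() == "!dataset_table_end")
    except StopIteration:
        raise ValidationError(
            "missing !dataset_table_begin/!dataset_table_end delimiters"
        ) from None
    _check(end > start + 1, "empty dataset table")
    table = pd.read_csv(io.StringIO("\n".join(lines[start + 1:end])),
                        sep="\t", dtype=str, keep_default_na=False)
    _check({"ID_REF", "IDENTIFIER"} <= set(table.columns),
           "dataset table lacks ID_REF/IDENTIFIER columns")
    sample_cols = [c for c in table.columns
                   if c not in ("ID_REF", "IDENTIFIER")]
    _check(len(sample_cols) > 0, "dataset table has zero samples")
    values = table[sample_cols].apply(
        lambda c: pd.to_numeric(c.replace({"null": np.nan, "": np.nan}),
                                errors="coerce"))
    values.index = table["IDENTIFIER"].map(str)
    values = values.dropna(how="all")
    if collapse == "max_mean":
        rows = []
        for sym_lower in pd.unique(values.index.str.lower()):
            mask = values.index.str.lower() == sym_lower
            sub = values[mask]
            rows.append(sub.iloc[int(np.argmax(sub.mean(axis=1).values))])
        values = pd.DataFrame(rows)
    elif collapse == "mean":
        values = values.groupby(values.index, sort=False).mean()
    else:
        raise ValueError(f"unknown collapse policy {collapse!r}")
    return ExpressionCohort(values=values)


# ---------------------------------------------------------------------------
# Ct and punch tables


def read_ct_table(path, sep: str = "\t",
                  reference_gene: str = "GAPDH") -> CtTable:
    return CtTable(pd.read_csv(path, sep=sep), reference_gene=reference_gene)


def write_ct_table(table: CtTable, path, sep: str = "\t") -> None:
    table.records.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_punch_table(path, sep: str = "\t") -> PunchTable:
    return PunchTable(pd.read_csv(path, sep=sep,
                                  dtype={"tumor_id": str, "marker": str}))


def write_punch_table(table: PunchTable, path, sep: str = "\t") -> None:
    out = table.records.copy()
    out["score"] = out["score"].map(
        lambda v: "" if (v is None or (isinstance(v, float) and math.isnan(v)))
        else str(int(v)))
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# generic result writer


def _six_sig(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    return x


def write_results(results, path, format: str = "tsv") -> None:
    """Write a result mapping / record list with deterministic ordering.

    Floats are serialized at 6 significant digits so repeated writes of
    the same result are byte-identical.
    """
    if format == "json":
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return _six_sig(float(o))
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"unserializable {type(o)}")

        def walk(o):
            if isinstance(o, dict):
                return {k: walk(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [walk(v) for v in o]
            if isinstance(o, float):
                return _six_sig(o)
            return o

        with open(path, "w", encoding="utf-8") as fh:
            json.dump(walk(results), fh, indent=2, default=default)
            fh.write("\n")
    elif format == "tsv":
        if isinstance(results, pd.DataFrame):
            df = results
        elif isinstance(results, dict):
            df = pd.DataFrame([results])
        else:
            df = pd.DataFrame(list(results))
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    else:
        raise ValueError(f"unknown format {format!r}")
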