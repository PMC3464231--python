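"""Relative qPCR quantification and the NF-kB target-gene filter cascade.

Fold changes use the standard ddCt method with an assumed amplification
efficiency of 2 (no efficiency correction): for a target gene and a
reference gene (GAPDH by default),

    ddCt = (Ct_gene,cond - Ct_ref,cond) - (Ct_gene,base - Ct_ref,base)
    fold = 2 ** (-ddCt)

Replicate wells are averaged on the Ct scale *before* taking differences,
the deterministic convention of ddCt practice.

The signature-derivation cascade filters a panel of NF-kB target genes:
genes induced more than ``induce_threshold``-fold by PMA in the control
line form the induced set; within it, genes whose PMA induction is blunted
by ING4 overexpression by at least 2-fold (ratio of induction folds,
control / ING4 line) form the broad repressed tier, and at least 4-fold
the stringent tier. Tiers nest: repressed4 <= repressed2 <= induced.

Also here: the luciferase-reporter normalization arithmetic (relative
light units per microgram protein per integrated luc2 copy, with copy
number read off a plasmid standard curve).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import CtTable, ValidationError

__all__ = [
    "FoldChangeRecord",
    "SignatureDerivation",
    "StandardCurve",
    "ReporterMeasurement",
    "ddct_fold_change",
    "select_induced",
    "repression_ratio",
    "select_repressed",
    "derive_signature",
    "copies_from_standard_curve",
    "reporter_activity",
    "fold_induction",
]


@dataclass(frozen=True)
class FoldChangeRecord:
    """2^(-ddCt) fold change for one gene under one contrast."""

    gene: str
    condition: str
    baseline: str
    ddct: float
    fold: float

    def __post_init__(self):
        if not math.isfinite(self.ddct):
            raise ValidationError(f"non-finite ddCt for {self.gene}")
        if not math.isclose(self.fold, 2.0 ** (-self.ddct),
                            rel_tol=1e-12):
            raise ValidationError("fold inconsistent with ddCt")


@dataclass(frozen=True)
class SignatureDerivation:
    """Induced / repressed gene tiers with the thresholds that made them."""

    induced: frozenset
    repressed2: frozenset
    repressed4: frozenset
    induce_threshold: float = 2.0
    repress_thresholds: tuple = (2.0, 4.0)

    def __post_init__(self):
        if not (self.repressed4 <= self.repressed2 <= self.induced):
            raise ValidationError("tiers must nest: repressed4 <= "
                                  "repressed2 <= induced")
        if self.induce_threshold <= 1 or min(self.repress_thresholds) <= 1:
            raise ValidationError("thresholds must exceed 1")


def ddct_fold_change(ct_table: CtTable, gene: str, condition: str,
                     baseline: str,
                     reference_gene: str | None = None) -> FoldChangeRecord:
    """ddCt fold change of ``gene`` in ``condition`` vs ``baseline``.

    Replicates are averaged to a mean Ct per (gene, condition) first.
    Raises if any of the four required Ct sets (gene/reference x
    condition/baseline) is absent.
    """
    ref = reference_gene or ct_table.reference_gene
    dct_cond = ct_table.mean_ct(gene, condition) \
        - ct_table.mean_ct(ref, condition)
    dct_base = ct_table.mean_ct(gene, baseline) \
        - ct_table.mean_ct(ref, baseline)
    ddct = dct_cond - dct_base
    return FoldChangeRecord(gene=gene, condition=condition,
                            baseline=baseline, ddct=ddct,
                            fold=2.0 ** (-ddct))


def select_induced(folds, threshold: float = 2.0) -> set:
    """Genes induced strictly more than ``threshold``-fold.

    ``folds`` maps gene -> PMA-vs-vehicle fold in the control line. The
    inequality is strict ("more than 2-fold"): a gene at exactly the
    threshold is excluded.
    """
    return {g for g, f in folds.items() if f > threshold}


def repression_ratio(fold_control: float, fold_ing4: float) -> float:
    """How much ING4 blunts PMA induction: control fold / ING4-line fold."""
    if fold_ing4 <= 0:
        raise ValidationError("ING4-line fold must be positive")
    return fold_control / fold_ing4


def select_repressed(induced, ratios, threshold: float = 2.0) -> set:
    """Induced genes whose repression ratio is >= ``threshold``."""
    return {g for g in induced if ratios.get(g, 0.0) >= threshold}


def derive_signature(folds_control, folds_ing4,
                     induce_threshold: float = 2.0,
                     repress_thresholds=(2.0, 4.0)) -> SignatureDerivation:
    """Run the full cascade from per-line PMA induction folds.

    ``folds_control`` / ``folds_ing4`` map gene -> PMA-vs-vehicle fold in
    the vector-control and ING4-overexpressing line respectively.
    """
    induced = select_induced(folds_control, induce_threshold)
    ratios = {g: repression_ratio(folds_control[g], folds_ing4[g])
              for g in induced if g in folds_ing4}
    lo, hi = sorted(repress_thresholds)
    return SignatureDerivation(
        induced=frozenset(induced),
        repressed2=frozenset(select_repressed(induced, ratios, lo)),
        repressed4=frozenset(select_repressed(induced, ratios, hi)),
        induce_threshold=induce_threshold,
        repress_thresholds=(lo, hi))


# ---------------------------------------------------------------------------
# luciferase reporter normalization


@dataclass
class StandardCurve:
    """Least-squares Ct vs log10(copies) calibration line.

    Requires >= 2 distinct points with Ct strictly decreasing as copy
    number increases (an amplifying assay has negative slope).
    """

    points: list  # of (log10_copies, ct)
    slope: float = field(init=False)
    intercept: float = field(init=False)

    def __post_init__(self):
        pts = sorted((float(x), float(y)) for x, y in self.points)
        if len(pts) < 2:
            raise ValidationError("standard curve needs >= 2 points")
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        if np.any(np.diff(xs) == 0):
            raise ValidationError("duplicate log10-copies standards")
        if not np.all(np.diff(ys) < 0):
            raise ValidationError("Ct must strictly decrease with copies")
        self.slope, self.intercept = np.polyfit(xs, ys, 1)
        if self.slope >= 0:
            raise ValidationError("non-amplifying curve (slope >= 0)")


def copies_from_standard_curve(ct: float, curve: StandardCurve) -> float:
    """Invert the calibration line: copies = 10^((ct - b) / m)."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


@dataclass(frozen=True)
class ReporterMeasurement:
    """One luciferase well: raw light units, protein load, luc2 copies."""

    rlu: float
    protein_ug: float
    luc2_copies: float

    def __post_init__(self):
        if self.protein_ug <= 0:
            raise ValidationError("protein_ug must be positive")
        if self.luc2_copies <= 0:
            raise ValidationError("luc2_copies must be positive")


def reporter_activity(m: ReporterMeasurement) -> float:
    """RLU per microgram protein per integrated luc2 copy."""
    return m.rlu / m.protein_ug / m.luc2_copies


def fold_induction(treated: ReporterMeasurement,
                   untreated: ReporterMeasurement) -> float:
    """Normalized reporter activity ratio, treated / untreated."""
    return reporter_activity(treated) / reporter_activity(untreated)
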