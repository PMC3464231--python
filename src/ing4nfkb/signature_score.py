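"""The ING4/NF-kB gene score: median-vote signature scoring.

For a fixed gene set, each gene is dichotomized at its own median
expression *within the scored dataset*: a sample gets +1 for a gene when
its expression is strictly greater than that gene's median, and 0 when
equal to or below it. A sample's score is the vote sum, an integer in
[0, |gene set|]. Because only within-gene ranks matter, the score is
invariant under any strictly increasing per-gene transform of the data
(log, quantile, linear rescale).

:class:`SignatureScorer` implements this as a scikit-learn style
transformer over samples x genes frames; the module-level functions wrap
it for the genes x samples :class:`~ing4nfkb.io_formats.ExpressionCohort`
container. Medians are always refit on the dataset being scored — they
are never transferred across datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io_formats import ExpressionCohort, ValidationError

__all__ = [
    "SignatureScorer",
    "GroupComparison",
    "read_gene_set",
    "fit_score_model",
    "score_samples",
    "split_by_marker_gene",
    "compare_group_scores",
]


class SignatureScorer(BaseEstimator, TransformerMixin):
    """Median-vote gene-signature scorer.

    Parameters
    ----------
    genes : sequence of str, optional
        Signature gene symbols (matched case-insensitively against the
        data's columns). ``None`` uses every column.
    on_missing : {"drop", "error"}
        What to do with signature genes absent from the data: drop them
        with a warning (the score range shrinks accordingly) or raise.

    Attributes
    ----------
    genes_used_ : list of str
        Signature genes found in the fitted data (data's column names).
    medians_ : pandas.Series
        Per-gene median (midpoint interpolation for even n), indexed by
        ``genes_used_``.
    n_missing_ : int
        Signature genes not found in the data.
    """

    def __init__(self, genes=None, on_missing: str = "drop"):
        self.genes = genes
        self.on_missing = on_missing

    # X: DataFrame of shape (n_samples, n_genes)
    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes DataFrame")
        lower = {str(c).lower(): c for c in X.columns}
        if len(lower) != X.shape[1]:
            raise ValidationError("gene columns collide case-insensitively")
        if self.genes is None:
            used = list(X.columns)
            missing = []
        else:
            used, missing = [], []
            for g in self.genes:
                col = lower.get(str(g).lower())
                (used if col is not None else missing).append(
                    col if col is not None else g)
        if not used:
            raise ValidationError("no signature gene present in the data")
        if missing:
            if self.on_missing == "error":
                raise ValidationError(f"missing signature genes: {missing}")
            warnings.warn(
                f"{len(missing)} signature gene(s) absent and dropped: "
                f"{missing}", stacklevel=2)
        self.genes_used_ = used
        self.n_missing_ = len(missing)
        self.medians_ = X[used].median(axis=0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-gene 0/1 votes (1 iff strictly above the fitted median)."""
        votes = (X[self.genes_used_] > self.medians_).astype(int)
        return votes

    def score_samples(self, X: pd.DataFrame) -> pd.Series:
        """Integer signature score per sample (vote sum)."""
        s = self.transform(X).sum(axis=1)
        s.name = "score"
        return s

    @property
    def max_score_(self) -> int:
        return len(self.genes_used_)


def read_gene_set(path) -> list:
    """Read a gene set: one symbol per line, '#' starts a comment."""
    genes = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym:
                genes.append(sym)
    return genes


# ---------------------------------------------------------------------------
# cohort-level wrappers


def fit_score_model(cohort: ExpressionCohort, gene_set) -> SignatureScorer:
    """Fit the median-vote model on a cohort (genes x samples container)."""
    scorer = SignatureScorer(genes=list(gene_set))
    return scorer.fit(cohort.values.T)


def score_samples(cohort: ExpressionCohort,
                  model: SignatureScorer) -> pd.DataFrame:
    """Score every sample; returns votes plus the summed score column."""
    X = cohort.values.T
    votes = model.transform(X)
    out = votes.copy()
    out["score"] = votes.sum(axis=1)
    out.index.name = "sample"
    return out


def split_by_marker_gene(cohort: ExpressionCohort,
                         marker_gene: str = "ING4",
                         cutoff: float | None = None) -> pd.Series:
    """Label samples low/high by a marker gene's expression.

    Default cutoff is the marker's within-dataset median with ties going
    low (<= median -> low), the same convention the score itself uses;
    pass ``cutoff`` to override (e.g. a ROC-derived value). With an
    explicit cutoff the rule stays <= cutoff -> low.
    """
    expr = cohort.expression(marker_gene)
    if cutoff is None:
        cutoff = float(np.median(expr.values))
    labels = pd.Series(np.where(expr > cutoff, "high", "low"),
                       index=expr.index, name=f"{marker_gene}_group")
    if (labels == "low").all():
        warnings.warn("degenerate split: every sample is 'low' "
                      "(constant marker?)", stacklevel=2)
    return labels


@dataclass(frozen=True)
class GroupComparison:
    """Unpaired two-tailed pooled-variance Student t comparison."""

    labels: tuple
    means: tuple
    mean_difference: float
    t: float
    df: int
    p: float


def compare_group_scores(scores: pd.Series,
                         labels: pd.Series) -> GroupComparison:
    """Compare mean scores between two labelled groups (pooled t-test).

    Degenerate case: zero pooled variance with zero mean difference has
    no defined t; it is reported as p = 1 with a warning.
    """
    common = scores.index.intersection(labels.index)
    s, l = scores.loc[common], labels.loc[common]
    names = sorted(pd.unique(l))
    if len(names) != 2:
        raise ValidationError(f"need exactly 2 groups, got {names}")
    g1 = s[l == names[0]].astype(float)
    g2 = s[l == names[1]].astype(float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("each group needs n >= 2")
    diff = float(g1.mean() - g2.mean())
    df = len(g1) + len(g2) - 2
    if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0 and diff == 0:
        warnings.warn("identical constant groups: p undefined, "
                      "reported as 1", stacklevel=2)
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(g1, g2, equal_var=True)
    return GroupComparison(labels=tuple(names),
                           means=(float(g1.mean()), float(g2.mean())),
                           mean_difference=diff, t=float(t), df=df,
                           p=float(p))
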