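"""Survival stratification: ROC cutoff, Kaplan-Meier, log-rank, hazard ratio.

Everything here is computed from first principles on (time, event,
group) arrays:

* Kaplan-Meier product-limit curves (censored subjects at an event time
  still count as at risk at that time — events precede censorings when
  tied, the standard convention);
* the two-group log-rank test: at each distinct event time the number of
  events in group 1 is compared with its hypergeometric expectation, and
  the accumulated (O1 - E1)^2 / V is referred to a 1-df chi-square;
* hazard ratios, by default the Mantel-Haenszel / log-rank one-step
  estimate ln HR = (O1 - E1) / V with SE = 1 / sqrt(V), with a
  one-covariate Cox partial-likelihood fit (Newton iteration, Breslow
  ties) available as an alternative method for cross-checking;
* ROC-based cutoff selection maximizing Youden's J over all midpoints
  between adjacent distinct marker values.

`stratify_and_compare` glues these into the end-to-end analysis: choose
a cutoff for a continuous marker (a gene's expression or a signature
score), split the cohort, and compare survival between the groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionCohort, ValidationError

__all__ = [
    "KMCurve",
    "LogrankResult",
    "HazardRatioResult",
    "CutoffResult",
    "StratifiedComparison",
    "km_curve",
    "logrank_test",
    "hazard_ratio",
    "roc_optimal_cutoff",
    "stratify_and_compare",
]

Z975 = 1.959963984540054  # two-sided 95% normal quantile


def _as_arrays(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.size == 0:
        raise ValidationError("empty survival data")
    if t.shape != e.shape:
        raise ValidationError("time and event lengths differ")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValidationError("times must be finite and > 0")
    return t, e


@dataclass
class KMCurve:
    """Kaplan-Meier step function: S(0) = 1, drops at event times only."""

    times: np.ndarray       # distinct event times, ascending
    at_risk: np.ndarray     # number at risk just before each event time
    n_events: np.ndarray    # events at each time
    survival: np.ndarray    # S(t) just after each event time

    def survival_at(self, t) -> np.ndarray:
        """Evaluate the step function at arbitrary times."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "at_risk": self.at_risk,
                             "n_events": self.n_events,
                             "survival": self.survival})

    def rmst(self, tau: float) -> float:
        """Restricted mean survival time: area under S(t) on [0, tau]."""
        knots = np.concatenate([[0.0], self.times[self.times < tau], [tau]])
        heights = np.concatenate([[1.0],
                                  self.survival[self.times < tau]])
        return float(np.sum(np.diff(knots) * heights))


def km_curve(time, event) -> KMCurve:
    """Product-limit survival estimate for one group."""
    t, e = _as_arrays(time, event)
    n = t.size
    ut = np.unique(t[e])
    if ut.size == 0:
        return KMCurve(times=np.empty(0), at_risk=np.empty(0, int),
                       n_events=np.empty(0, int), survival=np.empty(0))
    ts = np.sort(t)
    at_risk = n - np.searchsorted(ts, ut, side="left")
    d = np.array([(t[e] == u).sum() for u in ut])
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(times=ut, at_risk=at_risk.astype(int),
                   n_events=d.astype(int), survival=surv)


@dataclass
class LogrankResult:
    o1: float
    o2: float
    e1: float
    e2: float
    variance: float
    chi2: float
    p: float


def _logrank_oe(time, event, group1_mask):
    """Observed/expected/variance tabulation over distinct event times."""
    t, e = _as_arrays(time, event)
    g1 = np.asarray(group1_mask, dtype=bool)
    ut = np.unique(t[e])
    if ut.size == 0:
        raise ValidationError("no events: log-rank undefined")
    ts = np.sort(t)
    t1s = np.sort(t[g1])
    n_at = t.size - np.searchsorted(ts, ut, side="left")
    n1_at = g1.sum() - np.searchsorted(t1s, ut, side="left")
    # events per distinct time, overall and in group 1
    idx = np.searchsorted(ut, t[e])
    d = np.bincount(idx, minlength=ut.size).astype(float)
    d1 = np.bincount(idx, weights=g1[e].astype(float),
                     minlength=ut.size)
    e1 = d * n1_at / n_at
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(n_at > 1,
                     d * (n1_at / n_at) * (1 - n1_at / n_at)
                     * (n_at - d) / (n_at - 1),
                     0.0)
    return float(d1.sum()), float(d.sum() - d1.sum()), float(e1.sum()), \
        float((d - e1).sum()), float(v.sum())


def logrank_test(time, event, group) -> LogrankResult:
    """Two-group log-rank test; p from a 1-df chi-square."""
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValidationError(f"need exactly 2 groups, got {list(levels)}")
    o1, o2, e1, e2, v = _logrank_oe(time, event, g == levels[0])
    if v <= 0:
        raise ValidationError("zero log-rank variance: no informative "
                              "event times")
    chi2 = (o1 - e1) ** 2 / v
    return LogrankResult(o1=o1, o2=o2, e1=e1, e2=e2, variance=v, chi2=chi2,
                         p=float(stats.chi2.sf(chi2, df=1)))


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    method: str
    exposed: str


def hazard_ratio(time, event, group, exposed=None,
                 method: str = "mantel-haenszel") -> HazardRatioResult:
    """Hazard of the exposed group relative to the other group.

    ``exposed`` names the numerator group (default: the first level in
    sorted order). ``method="mantel-haenszel"`` uses the one-step
    log-rank estimate ln HR = (O - E) / V; ``method="cox"`` fits a
    one-covariate Cox model by Newton iteration (Breslow ties).
    """
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValidationError(f"need exactly 2 groups, got {list(levels)}")
    if exposed is None:
        exposed = levels[0]
    if exposed not in levels:
        raise ValidationError(f"exposed group {exposed!r} not present")
    mask = g == exposed
    t, e = _as_arrays(time, event)
    if e[mask].sum() == 0 or e[~mask].sum() == 0:
        warnings.warn("a group has no events; hazard ratio is a "
                      "boundary estimate", stacklevel=2)
    if method == "mantel-haenszel":
        o1, _, e1, _, v = _logrank_oe(t, e, mask)
        if v <= 0:
            raise ValidationError("zero variance: HR undefined")
        ln_hr = (o1 - e1) / v
        se = 1.0 / np.sqrt(v)
    elif method == "cox":
        ln_hr, se = _cox_one_covariate(t, e, mask.astype(float))
    else:
        raise ValueError(f"unknown method {method!r}")
    return HazardRatioResult(hr=float(np.exp(ln_hr)),
                             ci_low=float(np.exp(ln_hr - Z975 * se)),
                             ci_high=float(np.exp(ln_hr + Z975 * se)),
                             method=method, exposed=str(exposed))


def _cox_one_covariate(t, e, x, max_iter: int = 50, tol: float = 1e-10):
    """Newton fit of a single-covariate Cox partial likelihood.

    Breslow handling of tied event times. Returns (beta, SE).
    """
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    ut = np.unique(t[e])
    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * x)
        u, info = 0.0, 0.0
        for tt in ut:
            risk = t >= tt
            s0 = w[risk].sum()
            s1 = (w[risk] * x[risk]).sum()
            s2 = (w[risk] * x[risk] ** 2).sum()
            ev = e & (t == tt)
            d = ev.sum()
            u += x[ev].sum() - d * s1 / s0
            info += d * (s2 / s0 - (s1 / s0) ** 2)
        if info <= 0:
            raise ValidationError("singular Cox information")
        step = u / info
        beta += step
        if abs(step) < tol:
            break
    return beta, 1.0 / np.sqrt(info)


# ---------------------------------------------------------------------------
# ROC cutoff selection


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


def roc_optimal_cutoff(marker_values, outcome_labels,
                       low_is_positive: bool = True) -> CutoffResult:
    """Youden-optimal dichotomization cutoff for a continuous marker.

    Scans every midpoint between adjacent distinct marker values. With
    ``low_is_positive`` (the default — a *low* marker predicts the
    event, as for a tumor suppressor) a sample is called positive when
    its value is below the cutoff. Ties on J break toward higher
    sensitivity, then toward the lower cutoff.
    """
    x = np.asarray(marker_values, dtype=float)
    y = np.asarray(outcome_labels, dtype=bool)
    if y.all() or not y.any():
        raise ValidationError("both outcome classes must be present")
    distinct = np.unique(x)
    if distinct.size < 2:
        raise ValidationError("constant marker: no candidate cutoffs")
    if not low_is_positive:
        x = -x
        distinct = np.unique(x)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos, n_neg = y.sum(), (~y).sum()
    best = None
    for c in mids:
        pred = x < c
        sens = (pred & y).sum() / n_pos
        spec = (~pred & ~y).sum() / n_neg
        j = sens + spec - 1.0
        key = (j, sens, -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec, j)
    _, c, sens, spec, j = best
    cutoff = -c if not low_is_positive else c
    return CutoffResult(cutoff=float(cutoff), sensitivity=float(sens),
                        specificity=float(spec), youden_j=float(j))


# ---------------------------------------------------------------------------
# end-to-end stratification


@dataclass
class StratifiedComparison:
    cutoff: float
    cutoff_result: CutoffResult | None
    groups: pd.Series
    km_low: KMCurve
    km_high: KMCurve
    logrank: LogrankResult
    hr: HazardRatioResult


def stratify_and_compare(marker: pd.Series, clinical: pd.DataFrame,
                         cutoff_policy="roc",
                         exposed: str = "low") -> StratifiedComparison:
    """Cutoff -> groups -> KM + log-rank + hazard ratio, end to end.

    Parameters
    ----------
    marker : pandas.Series
        Continuous per-sample marker (a gene's expression, or a
        signature score), indexed by sample id.
    clinical : pandas.DataFrame
        Indexed by sample id, columns ``time`` and ``event``.
    cutoff_policy : "roc", "median", or a number
        How to choose the low/high cutoff. ``roc`` maximizes Youden's J
        against event-by-end-of-follow-up as the outcome label;
        ``median`` uses the marker median; a number is used as-is.
        Samples <= cutoff are "low".
    exposed : str
        Which group the hazard ratio is reported for ("low" for a
        protective marker like ING4, "high" for a risk score).
    """
    common = marker.index.intersection(clinical.index)
    if len(common) == 0:
        raise ValidationError("marker and clinical share no samples")
    m = marker.loc[common].astype(float)
    cl = clinical.loc[common]
    tvals = cl["time"].to_numpy(dtype=float)
    evals = cl["event"].to_numpy(dtype=bool)
    cutoff_result = None
    if isinstance(cutoff_policy, str) and cutoff_policy == "roc":
        cutoff_result = roc_optimal_cutoff(m.to_numpy(), evals)
        cutoff = cutoff_result.cutoff
    elif isinstance(cutoff_policy, str) and cutoff_policy == "median":
        cutoff = float(np.median(m.to_numpy()))
    elif isinstance(cutoff_policy, str):
        raise ValidationError(f"unknown cutoff policy {cutoff_policy!r}")
    else:
        cutoff = float(cutoff_policy)
    groups = pd.Series(np.where(m > cutoff, "high", "low"), index=m.index,
                       name="group")
    if (groups == "low").all() or (groups == "high").all():
        raise ValidationError("degenerate cutoff: one group is empty")
    low, high = groups == "low", groups == "high"
    return StratifiedComparison(
        cutoff=cutoff, cutoff_result=cutoff_result, groups=groups,
        km_low=km_curve(tvals[low], evals[low]),
        km_high=km_curve(tvals[high], evals[high]),
        logrank=logrank_test(tvals, evals, groups.to_numpy()),
        hr=hazard_ratio(tvals, evals, groups.to_numpy(), exposed=exposed))
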