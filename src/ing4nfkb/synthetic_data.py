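"""Seeded synthetic cohorts with known ground truth for every pipeline input.

Three generators mirror the three real data shapes:

* :func:`gen_tma_cohort` — punch-level ordinal IHC scores for ING4 and
  p-p65 on a tumor array (2-3 punches per tumor, ordinal noise, a small
  non-evaluable fraction), with p-p65 negatively coupled to the latent
  ING4 level through a logistic link and lymph-node positivity enriched
  in ING4-low / p-p65-high tumors by a configurable odds multiplier;
* :func:`gen_expression_cohort` — a genes x samples matrix in which each
  signature gene is negatively coupled to ING4 with strength ``beta``,
  plus independent filler genes, plus exponential survival whose hazard
  is multiplied by ``true_hr`` in the ING4-low (below-median) half, with
  independent uniform censoring calibrated to the requested rate;
* :func:`gen_ct_table` — replicated qPCR Ct values realizing specified
  true fold changes (reference gene flat across conditions, target Ct
  shifted by -log2(fold) plus normal replicate noise).

One :class:`SimulationConfig` seed drives independent per-generator
substreams (``numpy.random.SeedSequence`` spawn keys), so adding a
generator never perturbs the draws of another. Identical config + seed
gives byte-identical outputs.

Default cohort sizes follow the study design this pipeline models: 249
tumors on the array, 60 expression profiles, a 25-gene signature.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .io_formats import ExpressionCohort, CtTable, PunchTable, ValidationError

__all__ = [
    "SimulationConfig",
    "gen_tma_cohort",
    "gen_expression_cohort",
    "gen_ct_table",
]

_STREAMS = {"tma": 0, "expression": 1, "ct": 2}


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the synthetic cohorts.

    Times are in years; hazards in 1/year. ``beta`` is the strength of
    the ING4 -> target-gene repression (expression units per SD of log
    ING4); ``pp65_coupling`` the log-odds decrease of p-p65-high per
    IHC-score unit of latent ING4; ``ln_odds_multiplier`` the odds
    multiplier for lymph-node positivity in ING4-low/p-p65-high tumors.
    """

    seed: int = 0
    # TMA arm
    n_tumors: int = 249
    punch_noise: float = 0.3          # SD of ordinal scoring noise
    punch_missing_rate: float = 0.05  # non-evaluable punch fraction
    pp65_coupling: float = 1.0
    pp65_base_logit: float = -0.6     # marginal p-p65-high fraction ~ 0.27
    ln_base_rate: float = 0.33
    ln_odds_multiplier: float = 2.5
    # expression/survival arm
    n_samples: int = 60
    n_signature_genes: int = 25
    n_filler_genes: int = 50
    beta: float = 1.0
    expression_noise: float = 1.0
    true_hr: float = 3.0
    baseline_hazard: float = 0.15
    censor_rate: float = 0.2
    # qPCR arm
    ct_noise: float = 0.0
    n_replicates: int = 3
    reference_gene: str = "GAPDH"

    def __post_init__(self):
        if self.beta < 0 or self.punch_noise < 0 or self.ct_noise < 0:
            raise ValidationError("noise/coupling parameters must be >= 0")
        if self.true_hr <= 0 or self.baseline_hazard <= 0:
            raise ValidationError("hazards must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValidationError("censor_rate must be in [0, 1)")
        if not 0 <= self.punch_missing_rate < 1:
            raise ValidationError("punch_missing_rate must be in [0, 1)")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream generator for one data arm."""
        ss = np.random.SeedSequence(self.seed,
                                    spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# TMA punch scores


def _punch_scores(rng, latent, sigma, n_punches, missing_rate):
    rows = []
    for i, (lat, k) in enumerate(zip(latent, n_punches)):
        for p in range(k):
            if rng.uniform() < missing_rate:
                rows.append(np.nan)
            else:
                s = np.clip(np.rint(lat + rng.normal(0.0, sigma)), 0, 3)
                rows.append(float(s))
    return rows


def gen_tma_cohort(config: SimulationConfig):
    """Simulate a punch table for ING4 and p-p65 plus LN annotations.

    Returns ``(PunchTable, annotations, truth)``. ``annotations`` has
    one row per tumor with ``ln_positive``; ``truth`` records the latent
    ING4/p-p65 levels and the true low/high calls at the 1.5 cutoff.
    """
    rng = config.rng("tma")
    n = config.n_tumors
    tumor_ids = [f"T{i + 1:04d}" for i in range(n)]
    ing4_latent = rng.uniform(0.0, 3.0, size=n)
    # logistic link: high latent ING4 pushes p-p65 down
    eta = (config.pp65_base_logit
           - config.pp65_coupling * (ing4_latent - 1.5)
           + rng.normal(0.0, 1.0, size=n))
    pp65_latent = 3.0 * expit(eta)
    n_punches = rng.choice([2, 3], size=n)  # ~half double, half triple
    records = []
    for marker, latent in (("ING4", ing4_latent), ("pP65", pp65_latent)):
        scores = _punch_scores(rng, latent, config.punch_noise, n_punches,
                               config.punch_missing_rate)
        j = 0
        for i, tid in enumerate(tumor_ids):
            for p in range(n_punches[i]):
                records.append((tid, marker, f"{tid}-{marker}-p{p + 1}",
                                scores[j]))
                j += 1
    punch_df = pd.DataFrame(records,
                            columns=["tumor_id", "marker", "punch_id",
                                     "score"])
    ing4_low = ing4_latent < 1.5
    pp65_high = pp65_latent >= 1.5
    ln_logit = logit(config.ln_base_rate) \
        + np.log(config.ln_odds_multiplier) * (ing4_low & pp65_high)
    ln_positive = rng.uniform(size=n) < expit(ln_logit)
    annotations = pd.DataFrame({"tumor_id": tumor_ids,
                                "ln_positive": ln_positive.astype(int)})
    truth = {"ing4_latent": ing4_latent, "pp65_latent": pp65_latent,
             "ing4_low": ing4_low, "pp65_high": pp65_high,
             "n_punches": n_punches}
    return PunchTable(punch_df), annotations, truth


# ---------------------------------------------------------------------------
# expression + survival


def _uniform_censor_horizon(hazards, weights, target_rate):
    """Horizon c such that C ~ U(0, c) censors the target fraction.

    For exponential T with rate h, P(T > C) = (1 - exp(-h c)) / (h c);
    the overall rate averages over the mixture of arms.
    """
    def rate(c):
        return float(np.sum(weights * (1.0 - np.exp(-hazards * c))
                            / (hazards * c))) - target_rate

    # rate(c) -> 1 as c -> 0 and -> 0 as c -> inf; bracket and solve
    lo, hi = 1e-9, 1.0
    while rate(hi) > 0:
        hi *= 10.0
        if hi > 1e12:
            raise ValidationError("cannot calibrate censoring horizon")
    return brentq(rate, lo, hi)


def gen_expression_cohort(config: SimulationConfig):
    """Simulate an expression cohort with coupled survival.

    ING4 is log-normal; each signature gene g is
    ``baseline_g - beta * z(log ING4) + noise``; filler genes are
    independent. Survival is exponential with hazard
    ``baseline_hazard * true_hr`` for ING4-low (<= median) samples and
    ``baseline_hazard`` otherwise; censoring is an independent uniform
    time calibrated so the expected censored fraction is
    ``censor_rate``. Returns ``(ExpressionCohort, truth)``.
    """
    rng = config.rng("expression")
    n = config.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    log_ing4 = rng.normal(3.0, 0.5, size=n)
    ing4 = np.exp(log_ing4)
    z = (log_ing4 - log_ing4.mean()) / log_ing4.std()
    sig_genes = [f"NFKBTG{i + 1:02d}" for i in
                 range(config.n_signature_genes)]
    filler = [f"FILLER{i + 1:03d}" for i in range(config.n_filler_genes)]
    rows = {"ING4": ing4}
    for g in sig_genes:
        base = rng.uniform(4.0, 8.0)
        rows[g] = base - config.beta * z \
            + rng.normal(0.0, config.expression_noise, size=n)
    for g in filler:
        base = rng.uniform(4.0, 8.0)
        rows[g] = base + rng.normal(0.0, 1.0, size=n)
    values = pd.DataFrame(rows, index=sample_ids).T
    ing4_low = ing4 <= np.median(ing4)
    hazard = config.baseline_hazard * np.where(ing4_low, config.true_hr,
                                               1.0)
    t_event = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        arm_h = np.array([config.baseline_hazard * config.true_hr,
                          config.baseline_hazard])
        w = np.array([ing4_low.mean(), 1.0 - ing4_low.mean()])
        horizon = _uniform_censor_horizon(arm_h, w, config.censor_rate)
        c = rng.uniform(0.0, horizon, size=n)
        time = np.minimum(t_event, c)
        event = t_event <= c
    else:
        time, event = t_event, np.ones(n, dtype=bool)
    # guard against zero times from float underflow
    time = np.maximum(time, 1e-9)
    clinical = pd.DataFrame({"time": time, "event": event},
                            index=pd.Index(sample_ids, name="sample"))
    cohort = ExpressionCohort(values=values, clinical=clinical)
    truth = {"signature_genes": sig_genes, "ing4_low": ing4_low,
             "event_time": t_event, "hazard": hazard,
             "beta": config.beta, "true_hr": config.true_hr}
    return cohort, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables


def gen_ct_table(config: SimulationConfig, true_folds,
                 condition: str = "PMA", baseline: str = "vehicle",
                 sample_id: str = "S1") -> CtTable:
    """Simulate a Ct table realizing given true fold changes.

    ``true_folds`` maps gene -> fold change of ``condition`` vs
    ``baseline``. The reference gene sits at Ct 20 in both conditions;
    each target starts at Ct 28 in the baseline and is shifted by
    -log2(fold) in the condition, with N(0, ct_noise) per replicate.
    """
    for g, f in true_folds.items():
        if f <= 0:
            raise ValidationError(f"non-positive fold for {g!r}")
    # substream keyed on the sample label so two lines simulated under one
    # config get independent replicate noise
    key = zlib.crc32(sample_id.encode())
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed,
                               spawn_key=(_STREAMS["ct"], key)))
    rows = []

    def add(gene, cond, base_ct, noisy=True):
        for rep in range(1, config.n_replicates + 1):
            ct = base_ct
            if noisy:
                ct += rng.normal(0.0, config.ct_noise)
            rows.append((sample_id, gene, cond, rep, ct))

    # reference gene is held constant across conditions and replicates:
    # replicate noise is a property of the target measurements here
    for cond in (baseline, condition):
        add(config.reference_gene, cond, 20.0, noisy=False)
    for gene, fold in true_folds.items():
        add(gene, baseline, 28.0)
        add(gene, condition, 28.0 - np.log2(fold))
    df = pd.DataFrame(rows, columns=["sample", "gene", "condition",
                                     "replicate", "ct"])
    return CtTable(df, reference_gene=config.reference_gene)
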