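# Methods

This note documents the statistical procedures the package implements,
the choices made where the analysis convention was genuinely open, what
the synthetic generators do and do not emulate, and known limitations.

## ΔΔCt quantification

Fold change is `2^(−ΔΔCt)` with a fixed amplification efficiency of 2
(no efficiency correction) and a single reference gene (GAPDH by
default). Replicate wells are averaged **on the Ct scale** before any
differencing — averaging folds instead would make the estimate depend
on replicate pairing and is not standard practice. Two exact invariants
follow and are property-tested: swapping condition and baseline inverts
the fold, and adding a constant to every Ct (a plate offset) leaves it
unchanged.

Signature-derivation thresholds follow the wording of the assays they
model: induction is **strict** (`fold > 2`, "more than 2-fold"), and
both repression tiers are **inclusive** (`ratio ≥ 2`, `ratio ≥ 4`,
"4-fold or higher"); whether the 2-fold repression boundary was meant
strictly is not documented, so the inclusive form was chosen for
consistency with the 4-fold tier — boundary-exact ratios are measure-zero
in practice. The repression ratio is the ratio of PMA-induction folds
between the control and ING4-overexpressing lines (e.g. 1070/35 ≈ 30.6
for IL8), which matches the printed arithmetic of the assays; a direct
ING4-vs-control expression contrast under PMA can be substituted by
computing those folds and passing them through the same cascade.

## TMA scoring and association

Tumor-level IHC score = arithmetic mean of evaluable punches (2–3 per
tumor; non-evaluable punches dropped, tumors with no evaluable punch
excluded *per marker*, never listwise — each pairwise analysis keeps its
own maximal n). Dichotomization at 1.5 sends the boundary to "high"
(`< 1.5` low, `≥ 1.5` high). Averaging precedes dichotomization; voting
per punch would be a different estimator.

Fisher's exact test is the two-sided point-probability version: sum the
hypergeometric probabilities of all tables with the observed margins
whose point probability is ≤ the observed one. A relative tolerance of
1e−9 in that comparison keeps exact rational ties together despite
float rounding. The implementation is validated against both an exact
rational enumeration oracle and an independent library implementation,
exhaustively for all tables with total ≤ 30.

Display percentages round half away from zero (so 12.5% → 13%), which
reproduces the conventional presentation of count tables; two rows of
the bundled pathology table (the grade-1 and grade-3 rows) carry
printed percentages inconsistent with their own counts under any
rounding and are excluded from the rounding-reproduction check.

## The median-vote gene score

Per gene, the median is computed **within the dataset being scored**
(midpoint interpolation for even n) and never transferred across
datasets; a sample votes 1 for a gene only when strictly above the
median, so ties — including entirely constant genes — vote 0. The score
is the vote sum. Consequences, all property-tested: scores are invariant
under strictly increasing per-gene transforms; for a gene with distinct
values exactly ⌊n/2⌋ samples vote 1, with ties at most that many; an
all-equal cohort scores 0 everywhere.

Signature genes absent from a dataset are dropped with a warning and
the achievable maximum score shrinks accordingly (mirroring real use,
where platforms rarely carry a full signature). The ING4-low/high split
used when comparing score means defaults to the marker's within-dataset
median with ties going low — chosen for symmetry with the score's own
median convention, since no single convention is canonical — and any
explicit cutoff (e.g. ROC-derived) can be supplied instead.

## Survival analysis

Kaplan–Meier, log-rank and hazard ratios are computed from first
principles (and cross-checked in the test suite against lifelines):

* **KM**: product-limit estimator; subjects censored at an event time
  count as at risk at that time (events precede censorings at ties).
  With no censoring it reduces exactly to the empirical survival
  function. Restricted mean survival time (area under the curve to a
  horizon τ) is provided as the scalar summary used in direction checks,
  because pointwise curve dominance is not guaranteed at finite n even
  under a strong true hazard ratio.
* **Log-rank**: at each distinct event time, group-1 events are compared
  with their hypergeometric expectation; χ² = (O₁−E₁)²/V on 1 df. The
  statistic is exactly invariant to label swap.
* **Hazard ratio**: the default is the Mantel–Haenszel one-step
  ln HR = (O₁−E₁)/V with SE = 1/√V — consistent with the log-rank
  machinery and exactly satisfying HR(swapped) = 1/HR. Being a score
  approximation expanded at the null, it acquires a small away-from-null
  bias for large effects (~+0.09 on the log scale at true HR = 3 with
  500 subjects/arm in our simulations); the one-covariate Cox partial
  likelihood fit (`method="cox"`, Newton iteration, Breslow ties) is the
  consistent alternative and is the estimator used for parameter-recovery
  validation.
* **ROC cutoff**: all midpoints between adjacent distinct marker values
  are scanned and Youden's J = sensitivity + specificity − 1 maximized
  (ties → higher sensitivity, then lower cutoff); the outcome label is
  event-by-end-of-follow-up, and by default a *low* marker predicts the
  event (the tumor-suppressor orientation). Note that the maximal J is
  upward-biased under the null, as for any optimized cutpoint.

## Synthetic cohorts

The generators emulate the statistical structure the analyses assume,
with explicit ground truth:

* **TMA arm** (default 249 tumors): latent per-tumor ING4 uniform on
  [0,3]; punches = clamp(round(latent + N(0, σ))), 2–3 per tumor with a
  5% non-evaluable rate; latent p-p65 negatively coupled through a
  logistic link (baseline logit −0.6 ≈ 27% p-p65-high marginally);
  lymph-node positivity at base rate 0.33 with a configurable odds
  multiplier for ING4-low ∧ p-p65-high tumors.
* **Expression/survival arm** (default 60 samples, 25 signature genes —
  the scored-signature size): ING4 log-normal; signature gene g =
  baseline_g − β·z(log ING4) + N(0,1); filler genes independent.
  Survival is exponential with hazard `baseline_hazard · true_hr` for
  the ING4-below-median half (hazards in 1/year, baseline 0.15 ≈ a
  median time-to-recurrence of ~4–5 years in the high-risk group);
  censoring is an independent Uniform(0, c) time with the horizon c
  solved numerically so the expected censored fraction equals
  `censor_rate` (default 20%). Proportional hazards is exactly true by
  construction, making hazard-ratio recovery a clean validation surface,
  and the hazard is keyed to the same ING4-median split the scoring
  stage uses, so generator truth and pipeline estimate address the same
  contrast.
* **qPCR arm**: the reference gene is constant across conditions and
  replicates; target Ct = 28 − log2(fold) in the treated condition with
  N(0, σ_c) per replicate well. With σ_c = 0 every programmed fold is
  recovered to machine precision.

One seed drives independent per-generator substreams (SeedSequence
spawn keys), so adding or reordering generator calls never perturbs
another stream, and identical config + seed is byte-identical.

What the generators do **not** emulate: probe- and batch-level
microarray noise, platform-dependent dynamic range, correlated
censoring, pathologist drift, or inter-gene correlation beyond the
single shared ING4 axis. Passing the synthetic validations therefore
demonstrates correctness of the estimators under the stated model, not
robustness to real-data artifacts.

## Problem sizes in the validation suite

Calibration checks use 1000 null replicates at 50 subjects/arm
(log-rank type-I error), 500 replicates for CI coverage at HR = 1, and
single seeded cohorts of 500/arm for HR recovery at programmed
HR ∈ {1, 2, 3} (tolerance |ln(ĤR/HR)| < 0.25); direction checks use
200-sample cohorts with coupling β = 2. The Fisher implementation is
checked exhaustively over all 2×2 tables with total ≤ 30.

## Known limitations

* Single reference gene, no efficiency correction, no Ct calling from
  raw fluorescence.
* No multivariate or penalized Cox modeling, competing risks or
  interval censoring; the Cox fit is single-covariate by design.
* The GEO SOFT reader handles the GDS dataset-table dialect only, from
  local files; multi-probe genes collapse to the probe with the highest
  mean expression (a common signature-scoring convention — overridable
  to per-symbol averaging), since the original probe-collapse rule for
  such analyses is generally unreported.
* Scores are unweighted votes; continuous enrichment-style scores are
  out of scope.
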