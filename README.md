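# ing4nfkb

Analysis pipeline linking the ING4 tumor suppressor to NF-κB activation
and outcome in breast cancer. It is written for computational biologists
who want to reproduce, extend or stress-test this style of analysis:
marker scoring on tissue microarrays (TMAs), qPCR-derived gene
signatures, and survival stratification — with seeded synthetic cohorts
so every stage can be validated against known ground truth without any
external downloads.

## What it computes

**ΔΔCt fold changes and the signature cascade.** For a target gene and a
reference gene (GAPDH), replicate-averaged cycle thresholds give

    ΔΔCt = (Ct_gene,cond − Ct_ref,cond) − (Ct_gene,base − Ct_ref,base),
    fold = 2^(−ΔΔCt).

Genes induced more than 2-fold by PMA in a control line form the induced
set; within it, genes whose induction is blunted ≥2-fold (ratio of
induction folds, control / ING4-overexpressing line) form the broad
repressed tier and ≥4-fold the stringent tier (tiers always nest).

**TMA IHC statistics.** Punch-level ordinal scores (0–3) are averaged
per tumor, dichotomized at 1.5 (`< 1.5` → marker-low), cross-tabulated,
and tested with a two-sided point-probability Fisher exact test
(hypergeometric enumeration at fixed margins).

**The ING4/NF-κB gene score.** For a signature gene set, each tumor gets
+1 per gene expressed strictly above that gene's median *within the
dataset being scored* (ties score 0); the score is the vote sum in
[0, |gene set|]. Implemented as a scikit-learn style transformer
(`SignatureScorer`), so it composes with sklearn pipelines. Group means
are compared with an unpaired two-tailed pooled-variance t-test.

**Survival stratification.** ROC/Youden-optimal (or median, or explicit)
cutoffs split a cohort on a continuous marker; Kaplan–Meier curves, the
log-rank test and hazard ratios (Mantel–Haenszel one-step by default, a
one-covariate Cox fit as the alternative) are computed from first
principles.

**Synthetic cohorts.** `SimulationConfig` + three generators emulate
every input with programmed truth: ordinal punch scores with scoring
noise, expression matrices with negative ING4→target coupling,
exponential survival with a group-dependent hazard ratio and calibrated
independent censoring, and Ct tables realizing specified folds.

## Worked example

```python
from ing4nfkb import (SimulationConfig, gen_expression_cohort,
                      fit_score_model, score_samples,
                      split_by_marker_gene, compare_group_scores,
                      stratify_and_compare)

cfg = SimulationConfig(seed=3, n_samples=200, beta=2.0, true_hr=3.0)
cohort, truth = gen_expression_cohort(cfg)

model = fit_score_model(cohort, truth["signature_genes"])
scores = score_samples(cohort, model)["score"]
labels = split_by_marker_gene(cohort, "ING4")
cmp = compare_group_scores(scores, labels)
print(cmp.means, cmp.p)
# (3.77, 21.23) 2.68e-71   -> ING4-low tumors carry far higher scores

res = stratify_and_compare(scores.astype(float), cohort.clinical,
                           "median", exposed="high")
print(round(res.hr.hr, 2), round(res.logrank.p, 12))
# 2.87 1.576e-09           -> high-score tumors recur ~3x faster
```

The two printed results recover the programmed truth: with coupling
`beta = 2` the ING4-low half of the cohort accumulates most of the 25
signature votes (group means 21.2 vs 3.8), and stratifying on the score
recovers a hazard ratio near the programmed `true_hr = 3`.

The same stages are available from the shell:

```sh
ing4nfkb simulate --seed 1 --outdir out/sim
ing4nfkb signature-score --expression out/sim/expression.tsv \
    --genes out/sim/signature_genes.txt --outdir out/score
ing4nfkb survive --expression out/sim/expression.tsv \
    --clinical out/sim/clinical.tsv --marker ING4 \
    --cutoff-policy roc --outdir out/surv
ing4nfkb tma-assoc --punches out/sim/punches.tsv --outdir out/tma
```

Every command writes a manifest (input hashes, config, library
versions); reruns with the same seed are bit-identical.

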