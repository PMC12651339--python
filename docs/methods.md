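# Methods

## Problem and scope

The package implements the statistical side of an external validation of a
multi-label chest-radiograph (CXR) triage system. The system emits, for each
study, a probability score per pathology channel — cardiomegaly,
pneumothorax, pleural effusion, opacity, mass, consolidation — plus a
general-abnormality ("yesfinding") channel. The analysis has two stages:

1. **Per-channel operating points.** For each channel, an empirical ROC
   curve is built against that channel's binary ground truth, and the
   optimal probability threshold is chosen by maximizing Youden's
   J = sensitivity + specificity − 1.
2. **Study-level ensembles.** Four rules aggregate the score vector into a
   single normal/abnormal triage call, which is then evaluated as a binary
   diagnostic test: sensitivity, specificity, accuracy, PPV, NPV, F1 with
   95% confidence intervals, AUROC where the rule has an underlying
   continuous score, paired DeLong and McNemar comparisons between rules,
   and a false-negative "rescue" crosstab.

Image processing, report labeling and clinical integration are out of scope;
the pipeline consumes score tables only.

## Decision conventions

* A study is called positive iff its score is **≥** the threshold; this
  makes every candidate threshold an achievable operating point. Candidate
  thresholds are the unique observed scores plus a supremum sentinel, so the
  ROC curve includes both degenerate endpoints.
* Youden ties are broken toward the **highest** threshold (favoring
  specificity). J values within 1e−12 are treated as tied so that floating
  rounding of equivalent rational fractions cannot flip the choice.
* The hierarchical rule's outer-band tests are strict (< 0.8·θ, > 1.2·θ),
  matching their "significantly below/above" reading; everything else treats
  equality as positive.
* Metrics with a zero denominator (e.g. PPV with no positive calls) are
  reported as explicitly undefined, never coerced to 0, and carry no CI.

## The four ensemble rules

* **Possibility**: abnormal if any channel's score falls in its *high* or
  *certain* qualitative-likelihood bin. The commercial product's bin edges
  are not public; the default here sets each channel's *high* edge at its
  Youden threshold and *certain* at the midpoint between that and 1 (bins
  closed at the lower edge). Under these defaults the possibility rule
  coincides with the threshold rule — the two differ only when bespoke bin
  edges are supplied, which the configuration allows.
* **Threshold**: abnormal if any channel is at/above its Youden threshold.
  By the any-rule monotonicity this rule has sensitivity ≥ and specificity ≤
  every single-channel rule, and empirically the highest sensitivity and
  lowest specificity of the four strategies.
* **Weighted sum**: Σ w_c·s_c with w = 2.0 for the general channel and 1.0
  for the six specific channels (fixed constants, not learned); the cutoff
  is itself Youden-optimized by ROC analysis of the sum against study-level
  truth. Decisions are invariant under common positive rescaling of weights
  and cutoff.
* **Hierarchical**: triage on the general score first (normal below
  0.8·θ, abnormal above 1.2·θ); inside the band, any specific finding
  at/above its own threshold means abnormal, else fall back to the general
  score against its plain threshold. The specific-finding check deliberately
  excludes the general channel, which the band already interrogates.

For paired AUROC comparison the threshold rule is given the continuous
statistic max_c s_c/θ_c (its decision is exactly "statistic ≥ 1"); the
weighted-sum rule uses the sum score. The possibility and hierarchical rules
are discrete-output and carry no AUROC, mirroring the validated system's
reporting.

## Inference

* **Proportion CIs** are Wilson score intervals. The method reproduces the
  published intervals exactly (e.g. 892/1045 → 0.831–0.874), which a Wald or
  Clopper–Pearson interval does not; the package treats this as the CI
  method of record.
* **AUROC variance and CIs** use the DeLong structural-components estimator
  in the midrank formulation (tie-robust); paired AUROC comparison uses the
  normal approximation of the difference with covariance from the shared
  components. A zero-variance difference is flagged degenerate with an
  undefined p-value rather than forced to 0 or 1.
* **McNemar** uses the exact two-sided binomial test when the discordant
  count b + c ≤ 25 and the continuity-corrected chi-square otherwise; only
  discordant pairs enter the statistic. Sensitivity comparisons restrict the
  correctness vectors to truth-positive studies, specificity to
  truth-negative.
* α = 0.05 two-sided throughout; no multiplicity correction by default,
  matching the study design; Holm adjustment is available behind a flag.

## Synthetic cohort generator

The generator emulates the validation cohort's statistical structure, not
its images: 1045 studies with exactly 477 abnormal (stratified sampling by
default; Bernoulli mode available), specific-channel prevalences conditional
on abnormality chosen so the expected positive counts equal the published
ones (cardiomegaly 199, pneumothorax 52, effusion 150, opacity 264, mass 56,
consolidation 41 per 1045 studies), and scores from an equal-variance
binormal latent model: negatives N(0, 1), positives N(μ, 1) with
μ = √2·Φ⁻¹(AUC) so the theoretical AUROC equals the per-channel target
(yesfinding 0.911, cardiomegaly 0.968, pneumothorax 0.955, effusion 0.935,
opacity 0.865, mass 0.839, consolidation 0.775). Latents are squashed to
(0, 1) by a fixed monotone map; every downstream statistic depends on scores
only through ranks and thresholds, so the map is immaterial.

Simplifications, hence what passing tests do *not* show about real data:
channels are conditionally independent given abnormality (a shared-liability
co-occurrence knob exists but defaults off — the real co-occurrence
structure is unknown); specific findings never occur in normal studies;
score distributions are binormal rather than the classifier's true, unknown
shape. An optional label-noise proportion flips observed labels while scores
stay conditioned on the true state, emulating imperfect report-derived
ground truth (≈2% audit error in the study); noise therefore attenuates
recovered AUROC, as it would in reality.

All randomness flows through one injectable `numpy` Generator; the same seed
yields a bit-identical cohort.

## Reconstruction of the published ensemble table

The study's raw scores are withheld, so its headline table cannot be
recomputed from data. What *can* be reproduced exactly is its internal
arithmetic: from each strategy's printed sensitivity and specificity and the
cohort composition (477/568), the integer confusion matrix is recovered by
half-up rounding (tp = round(sens·477), tn = round(spec·568)), and accuracy,
PPV, NPV, F1 and the Wilson CIs are recomputed. All derived cells agree with
the printed table at its 3-decimal display precision (display rounding is
half-up; machine outputs keep full precision).

## Problem sizes used in tests

Oracle-equivalence suites run 200 random cohorts of 20–120 studies;
generator recovery uses one 10 000-study cohort (≈3 DeLong standard errors
≈ 0.01–0.03 depending on channel prevalence); bootstrap cross-check of the
DeLong variance uses 2000 resamples of a 500-study cohort; type-I-error
calibration uses 2000 replicates per test (Monte-Carlo SE ≈ 0.005, so the
acceptance band 0.05 ± 0.015). These sizes give the property checks
resolving power a few times finer than the tolerances they assert.

## Known limitations

* The validation cohort's published yesfinding positive count (502) differs
  from its stated abnormal study count (477); the generator follows the
  cohort composition, and the data model accepts either.
* The published hierarchical-rule description is partially garbled; the
  implementation follows the reconstruction documented above (band →
  specific findings → general-score fallback).
* Stage-1 thresholds are fitted on the evaluation cohort itself, as the
  analysis describes; `RunConfig.fixed_thresholds` supports carrying
  thresholds from elsewhere, in which case reported operating points are
  honest out-of-sample estimates.
* With a single unique score value the ROC "curve" collapses to the two
  achievable points (call-nothing and call-everything); the interior point
  coincides with the latter.
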