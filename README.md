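# cxr-triage-validation

Statistical pipeline for externally validating a multi-label chest-radiograph
(CXR) triage system. The system scores each study on seven pathology channels
(a general-abnormality "yesfinding" channel plus cardiomegaly, pneumothorax,
effusion, opacity, mass, consolidation); this package turns those scores into
a reproducible diagnostic-accuracy analysis for the radiology/biostatistics
audience evaluating such tools.

The analysis is two-staged. Stage 1 fits each channel's optimal operating
point by maximizing Youden's J = Se + Sp − 1 on the empirical ROC curve
(positive iff score ≥ threshold). Stage 2 aggregates the per-channel scores
into a single study-level normal/abnormal call under four ensemble rules —
possibility bins, any-channel threshold, weighted sum (yesfinding weighted
2.0, specifics 1.0, cutoff Youden-optimized on the sum), and a hierarchical
band rule — and evaluates each as a binary test: Se, Sp, accuracy, PPV, NPV,
F1 with 95% Wilson CIs, AUROC with DeLong CIs where the rule is rankable,
paired DeLong and McNemar tests between rules, and a false-negative rescue
crosstab. A binormal synthetic-cohort generator (477 abnormal / 568 normal,
per-channel AUROCs and prevalences matching the published system) makes every
stage testable without the withheld imaging data.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 1   # writes results/synthetic_cohort.csv
python analysis/02_fit_thresholds.py             # stage 1
python analysis/03_run_ensembles.py              # stage 2
```

Stage 1 prints each channel's fitted operating point, e.g.:

```
  yesfinding     threshold=0.411 J=0.662 sens=0.868 spec=0.794 AUROC=0.908
  cardiomegaly   threshold=0.489 J=0.813 sens=0.911 spec=0.903 AUROC=0.964
```

(the recovered AUROCs sit within sampling error of the generator's targets,
0.911 and 0.968 here). Stage 2 prints the four ensemble rows:

```
  possibility   acc=0.572 (0.542-0.602) sens=0.990 spec=0.222 AUROC=N/A
  threshold     acc=0.572 (0.542-0.602) sens=0.990 spec=0.222 AUROC=0.880
  weighted_sum  acc=0.855 (0.832-0.875) sens=0.855 spec=0.854 AUROC=0.932
  hierarchical  acc=0.811 (0.786-0.833) sens=0.897 spec=0.738 AUROC=N/A
```

The weighted-sum rule balances sensitivity against specificity and carries
the best accuracy and AUROC; the any-channel threshold rule (and the
possibility rule, which coincides with it under default bin edges) trades
almost-perfect sensitivity for poor specificity — the qualitative ordering
the validated system reported. `analysis/04_paired_comparisons.py` adds the
DeLong/McNemar table, and `analysis/05_reproduce_published_table.py`
rebuilds the published four-ensemble table's confusion matrices and derived
cells from its printed operating points:

```
  weighted_sum  tp=403 fp=79 tn=489 fn=74  acc=0.854 (0.831-0.874)  ppv=0.836 npv=0.869 f1=0.840
```

The same functions are importable directly (`cxrtriage.run_validation`,
`cxrtriage.generate_cohort`, `cxrtriage.reproduce_published_ensemble_table`).
See `docs/methods.md` for conventions, model assumptions and limitations.

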