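"""End-to-end orchestration of the two-stage validation analysis.

Stage 1 fits per-channel ROC curves and Youden-optimal thresholds; stage 2
applies the four ensemble strategies, computes diagnostic-accuracy metrics
with 95% Wilson confidence intervals, runs the paired DeLong and McNemar
comparisons, and tabulates the false-negative rescue crosstab. A run is a
pure function of (cohort, configuration), reproducible byte-for-byte.

`reproduce_published_ensemble_table` is a self-contained arithmetic check: it
reconstructs integer confusion matrices from the published per-strategy
sensitivity/specificity and the cohort composition (477 abnormal, 568
normal), then recomputes accuracy, PPV, NPV, F1 and Wilson CIs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ensembles import (
    EnsembleConfig,
    STRATEGIES,
    ThresholdSet,
    false_negative_crosstab,
    fit_weighted_sum_threshold,
    run_all_strategies,
    weighted_sum_scores,
)
from .paired_tests import (
    delong_ci,
    delong_paired_test,
    delong_variance,
    holm_adjust,
    mcnemar_test,
    metric_correctness,
)
from .roc import (
    BinaryMetrics,
    DegenerateLabelsError,
    confusion_metrics,
    fit_youden_threshold,
    reconstruct_confusion,
)
from .score_table import ScoreTable

#: Published per-strategy (sensitivity, specificity) of the four ensembles on
#: the 1045-study validation cohort; inputs to the reconstruction check.
PUBLISHED_ENSEMBLE_SENS_SPEC = {
    "weighted_sum": (0.845, 0.861),
    "hierarchical": (0.847, 0.815),
    "possibility": (0.922, 0.685),
    "threshold": (0.943, 0.609),
}

#: Published validation cohort composition: abnormal / normal study counts.
PUBLISHED_COHORT_COUNTS = (477, 568)


def round_display(x: float, places: int = 3) -> float:
    """Half-up rounding to the table display precision."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Everything that determines a validation run apart from the cohort."""

    conf_level: float = 0.95
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    alpha: float = 0.05
    holm: bool = False
    refit_thresholds: bool = True  # fit stage-1 thresholds on this cohort
    fixed_thresholds: dict[str, float] | None = None
    seed: int = 0


@dataclass
class ValidationReport:
    """All artifacts of one validation run."""

    thresholds: ThresholdSet
    per_channel: pd.DataFrame
    per_strategy: pd.DataFrame
    comparisons: pd.DataFrame
    crosstab: pd.DataFrame
    confusions: dict[str, BinaryMetrics]
    decisions: dict[str, np.ndarray]
    provenance: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_channel.to_csv(out / "per_channel_metrics.csv", index=False)
        self.per_strategy.to_csv(out / "per_strategy_metrics.csv", index=False)
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        self.crosstab.to_csv(out / "false_negative_crosstab.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)


def _metrics_row(name: str, m: BinaryMetrics) -> dict:
    row = {"name": name, "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn}
    for metric in ("acc", "sens", "spec", "ppv", "npv"):
        val = getattr(m, metric)
        row[metric] = val
        lo, hi = m.ci.get(metric, (np.nan, np.nan))
        row[f"{metric}_lo"], row[f"{metric}_hi"] = lo, hi
    row["f1"] = m.f1
    row["auroc"] = m.auroc
    if m.auroc_ci is not None:
        row["auroc_lo"], row["auroc_hi"] = m.auroc_ci
    else:
        row["auroc_lo"] = row["auroc_hi"] = np.nan
    return row


def fit_stage1(cohort: ScoreTable, config: RunConfig) -> tuple[ThresholdSet, pd.DataFrame, list[str]]:
    """Per-channel Youden thresholds and the per-channel metrics table.

    Channels whose observed labels are single-class are reported as skipped,
    not fatal.
    """
    from .roc import OperatingPoint

    per_channel_rows = []
    ops: dict[str, OperatingPoint] = {}
    skipped: list[str] = []
    for ch in cohort.channels:
        scores, labels = cohort.observed(ch)
        try:
            if config.refit_thresholds or not config.fixed_thresholds:
                op = fit_youden_threshold(scores, labels)
            else:
                thr = config.fixed_thresholds[ch]
                pred = (scores >= thr).astype(int)
                m = confusion_metrics(pred, labels, config.conf_level)
                op = OperatingPoint(threshold=thr, sens=m.sens, spec=m.spec)
        except DegenerateLabelsError:
            skipped.append(ch)
            continue
        ops[ch] = op
        pred = (scores >= op.threshold).astype(int)
        m = confusion_metrics(pred, labels, config.conf_level)
        m.auroc, _ = delong_variance(scores, labels)
        m.auroc_ci = delong_ci(scores, labels, config.conf_level)
        row = _metrics_row(ch, m)
        row["threshold"] = op.threshold
        row["youden_j"] = op.j
        per_channel_rows.append(row)
    return ThresholdSet(per_channel=ops), pd.DataFrame(per_channel_rows), skipped


def run_validation(cohort: ScoreTable, config: RunConfig | None = None) -> ValidationReport:
    """Execute the full two-stage analysis on one cohort."""
    config = config or RunConfig()
    general = cohort.general_channel

    thresholds, per_channel, skipped = fit_stage1(cohort, config)
    if general not in thresholds.per_channel:
        raise DegenerateLabelsError(
            "general-abnormality channel has single-class labels; "
            "study-level validation is impossible"
        )
    if skipped:
        # stage 2 runs over the channels that could be thresholded
        fitted = tuple(ch for ch in cohort.channels if ch in thresholds.per_channel)
        cohort = ScoreTable(
            channels=fitted, data=cohort.data, general_channel=general
        )

    weights = config.ensemble.resolve_weights(cohort.channels, general)
    agg_op = fit_weighted_sum_threshold(cohort, weights, general)
    thresholds.aggregate_threshold = agg_op.threshold

    decisions_raw = run_all_strategies(cohort, thresholds, config.ensemble)
    decisions = {
        s: np.array([d.decision for d in decisions_raw[s]], dtype=int)
        for s in STRATEGIES
    }

    truth = cohort.labels(general)
    keep = ~np.isnan(truth)
    truth_obs = truth[keep].astype(int)

    # continuous scores underlying the two rankable strategies
    ws = weighted_sum_scores(cohort, weights)[keep]
    thr_norm = _threshold_normalized_max(cohort, thresholds)[keep]
    strategy_scores = {"weighted_sum": ws, "threshold": thr_norm}

    confusions: dict[str, BinaryMetrics] = {}
    per_strategy_rows = []
    for s in STRATEGIES:
        m = confusion_metrics(decisions[s][keep], truth_obs, config.conf_level)
        if s in strategy_scores:
            m.auroc, _ = delong_variance(strategy_scores[s], truth_obs)
            m.auroc_ci = delong_ci(strategy_scores[s], truth_obs, config.conf_level)
        confusions[s] = m
        per_strategy_rows.append(_metrics_row(s, m))
    per_strategy = pd.DataFrame(per_strategy_rows)

    comparisons = _paired_comparisons(
        decisions, strategy_scores, truth_obs, keep, config
    )
    crosstab = false_negative_crosstab(cohort, thresholds)

    provenance = {
        "package_version": __version__,
        "n_studies": cohort.n_studies,
        "channels": list(cohort.channels),
        "general_channel": general,
        "conf_level": config.conf_level,
        "alpha": config.alpha,
        "holm": config.holm,
        "seed": config.seed,
        "skipped_channels": skipped,
        "weights": weights,
        "band": [config.ensemble.band_low, config.ensemble.band_high],
        "aggregate_threshold": thresholds.aggregate_threshold,
        "thresholds": {
            ch: op.threshold for ch, op in thresholds.per_channel.items()
        },
        "ci_method": "wilson",
        "youden_tie_break": "highest threshold",
        "decision_rule": "positive iff score >= threshold",
    }
    return ValidationReport(
        thresholds=thresholds,
        per_channel=per_channel,
        per_strategy=per_strategy,
        comparisons=comparisons,
        crosstab=crosstab,
        confusions=confusions,
        decisions=decisions,
        provenance=provenance,
    )


def _threshold_normalized_max(cohort: ScoreTable, thresholds: ThresholdSet) -> np.ndarray:
    """Continuous statistic underlying the threshold strategy: the maximum of
    score/threshold over channels (decision is statistic >= 1)."""
    ratios = np.stack(
        [
            cohort.scores(ch) / max(thresholds.threshold(ch), 1e-12)
            for ch in cohort.channels
        ]
    )
    return ratios.max(axis=0)


def _paired_comparisons(decisions, strategy_scores, truth_obs, keep, config) -> pd.DataFrame:
    """DeLong on every rankable strategy pair, McNemar on every strategy pair
    for accuracy/sensitivity/specificity."""
    labels_of = {
        "weighted_sum": "Weighted Sum",
        "hierarchical": "Hierarchical",
        "possibility": "Possibility",
        "threshold": "Threshold",
    }
    rows = []
    rankable = list(strategy_scores)
    for i, a in enumerate(rankable):
        for b in rankable[i + 1:]:
            label = f"{labels_of[a]} vs. {labels_of[b]}"
            cmp_ = delong_paired_test(
                strategy_scores[a], strategy_scores[b], truth_obs, label
            )
            rows.append(cmp_)
    for i, a in enumerate(STRATEGIES):
        for b in STRATEGIES[i + 1:]:
            label = f"{labels_of[a]} vs. {labels_of[b]}"
            for metric in ("accuracy", "sensitivity", "specificity"):
                ca = metric_correctness(decisions[a][keep], truth_obs, metric)
                cb = metric_correctness(decisions[b][keep], truth_obs, metric)
                rows.append(mcnemar_test(ca, cb, label, metric))
    df = pd.DataFrame(
        {
            "comparison": [r.comparison_label for r in rows],
            "metric": [r.metric for r in rows],
            "test": [r.test_name for r in rows],
            "statistic": [r.statistic for r in rows],
            "p_value": [r.p_value for r in rows],
            "significant": [r.significant for r in rows],
            "degenerate": [r.degenerate for r in rows],
        }
    )
    if config.holm:
        mask = df["p_value"].notna()
        df.loc[mask, "p_adjusted"] = holm_adjust(df.loc[mask, "p_value"].tolist())
        df["significant"] = df.get("p_adjusted", df["p_value"]) < config.alpha
    return df


def reproduce_published_ensemble_table(
    sens_spec: dict[str, tuple[float, float]] | None = None,
    cohort_counts: tuple[int, int] | None = None,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Derived-metrics table from published per-strategy sensitivity and
    specificity plus the cohort composition.

    Reconstructs the integer confusion matrix per strategy (rounding half-up)
    and recomputes accuracy, PPV, NPV, F1 and Wilson CIs — every cell that is
    arithmetic on the published operating points rather than new data.
    """
    sens_spec = sens_spec or PUBLISHED_ENSEMBLE_SENS_SPEC
    n_pos, n_neg = cohort_counts or PUBLISHED_COHORT_COUNTS
    rows = []
    for strategy, (sens, spec) in sens_spec.items():
        tp, fp, tn, fn = reconstruct_confusion(sens, spec, n_pos, n_neg)
        m = BinaryMetrics(tp=tp, fp=fp, tn=tn, fn=fn, conf_level=conf_level)
        row = _metrics_row(strategy, m)
        row["published_sens"] = sens
        row["published_spec"] = spec
        for metric in ("acc", "sens", "spec", "ppv", "npv", "f1"):
            row[f"{metric}_display"] = round_display(row[metric])
        row["acc_lo_display"] = round_display(row["acc_lo"])
        row["acc_hi_display"] = round_display(row["acc_hi"])
        row["sens_lo_display"] = round_display(row["sens_lo"])
        row["sens_hi_display"] = round_display(row["sens_hi"])
        rows.append(row)
    return pd.DataFrame(rows)
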