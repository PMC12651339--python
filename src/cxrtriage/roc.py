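"""ROC construction, AUROC, Youden-J threshold optimization, and binary
diagnostic-accuracy metrics with Wilson confidence intervals.

Decision rule throughout: a study is called positive iff its score is
**greater than or equal to** the threshold, so every candidate threshold is
itself an achievable operating point. The Youden-optimal operating point
maximizes J = sensitivity + specificity - 1; ties are broken toward the
highest threshold (favoring specificity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint


class DegenerateLabelsError(ValueError):
    """Raised when a computation requires both classes but one is absent."""


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve over all candidate thresholds.

    ``thresholds`` is descending and starts with a supremum sentinel
    (``+inf``) at which nothing is called positive, so the curve includes the
    degenerate endpoints (sens 0, spec 1) and (sens 1, spec 0).
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auroc: float


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sens: float
    spec: float

    @property
    def j(self) -> float:
        return self.sens + self.spec - 1.0


def _check_two_class(labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min(initial=1) == 1 or labels.max(initial=0) == 0:
        raise DegenerateLabelsError(
            "AUROC/ROC require at least one positive and one negative label"
        )


def auroc(scores, labels) -> float:
    """Rank-statistic AUROC: P(random positive outscores random negative),
    ties counted 1/2. Identical to the trapezoidal area under the empirical
    ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_class(labels)
    return float(roc_auc_score(labels, scores))


def compute_roc(scores, labels) -> RocCurve:
    """Empirical ROC with candidate thresholds at every unique observed score
    plus a supremum sentinel (positive iff score >= threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_class(labels)
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(
        thresholds=np.asarray(thr, dtype=float),
        sens=np.asarray(tpr, dtype=float),
        spec=1.0 - np.asarray(fpr, dtype=float),
        auroc=float(roc_auc_score(labels, scores)),
    )


def youden_optimal(curve: RocCurve) -> OperatingPoint:
    """Operating point maximizing Youden's J over the curve's candidate
    thresholds; the highest threshold wins ties.

    The supremum sentinel (call-nothing-positive point) is excluded unless it
    is the sole candidate, so a real cutoff is always returned.
    """
    j = curve.sens + curve.spec - 1.0
    candidates = np.isfinite(curve.thresholds)
    if not candidates.any():
        candidates = np.ones_like(j, dtype=bool)
    jc = np.where(candidates, j, -np.inf)
    # thresholds are descending: the first index within rounding error of the
    # maximum J is the highest tied threshold
    idx = int(np.argmax(jc >= jc.max() - 1e-12))
    return OperatingPoint(
        threshold=float(curve.thresholds[idx]),
        sens=float(curve.sens[idx]),
        spec=float(curve.spec[idx]),
    )


def fit_youden_threshold(scores, labels) -> OperatingPoint:
    """Convenience: stage-1 per-channel optimum straight from scores/labels."""
    return youden_optimal(compute_roc(scores, labels))


def wilson_interval(successes: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - conf_level, method="wilson")
    return float(lo), float(hi)


@dataclass
class BinaryMetrics:
    """Confusion counts with the derived diagnostic-accuracy metrics.

    Metrics with a zero denominator are ``None`` (explicitly undefined, never
    coerced to 0) and carry no confidence interval. ``ci`` maps metric name to
    a Wilson interval at ``conf_level``; AUROC and its CI, when the underlying
    score is continuous, are attached by the caller.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    conf_level: float = 0.95
    auroc: float | None = None
    auroc_ci: tuple[float, float] | None = None
    ci: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ci = dict(self.ci)
        for name, (num, den) in {
            "sens": (self.tp, self.tp + self.fn),
            "spec": (self.tn, self.tn + self.fp),
            "acc": (self.tp + self.tn, self.tp + self.tn + self.fp + self.fn),
            "ppv": (self.tp, self.tp + self.fp),
            "npv": (self.tn, self.tn + self.fn),
        }.items():
            if den > 0:
                setattr(self, name, num / den)
                self.ci[name] = wilson_interval(num, den, self.conf_level)
            else:
                setattr(self, name, None)
        if self.ppv is not None and self.sens is not None and (self.ppv + self.sens) > 0:
            self.f1 = 2 * self.ppv * self.sens / (self.ppv + self.sens)
        elif self.ppv == self.sens == 0.0:
            self.f1 = 0.0
        else:
            self.f1 = None

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


def confusion_metrics(predictions, labels, conf_level: float = 0.95) -> BinaryMetrics:
    """Confusion counts and metrics from aligned binary predictions/labels."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape or predictions.size == 0:
        raise ValueError("predictions and labels must be aligned and non-empty")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    return BinaryMetrics(tp=tp, fp=fp, tn=tn, fn=fn, conf_level=conf_level)


def reconstruct_confusion(
    sens: float, spec: float, n_pos: int, n_neg: int
) -> tuple[int, int, int, int]:
    """Recover integer confusion counts (tp, fp, tn, fn) from printed
    sensitivity/specificity and class totals, rounding half-up."""

    def _round_half_up(x: float) -> int:
        return int(math.floor(x + 0.5))

    tp = _round_half_up(sens * n_pos)
    tn = _round_half_up(spec * n_neg)
    return tp, n_neg - tn, tn, n_pos - tp
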