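"""Paired statistical comparison of triage strategies on one cohort.

Two complementary tests, both operating on paired predictions from the same
studies:

* **DeLong** — nonparametric comparison of two correlated AUROCs via
  structural components (midrank formulation, robust to ties). Also supplies
  the sampling variance used for single-AUROC confidence intervals.
* **McNemar** — paired comparison of binary correctness (accuracy,
  sensitivity or specificity), using only the discordant pairs. Exact
  two-sided binomial p-value when the discordant count is small (<= 25),
  continuity-corrected chi-square otherwise.

Significance is judged two-sided at alpha = 0.05 by default; no
multiple-testing correction is applied unless requested (Holm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .roc import DegenerateLabelsError

ALPHA = 0.05

#: Discordant-pair count at or below which the exact binomial test is used.
EXACT_MCNEMAR_MAX = 25


@dataclass(frozen=True)
class PairedComparison:
    comparison_label: str
    metric: str
    test_name: str
    statistic: float
    p_value: float | None
    alpha: float = ALPHA
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < self.alpha


# -- DeLong machinery -------------------------------------------------------


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """AUROC and its positive/negative structural components (midranks)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise DegenerateLabelsError("DeLong requires both classes")
    ranks_all = rankdata(np.concatenate([pos, neg]))
    ranks_pos = rankdata(pos)
    ranks_neg = rankdata(neg)
    # V10[i] = P(pos_i > random neg) with ties 1/2; V01[j] symmetric
    v10 = (ranks_all[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """AUROC and its DeLong sampling variance."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc, v10, v01 = _structural_components(scores, labels)
    m, n = len(v10), len(v01)
    var = _var(v10) / m + _var(v01) / n
    return auc, max(var, 0.0)


def _var(v: np.ndarray) -> float:
    return float(np.var(v, ddof=1)) if len(v) > 1 else 0.0


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.cov(a, b, ddof=1)[0, 1]) if len(a) > 1 else 0.0


def delong_ci(scores, labels, conf_level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for a single AUROC, clipped to [0, 1]."""
    auc, var = delong_variance(scores, labels)
    z = norm.ppf(0.5 + conf_level / 2.0)
    half = z * np.sqrt(var)
    return float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def delong_paired_test(
    scores_a, scores_b, labels, comparison_label: str = "A vs. B"
) -> PairedComparison:
    """Two-sided DeLong test of AUROC_a - AUROC_b on shared labels.

    Covariance of the two AUROC estimates comes from the shared structural
    components. Identical score vectors give difference 0 and p = 1; a zero
    variance with a genuine difference is reported as degenerate with the
    p-value undefined.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != labels.shape or scores_b.shape != labels.shape:
        raise ValueError("score vectors must align with labels")
    auc_a, v10_a, v01_a = _structural_components(scores_a, labels)
    auc_b, v10_b, v01_b = _structural_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    var_diff = (
        (_var(v10_a) + _var(v10_b) - 2 * _cov(v10_a, v10_b)) / m
        + (_var(v01_a) + _var(v01_b) - 2 * _cov(v01_a, v01_b)) / n
    )
    diff = auc_a - auc_b
    if var_diff <= 0:
        if diff == 0.0:
            return PairedComparison(comparison_label, "auroc", "delong", 0.0, 1.0)
        return PairedComparison(
            comparison_label, "auroc", "delong", np.inf, None, degenerate=True
        )
    z = diff / np.sqrt(var_diff)
    p = float(2.0 * norm.sf(abs(z)))
    return PairedComparison(comparison_label, "auroc", "delong", float(z), min(p, 1.0))


# -- McNemar ----------------------------------------------------------------


def mcnemar_test(
    correct_a, correct_b, comparison_label: str = "A vs. B", metric: str = "accuracy"
) -> PairedComparison:
    """McNemar test on paired per-study correctness indicators.

    Discordant counts: b = A correct & B wrong, c = A wrong & B correct.
    Exact two-sided binomial p when b + c <= 25, otherwise chi-square with
    continuity correction. b + c = 0 gives p = 1, flagged degenerate.
    """
    correct_a = np.asarray(correct_a, dtype=int)
    correct_b = np.asarray(correct_b, dtype=int)
    if correct_a.shape != correct_b.shape or correct_a.size == 0:
        raise ValueError("correctness vectors must be aligned and non-empty")
    b = int(np.sum((correct_a == 1) & (correct_b == 0)))
    c = int(np.sum((correct_a == 0) & (correct_b == 1)))
    if b + c == 0:
        return PairedComparison(
            comparison_label, metric, "mcnemar", 0.0, 1.0, degenerate=True
        )
    # concordant cells do not enter the test
    table = [[0, b], [c, 0]]
    exact = (b + c) <= EXACT_MCNEMAR_MAX
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return PairedComparison(
        comparison_label, metric, "mcnemar",
        float(res.statistic), float(min(res.pvalue, 1.0)),
    )


def metric_correctness(decisions, labels, metric: str) -> np.ndarray:
    """Per-study correctness vector for a metric.

    accuracy -> all studies; sensitivity -> truth-positive studies only;
    specificity -> truth-negative studies only.
    """
    decisions = np.asarray(decisions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if decisions.shape != labels.shape:
        raise ValueError("decisions and labels must align")
    correct = (decisions == labels).astype(int)
    if metric == "accuracy":
        out = correct
    elif metric == "sensitivity":
        out = correct[labels == 1]
    elif metric == "specificity":
        out = correct[labels == 0]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if out.size == 0:
        raise DegenerateLabelsError(f"no studies in the {metric} restriction")
    return out


def holm_adjust(p_values) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    k = len(p)
    adj = np.empty(k)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (k - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()
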