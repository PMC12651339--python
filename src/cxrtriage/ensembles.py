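"""Study-level normal/abnormal ensemble decision strategies.

Four rules aggregate the per-pathology probability scores of one study into a
single triage call:

* **possibility** — abnormal if any channel's score falls in its "high" or
  "certain" qualitative-likelihood bin (the rule-based commercial logic).
* **threshold** — abnormal if any channel's score reaches its Youden-optimal
  threshold (any single positive finding flips the study).
* **weighted_sum** — abnormal if the weighted sum of all channel scores
  (general-abnormality channel weighted 2.0, specific channels 1.0) reaches a
  cutoff fitted by ROC analysis on the sum scores themselves.
* **hierarchical** — the general-abnormality score is triaged first: well
  below its threshold (< band_low x theta) means normal, well above
  (> band_high x theta) means abnormal; in the intermediate band any specific
  finding at/above its own threshold means abnormal, otherwise the call falls
  back to the general score against its plain threshold.

Comparisons against thresholds and cutoffs treat equality as positive (>=),
except the hierarchical outer-band tests which are strict, matching their
"significantly below/above" wording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .roc import OperatingPoint, compute_roc, youden_optimal
from .score_table import ScoreTable

STRATEGIES = ("possibility", "threshold", "weighted_sum", "hierarchical")

LIKELIHOOD_LEVELS = ("low", "moderate", "high", "certain")


class EnsembleConfigError(ValueError):
    pass


@dataclass
class ThresholdSet:
    """Stage-1 per-channel Youden operating points, plus the fitted cutoff for
    the weighted-sum aggregate score."""

    per_channel: dict[str, OperatingPoint]
    aggregate_threshold: float | None = None

    def threshold(self, channel: str) -> float:
        try:
            return self.per_channel[channel].threshold
        except KeyError:
            raise EnsembleConfigError(f"no fitted threshold for channel {channel!r}")


@dataclass
class PossibilityBins:
    """Per-channel cut points mapping a probability score to a qualitative
    likelihood in {low, moderate, high, certain}.

    Edges per channel: (t_moderate, t_high, t_certain) with
    t_moderate <= t_high <= t_certain; bins are closed at the lower edge.
    Defaults derive t_high from the channel's Youden threshold,
    t_certain = (t_high + 1)/2 and t_moderate = t_high/2.
    """

    edges: dict[str, tuple[float, float, float]]

    @classmethod
    def from_thresholds(cls, thresholds: ThresholdSet, channels) -> "PossibilityBins":
        edges = {}
        for ch in channels:
            t_high = thresholds.threshold(ch)
            edges[ch] = (t_high / 2.0, t_high, (t_high + 1.0) / 2.0)
        return cls(edges=edges)

    def likelihood(self, channel: str, score: float) -> str:
        try:
            t_mod, t_high, t_cert = self.edges[channel]
        except KeyError:
            raise EnsembleConfigError(f"no possibility bins for channel {channel!r}")
        if score >= t_cert:
            return "certain"
        if score >= t_high:
            return "high"
        if score >= t_mod:
            return "moderate"
        return "low"


@dataclass
class EnsembleConfig:
    """Tunables of the four strategies; defaults follow the validated system."""

    weights: dict[str, float] | None = None
    band_low: float = 0.8
    band_high: float = 1.2
    bins: PossibilityBins | None = None

    def __post_init__(self) -> None:
        if not self.band_low < 1.0 < self.band_high:
            raise EnsembleConfigError("band must satisfy band_low < 1 < band_high")
        if self.weights is not None:
            w = np.array(list(self.weights.values()), dtype=float)
            if (w < 0).any() or not (w > 0).any():
                raise EnsembleConfigError(
                    "weights must be non-negative with at least one positive"
                )

    def resolve_weights(self, channels, general_channel: str) -> dict[str, float]:
        if self.weights is not None:
            return dict(self.weights)
        return {ch: (2.0 if ch == general_channel else 1.0) for ch in channels}


@dataclass(frozen=True)
class EnsembleDecision:
    """One study's triage call under one strategy, with the triggering
    channels/values retained for audit."""

    study_id: str
    strategy: str
    decision: int  # 0 normal, 1 abnormal
    evidence: dict = field(default_factory=dict)


def _record_scores(record, channels) -> dict[str, float]:
    return {ch: float(record[f"{ch}_score"]) for ch in channels}


def possibility_ensemble(record, channels, bins: PossibilityBins) -> EnsembleDecision:
    """Abnormal iff any channel's score maps to the high or certain bin."""
    scores = _record_scores(record, channels)
    evidence = {}
    for ch, s in scores.items():
        lik = bins.likelihood(ch, s)
        if lik in ("high", "certain"):
            evidence[ch] = s
    return EnsembleDecision(
        study_id=str(record["study_id"]),
        strategy="possibility",
        decision=int(bool(evidence)),
        evidence=evidence,
    )


def threshold_ensemble(record, channels, thresholds: ThresholdSet) -> EnsembleDecision:
    """Abnormal iff any channel's score reaches its Youden threshold."""
    scores = _record_scores(record, channels)
    evidence = {
        ch: s for ch, s in scores.items() if s >= thresholds.threshold(ch)
    }
    return EnsembleDecision(
        study_id=str(record["study_id"]),
        strategy="threshold",
        decision=int(bool(evidence)),
        evidence=evidence,
    )


def weighted_sum_score(record, channels, weights: dict[str, float]) -> float:
    """Weighted sum of the study's channel scores."""
    scores = _record_scores(record, channels)
    missing = set(channels) - set(weights)
    if missing:
        raise EnsembleConfigError(f"weights missing for channels {sorted(missing)}")
    return float(sum(weights[ch] * scores[ch] for ch in channels))


def weighted_sum_scores(cohort: ScoreTable, weights: dict[str, float]) -> np.ndarray:
    """Vector of weighted-sum scores over a whole cohort."""
    total = np.zeros(cohort.n_studies)
    for ch in cohort.channels:
        if ch not in weights:
            raise EnsembleConfigError(f"weights missing for channel {ch!r}")
        total += weights[ch] * cohort.scores(ch)
    return total


def fit_weighted_sum_threshold(
    cohort: ScoreTable, weights: dict[str, float], truth_channel: str
) -> OperatingPoint:
    """Youden-optimal cutoff of the weighted-sum score against study-level
    abnormality truth (ROC analysis on the sum scores themselves)."""
    sums = weighted_sum_scores(cohort, weights)
    truth = cohort.labels(truth_channel)
    keep = ~np.isnan(truth)
    return youden_optimal(compute_roc(sums[keep], truth[keep].astype(int)))


def weighted_sum_ensemble(
    record, channels, weights: dict[str, float], cutoff: float
) -> EnsembleDecision:
    """Abnormal iff the weighted-sum score reaches the fitted cutoff."""
    s = weighted_sum_score(record, channels, weights)
    return EnsembleDecision(
        study_id=str(record["study_id"]),
        strategy="weighted_sum",
        decision=int(s >= cutoff),
        evidence={"weighted_sum": s, "cutoff": cutoff},
    )


def hierarchical_ensemble(
    record,
    channels,
    thresholds: ThresholdSet,
    general_channel: str,
    band_low: float = 0.8,
    band_high: float = 1.2,
) -> EnsembleDecision:
    """Multi-step rule triaging on the general-abnormality score first.

    Strictly below band_low x theta -> normal; strictly above band_high x
    theta -> abnormal; inside the band, any *specific* channel at/above its
    own threshold -> abnormal, otherwise fall back to the general score
    against its plain threshold (>=).
    """
    theta = thresholds.threshold(general_channel)
    s_gen = float(record[f"{general_channel}_score"])
    study_id = str(record["study_id"])
    if s_gen < band_low * theta:
        return EnsembleDecision(study_id, "hierarchical", 0,
                                {"branch": "below_band", general_channel: s_gen})
    if s_gen > band_high * theta:
        return EnsembleDecision(study_id, "hierarchical", 1,
                                {"branch": "above_band", general_channel: s_gen})
    specific = [ch for ch in channels if ch != general_channel]
    fired = {
        ch: float(record[f"{ch}_score"])
        for ch in specific
        if float(record[f"{ch}_score"]) >= thresholds.threshold(ch)
    }
    if fired:
        return EnsembleDecision(study_id, "hierarchical", 1,
                                {"branch": "specific_finding", **fired})
    return EnsembleDecision(
        study_id, "hierarchical", int(s_gen >= theta),
        {"branch": "fallback_general", general_channel: s_gen},
    )


def run_all_strategies(
    cohort: ScoreTable,
    thresholds: ThresholdSet,
    config: EnsembleConfig | None = None,
) -> dict[str, list[EnsembleDecision]]:
    """Apply all four strategies to every study; aligned decision vectors."""
    config = config or EnsembleConfig()
    channels = cohort.channels
    general = cohort.general_channel
    weights = config.resolve_weights(channels, general)
    bins = config.bins or PossibilityBins.from_thresholds(thresholds, channels)
    if thresholds.aggregate_threshold is None:
        thresholds.aggregate_threshold = fit_weighted_sum_threshold(
            cohort, weights, general
        ).threshold
    cutoff = thresholds.aggregate_threshold
    out: dict[str, list[EnsembleDecision]] = {s: [] for s in STRATEGIES}
    for _, record in cohort.data.iterrows():
        out["possibility"].append(possibility_ensemble(record, channels, bins))
        out["threshold"].append(threshold_ensemble(record, channels, thresholds))
        out["weighted_sum"].append(
            weighted_sum_ensemble(record, channels, weights, cutoff)
        )
        out["hierarchical"].append(
            hierarchical_ensemble(
                record, channels, thresholds, general,
                config.band_low, config.band_high,
            )
        )
    return out


def false_negative_crosstab(cohort: ScoreTable, thresholds: ThresholdSet):
    """Per-channel false negatives and how many were rescued at study level.

    For each specific channel: studies whose finding the channel missed
    (truth 1, score below threshold), of which how many the
    general-abnormality channel still called abnormal, and how many carried
    another channel's true-positive finding.
    """
    import pandas as pd

    general = cohort.general_channel
    theta_gen = thresholds.threshold(general)
    gen_pos = cohort.scores(general) >= theta_gen
    rows = []
    specific = [ch for ch in cohort.channels if ch != general]
    # true-positive mask per specific channel, for "other channel" rescue
    tp_mask = {
        ch: (cohort.labels(ch) == 1.0)
        & (cohort.scores(ch) >= thresholds.threshold(ch))
        for ch in specific
    }
    for ch in specific:
        lab = cohort.labels(ch)
        fn_mask = (lab == 1.0) & (cohort.scores(ch) < thresholds.threshold(ch))
        n_fn = int(fn_mask.sum())
        n_yes = int((fn_mask & gen_pos).sum())
        other = np.zeros(cohort.n_studies, dtype=bool)
        for oth in specific:
            if oth != ch:
                other |= tp_mask[oth]
        n_other = int((fn_mask & other).sum())
        rows.append(
            {
                "channel": ch,
                "n_false_neg": n_fn,
                "n_rescued_by_yesfinding": n_yes,
                "n_rescued_by_other_channel": n_other,
            }
        )
    return pd.DataFrame(rows)
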