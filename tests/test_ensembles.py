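"""Ensemble decision strategies: boundary conventions, branch semantics,
monotonicity, and the false-negative rescue crosstab."""

import numpy as np
import pandas as pd
import pytest

from cxrtriage import (
    EnsembleConfig,
    PossibilityBins,
    ScoreTable,
    ThresholdSet,
    false_negative_crosstab,
    fit_weighted_sum_threshold,
    hierarchical_ensemble,
    possibility_ensemble,
    run_all_strategies,
    threshold_ensemble,
    weighted_sum_ensemble,
    weighted_sum_score,
)
from cxrtriage.ensembles import EnsembleConfigError
from cxrtriage.roc import OperatingPoint

CHANNELS = ("yesfinding", "opacity", "effusion")


def _record(scores, study_id="s0"):
    rec = {"study_id": study_id}
    for ch, s in zip(CHANNELS, scores):
        rec[f"{ch}_score"] = s
    return pd.Series(rec)


def _thresholds(values=(0.5, 0.6, 0.4)):
    return ThresholdSet(
        per_channel={
            ch: OperatingPoint(threshold=t, sens=0.8, spec=0.8)
            for ch, t in zip(CHANNELS, values)
        }
    )


def _bins(values=(0.5, 0.6, 0.4)):
    return PossibilityBins(
        edges={ch: (t / 2, t, (t + 1) / 2) for ch, t in zip(CHANNELS, values)}
    )


# -- possibility ------------------------------------------------------------

def test_possibility_all_low_scores_is_normal():
    d = possibility_ensemble(_record((0.0, 0.0, 0.0)), CHANNELS, _bins())
    assert d.decision == 0 and d.evidence == {}


def test_possibility_high_bin_triggers_with_evidence():
    d = possibility_ensemble(_record((0.1, 0.7, 0.1)), CHANNELS, _bins())
    assert d.decision == 1 and "opacity" in d.evidence


def test_possibility_closed_lower_bin_edge():
    # score exactly at t_high counts as "high"
    d = possibility_ensemble(_record((0.5, 0.0, 0.0)), CHANNELS, _bins())
    assert d.decision == 1


def test_possibility_missing_bin_is_config_error():
    bins = PossibilityBins(edges={"yesfinding": (0.2, 0.4, 0.7)})
    with pytest.raises(EnsembleConfigError):
        possibility_ensemble(_record((0.1, 0.1, 0.1)), CHANNELS, bins)


# -- threshold --------------------------------------------------------------

def test_threshold_rule_boundary_and_monotonicity():
    thr = _thresholds()
    assert threshold_ensemble(_record((0.4, 0.5, 0.3)), CHANNELS, thr).decision == 0
    # equality is positive
    d = threshold_ensemble(_record((0.5, 0.5, 0.3)), CHANNELS, thr).decision
    assert d == 1
    # adding a firing channel can only flip normal -> abnormal
    base = threshold_ensemble(_record((0.4, 0.5, 0.3)), CHANNELS, thr).decision
    more = threshold_ensemble(_record((0.4, 0.5, 0.9)), CHANNELS, thr).decision
    assert more >= base


# -- weighted sum -----------------------------------------------------------

def test_weighted_sum_score_default_weights():
    weights = {"yesfinding": 2.0, "opacity": 1.0, "effusion": 1.0}
    assert weighted_sum_score(_record((0.0, 0.0, 0.0)), CHANNELS, weights) == 0.0
    assert weighted_sum_score(_record((1.0, 1.0, 1.0)), CHANNELS, weights) == 4.0
    s = weighted_sum_score(_record((0.3, 0.4, 0.5)), CHANNELS, weights)
    doubled = weighted_sum_score(
        _record((0.3, 0.4, 0.5)), CHANNELS, {k: 2 * v for k, v in weights.items()}
    )
    assert doubled == pytest.approx(2 * s)


def test_weighted_sum_seven_channel_range():
    channels = tuple(f"c{i}" for i in range(6)) + ("yesfinding",)
    weights = {ch: 1.0 for ch in channels}
    weights["yesfinding"] = 2.0
    rec = {"study_id": "s", **{f"{ch}_score": 1.0 for ch in channels}}
    assert weighted_sum_score(pd.Series(rec), channels, weights) == pytest.approx(8.0)


def _cohort_from_matrix(scores, yes_labels):
    data = {"study_id": [f"s{i}" for i in range(len(scores))]}
    for j, ch in enumerate(CHANNELS):
        data[f"{ch}_score"] = [row[j] for row in scores]
        data[f"{ch}_label"] = yes_labels if ch == "yesfinding" else [0.0] * len(scores)
    return ScoreTable(channels=CHANNELS, data=pd.DataFrame(data))


def test_fit_weighted_sum_threshold_matches_brute_force(rng):
    n = 80
    scores = rng.random((n, 3))
    labels = (rng.random(n) < 0.5).astype(float)
    if labels.sum() in (0, n):
        labels[0] = 1 - labels[0]
    cohort = _cohort_from_matrix(scores.tolist(), labels.tolist())
    weights = {"yesfinding": 2.0, "opacity": 1.0, "effusion": 1.0}
    op = fit_weighted_sum_threshold(cohort, weights, "yesfinding")
    sums = scores @ np.array([2.0, 1.0, 1.0])
    best_j = max(
        ((sums >= t) & (labels == 1)).sum() / labels.sum()
        + ((sums < t) & (labels == 0)).sum() / (1 - labels).sum()
        - 1
        for t in set(sums)
    )
    assert op.j == pytest.approx(best_j, abs=1e-12)
    # decision invariant under common rescaling of weights and cutoff
    op2 = fit_weighted_sum_threshold(
        cohort, {k: 3 * v for k, v in {"yesfinding": 2.0, "opacity": 1.0, "effusion": 1.0}.items()},
        "yesfinding",
    )
    assert op2.threshold == pytest.approx(3 * op.threshold)
    assert op2.j == pytest.approx(op.j)


def test_weighted_sum_ensemble_cutoff_boundary():
    weights = {"yesfinding": 2.0, "opacity": 1.0, "effusion": 1.0}
    rec = _record((0.5, 0.5, 0.5))  # sum = 2.0
    assert weighted_sum_ensemble(rec, CHANNELS, weights, 2.0).decision == 1
    assert weighted_sum_ensemble(rec, CHANNELS, weights, 2.0001).decision == 0


# -- hierarchical -----------------------------------------------------------

@pytest.mark.parametrize(
    "scores, expected, branch",
    [
        ((0.3, 0.9, 0.9), 0, "below_band"),  # yesfinding < 0.8 * 0.5
        ((0.7, 0.0, 0.0), 1, "above_band"),  # yesfinding > 1.2 * 0.5
        ((0.45, 0.7, 0.0), 1, "specific_finding"),  # in band, opacity fires
        ((0.45, 0.5, 0.3), 0, "fallback_general"),  # in band, 0.45 < 0.5
        ((0.55, 0.5, 0.3), 1, "fallback_general"),  # in band, 0.55 >= 0.5
    ],
)
def test_hierarchical_branches(scores, expected, branch):
    d = hierarchical_ensemble(
        _record(scores), CHANNELS, _thresholds(), "yesfinding", 0.8, 1.2
    )
    assert d.decision == expected
    assert d.evidence["branch"] == branch


def test_hierarchical_degenerate_band_equals_single_channel_rule(rng):
    # band_low = band_high = 1 with no specific channel firing reduces to the
    # plain yesfinding >= threshold rule
    thr = _thresholds()
    for _ in range(50):
        s_yes = rng.random()
        rec = _record((s_yes, 0.0, 0.0))
        d = hierarchical_ensemble(rec, CHANNELS, thr, "yesfinding", 1.0, 1.0)
        assert d.decision == int(s_yes >= 0.5)


# -- full run ---------------------------------------------------------------

def test_run_all_strategies_aligned_and_deterministic(edge_cohort):
    from cxrtriage.pipeline import fit_stage1, RunConfig

    thresholds, _, _ = fit_stage1(edge_cohort, RunConfig())
    out1 = run_all_strategies(edge_cohort, thresholds, EnsembleConfig())
    out2 = run_all_strategies(edge_cohort, thresholds, EnsembleConfig())
    for strat, decisions in out1.items():
        assert len(decisions) == edge_cohort.n_studies
        assert [d.decision for d in decisions] == [d.decision for d in out2[strat]]
        assert all(d.evidence is not None for d in decisions)


def test_threshold_strategy_dominates_single_channel_rules(default_cohort):
    from cxrtriage.pipeline import fit_stage1, RunConfig

    thresholds, _, _ = fit_stage1(default_cohort, RunConfig())
    out = run_all_strategies(default_cohort, thresholds, EnsembleConfig())
    decisions = np.array([d.decision for d in out["threshold"]])
    truth = default_cohort.labels("yesfinding")
    for ch in default_cohort.channels:
        single = (default_cohort.scores(ch) >= thresholds.threshold(ch)).astype(int)
        # any-rule: strictly more positive calls than each member rule
        sens_any = decisions[truth == 1].mean()
        sens_single = single[truth == 1].mean()
        spec_any = 1 - decisions[truth == 0].mean()
        spec_single = 1 - single[truth == 0].mean()
        assert sens_any >= sens_single
        assert spec_any <= spec_single


# -- crosstab ---------------------------------------------------------------

def test_crosstab_reproduces_published_opacity_rescue_counts():
    # constructed cohort: 38 opacity false negatives of which exactly 25 are
    # flagged abnormal by the general channel
    n = 38
    data = {"study_id": [f"s{i}" for i in range(n)]}
    data["opacity_score"] = [0.1] * n  # all below threshold -> all missed
    data["opacity_label"] = [1.0] * n
    data["yesfinding_score"] = [0.9] * 25 + [0.1] * 13
    data["yesfinding_label"] = [1.0] * n
    data["effusion_score"] = [0.0] * n
    data["effusion_label"] = [0.0] * n
    cohort = ScoreTable(channels=CHANNELS, data=pd.DataFrame(data))
    tab = false_negative_crosstab(cohort, _thresholds())
    row = tab.set_index("channel").loc["opacity"]
    assert row["n_false_neg"] == 38
    assert row["n_rescued_by_yesfinding"] == 25
    assert row["n_rescued_by_other_channel"] == 0


def test_crosstab_rescued_never_exceeds_false_negatives(default_cohort):
    from cxrtriage.pipeline import fit_stage1, RunConfig

    thresholds, _, _ = fit_stage1(default_cohort, RunConfig())
    tab = false_negative_crosstab(default_cohort, thresholds)
    assert (tab["n_rescued_by_yesfinding"] <= tab["n_false_neg"]).all()
    assert (tab["n_rescued_by_other_channel"] <= tab["n_false_neg"]).all()


def test_crosstab_zero_false_negatives_zero_rescued():
    data = {
        "study_id": ["a", "b"],
        "yesfinding_score": [0.9, 0.1],
        "yesfinding_label": [1.0, 0.0],
        "opacity_score": [0.9, 0.1],
        "opacity_label": [1.0, 0.0],
        "effusion_score": [0.9, 0.1],
        "effusion_label": [1.0, 0.0],
    }
    cohort = ScoreTable(channels=CHANNELS, data=pd.DataFrame(data))
    tab = false_negative_crosstab(cohort, _thresholds()).set_index("channel")
    assert (tab["n_false_neg"] == 0).all()
    assert (tab["n_rescued_by_yesfinding"] == 0).all()
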