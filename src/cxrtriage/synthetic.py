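"""Synthetic score-cohort generator with the statistical structure the
validation pipeline assumes.

The generator emulates an enriched two-class validation cohort: 1045 studies,
477 abnormal and 568 normal, seven pathology channels whose positive-case
counts and per-channel discrimination match the validated system's published
operating characteristics. Classifier scores follow an equal-variance
binormal latent model — negative-class latents N(0, 1), positive-class
latents N(mu, 1) with mu = sqrt(2) * Phi^{-1}(AUC) so the theoretical AUROC
equals the target exactly — squashed monotonically to (0, 1). Every
downstream statistic depends on scores only through ranks and thresholds, so
the choice of squashing map is immaterial.

Specific-channel labels are drawn conditional on study-level abnormality
(all specific channels absent in normal studies); channels are conditionally
independent given abnormality unless a pairwise co-occurrence knob is set.
An optional label-noise proportion flips each label independently, emulating
imperfect report-derived ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .score_table import DEFAULT_CHANNELS, GENERAL_CHANNEL, ScoreTable

#: Expected positive-case counts per specific channel, out of the default
#: 1045-study cohort (477 abnormal).
DEFAULT_POSITIVE_COUNTS = {
    "cardiomegaly": 199,
    "pneumothorax": 52,
    "effusion": 150,
    "opacity": 264,
    "mass": 56,
    "consolidation": 41,
}

#: Published per-channel discrimination of the validated classifiers.
DEFAULT_TARGET_AUROC = {
    "yesfinding": 0.911,
    "cardiomegaly": 0.968,
    "pneumothorax": 0.955,
    "effusion": 0.935,
    "opacity": 0.865,
    "mass": 0.839,
    "consolidation": 0.775,
}

_DEFAULT_N = 1045
_DEFAULT_N_ABNORMAL = 477


def _default_channel_prevalence() -> dict[str, float]:
    # P(channel positive | study abnormal) so that expected positives over the
    # whole cohort match the published counts
    return {ch: n / _DEFAULT_N_ABNORMAL for ch, n in DEFAULT_POSITIVE_COUNTS.items()}


@dataclass
class CohortSpec:
    """Generative parameters for one synthetic validation cohort.

    Attributes
    ----------
    n_studies
        Cohort size (default 1045).
    abnormal_prevalence
        P(study abnormal); default 477/1045.
    channel_prevalence_given_abnormal
        P(specific channel positive | abnormal) per channel.
    target_auroc
        Theoretical AUROC per channel for the binormal score model.
    label_noise
        Probability each observed label is flipped (default 0).
    stratified
        If True (default), draw exactly round(n * prevalence) abnormal
        studies, mirroring a purposive sampling design; if False, Bernoulli.
    cooccurrence
        Optional shared-liability weight in [0, 1) inducing positive
        pairwise co-occurrence between specific channels (default 0 =
        conditional independence).
    seed
        Generator seed; same seed gives a bit-identical cohort.
    """

    n_studies: int = _DEFAULT_N
    abnormal_prevalence: float = _DEFAULT_N_ABNORMAL / _DEFAULT_N
    channel_prevalence_given_abnormal: dict[str, float] = field(
        default_factory=_default_channel_prevalence
    )
    target_auroc: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_AUROC)
    )
    label_noise: float = 0.0
    stratified: bool = True
    cooccurrence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.abnormal_prevalence <= 1:
            raise ValueError("abnormal_prevalence must be in [0, 1]")
        if not 0 <= self.label_noise <= 1:
            raise ValueError("label_noise must be in [0, 1]")
        for ch, p in self.channel_prevalence_given_abnormal.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {ch!r} must be in [0, 1]")
        for ch, a in self.target_auroc.items():
            if not 0.5 < a < 1:
                raise ValueError(f"target AUROC for {ch!r} must be in (0.5, 1)")

    @property
    def channels(self) -> tuple[str, ...]:
        return (GENERAL_CHANNEL,) + tuple(self.channel_prevalence_given_abnormal)


def binormal_mu(target_auc: float) -> float:
    """Positive-class latent mean of the equal-variance binormal model:
    mu = sqrt(2) * Phi^{-1}(AUC), the unique mean separation whose
    theoretical AUROC Phi(mu / sqrt(2)) equals the target."""
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target AUC must be in (0.5, 1)")
    return float(np.sqrt(2.0) * norm.ppf(target_auc))


def simulate_labels(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw study-level abnormality and per-channel finding labels.

    The general channel's label equals study abnormality; specific channels
    are positive only within abnormal studies. With ``stratified`` the
    abnormal count is exact; otherwise Bernoulli at the prevalence.
    """
    n = spec.n_studies
    if spec.stratified:
        n_abn = int(round(n * spec.abnormal_prevalence))
        abnormal = np.zeros(n, dtype=int)
        abnormal[rng.permutation(n)[:n_abn]] = 1
    else:
        abnormal = (rng.random(n) < spec.abnormal_prevalence).astype(int)
    out = {"study_id": [f"S{i:05d}" for i in range(n)],
           f"{GENERAL_CHANNEL}_label": abnormal.astype(float)}
    specific = list(spec.channel_prevalence_given_abnormal)
    if spec.cooccurrence > 0:
        # shared-liability model: common per-study uniform tilts all channels
        liability = rng.random(n)
    for ch in specific:
        p = spec.channel_prevalence_given_abnormal[ch]
        if spec.cooccurrence > 0:
            u = spec.cooccurrence * liability + (1 - spec.cooccurrence) * rng.random(n)
        else:
            u = rng.random(n)
        lab = ((u < p) & (abnormal == 1)).astype(float)
        out[f"{ch}_label"] = lab
    df = pd.DataFrame(out)
    if spec.label_noise > 0:
        # scores are later drawn from the true state; only the *observed*
        # label is corrupted, so noise attenuates recovered AUROC
        for ch in (GENERAL_CHANNEL, *specific):
            col = f"{ch}_label"
            df[f"{col}_true"] = df[col]
            flip = rng.random(n) < spec.label_noise
            df[col] = np.where(flip, 1.0 - df[col], df[col])
    return df


def simulate_scores(
    labels: pd.DataFrame, spec: CohortSpec, rng: np.random.Generator
) -> ScoreTable:
    """Attach binormal classifier scores to generated labels.

    Per channel: latent N(0,1) for label 0, N(mu,1) for label 1 with mu from
    :func:`binormal_mu`; the latent is squashed to (0, 1) by the standard
    normal CDF centred between the class means. Scores are independent
    across channels given labels.
    """
    df = labels.copy()
    n = len(df)
    for ch in spec.channels:
        mu = binormal_mu(spec.target_auroc[ch])
        true_col = f"{ch}_label_true"
        lab_col = true_col if true_col in df.columns else f"{ch}_label"
        lab = df[lab_col].to_numpy(dtype=float)
        z = rng.standard_normal(n) + mu * np.nan_to_num(lab, nan=0.0)
        df[f"{ch}_score"] = norm.cdf(z - mu / 2.0)
    df = df.drop(columns=[c for c in df.columns if c.endswith("_label_true")])
    cols = ["study_id"]
    for ch in spec.channels:
        cols += [f"{ch}_score", f"{ch}_label"]
    extra = [c for c in df.columns if c not in cols]
    return ScoreTable(channels=spec.channels, data=df[cols + extra])


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> ScoreTable:
    """Labels + scores in one call; ``seed`` overrides ``spec.seed``."""
    spec = spec or CohortSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    return simulate_scores(simulate_labels(spec, rng), spec, rng)


def make_validation_fixture(seed: int = 0) -> ScoreTable:
    """Small deterministic cohort (n = 200) exercising every pipeline branch.

    Contains missing labels, exact score ties across studies, all-zero and
    all-one score rows, and both classes on every channel — for tests that
    need structural edge cases rather than statistical realism.
    """
    spec = CohortSpec(n_studies=200, seed=seed)
    table = generate_cohort(spec)
    df = table.data
    channels = table.channels
    # hand-placed edge cases on the first rows (labels arranged so both
    # classes survive on every channel)
    for ch in channels:
        df.loc[0, f"{ch}_score"] = 0.0
        df.loc[1, f"{ch}_score"] = 1.0
        df.loc[2, f"{ch}_score"] = 0.5  # tie block
        df.loc[3, f"{ch}_score"] = 0.5
        df.loc[0, f"{ch}_label"] = 0.0
        df.loc[1, f"{ch}_label"] = 1.0
    df.loc[4, f"{channels[1]}_label"] = np.nan  # missing label case
    df.loc[5, f"{channels[2]}_label"] = np.nan
    return ScoreTable(channels=channels, data=df)
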