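"""Data model and I/O for per-study multi-channel classifier scores and labels.

A cohort is a flat table with one row per radiographic study. Each pathology
channel contributes a ``<channel>_score`` column (probability in [0, 1]) and a
``<channel>_label`` column (1 = finding present, 0 = absent, blank/"NA" =
label unavailable for that channel). Exactly one channel is the
general-abnormality ("yesfinding") channel, whose label encodes study-level
normal/abnormal truth. Missing labels are a first-class state: a study with a
missing label for a channel is excluded from that channel's metrics, never
coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Channel set of the triage system under validation; the first entry is the
#: general-abnormality channel.
DEFAULT_CHANNELS = (
    "yesfinding",
    "cardiomegaly",
    "pneumothorax",
    "effusion",
    "opacity",
    "mass",
    "consolidation",
)

GENERAL_CHANNEL = "yesfinding"

MISSING_TOKEN = "NA"


class ScoreTableError(ValueError):
    """Malformed or invalid score-table content."""


@dataclass
class ScoreTable:
    """Per-study scores and labels for a declared, ordered set of channels.

    Parameters
    ----------
    channels
        Ordered channel names; must contain the general-abnormality channel.
    data
        One row per study. Required columns: ``study_id``, plus
        ``<channel>_score`` (float in [0, 1]) and ``<channel>_label``
        (0.0, 1.0 or NaN for missing) for every channel. Any further columns
        are carried as study metadata.
    general_channel
        Name of the general-abnormality channel (default ``"yesfinding"``).
    """

    channels: tuple[str, ...]
    data: pd.DataFrame
    general_channel: str = GENERAL_CHANNEL

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.general_channel not in self.channels:
            raise ScoreTableError(
                f"general-abnormality channel {self.general_channel!r} "
                "is not among the declared channels"
            )
        if "study_id" not in self.data.columns:
            raise ScoreTableError("missing 'study_id' column")
        ids = self.data["study_id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ScoreTableError(f"duplicate study_id {dup!r}")
        for ch in self.channels:
            scol, lcol = f"{ch}_score", f"{ch}_label"
            if scol not in self.data.columns:
                raise ScoreTableError(f"missing score column {scol!r}")
            if lcol not in self.data.columns:
                raise ScoreTableError(f"missing label column {lcol!r}")
            s = self.data[scol].to_numpy(dtype=float)
            if len(s) and (not np.isfinite(s).all() or s.min() < 0 or s.max() > 1):
                bad = self.data.loc[
                    ~np.isfinite(s) | (s < 0) | (s > 1), "study_id"
                ].iloc[0]
                raise ScoreTableError(
                    f"score outside [0, 1] for study {bad!r}, channel {ch!r}"
                )
            lab = self.data[lcol].to_numpy(dtype=float)
            obs = lab[~np.isnan(lab)]
            if len(obs) and not np.isin(obs, (0.0, 1.0)).all():
                raise ScoreTableError(f"labels for channel {ch!r} must be 0, 1 or missing")

    # -- accessors ----------------------------------------------------------

    @property
    def n_studies(self) -> int:
        return len(self.data)

    @property
    def study_ids(self) -> list[str]:
        return self.data["study_id"].astype(str).tolist()

    @property
    def metadata_columns(self) -> list[str]:
        core = {"study_id"} | {
            f"{ch}{suf}" for ch in self.channels for suf in ("_score", "_label")
        }
        return [c for c in self.data.columns if c not in core]

    def scores(self, channel: str) -> np.ndarray:
        self._check_channel(channel)
        return self.data[f"{channel}_score"].to_numpy(dtype=float)

    def labels(self, channel: str) -> np.ndarray:
        """Labels as floats with NaN for missing."""
        self._check_channel(channel)
        return self.data[f"{channel}_label"].to_numpy(dtype=float)

    def label_counts(self, channel: str) -> tuple[int, int, int]:
        """(n_pos, n_neg, n_missing) for a channel."""
        lab = self.labels(channel)
        n_missing = int(np.isnan(lab).sum())
        n_pos = int(np.nansum(lab))
        return n_pos, len(lab) - n_pos - n_missing, n_missing

    def observed(self, channel: str) -> tuple[np.ndarray, np.ndarray]:
        """(scores, labels) restricted to studies with an observed label."""
        lab = self.labels(channel)
        keep = ~np.isnan(lab)
        return self.scores(channel)[keep], lab[keep].astype(int)

    def _check_channel(self, channel: str) -> None:
        if channel not in self.channels:
            raise KeyError(f"unknown channel {channel!r}")


def split_by_truth(table: ScoreTable, channel: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition studies into truth-positive and truth-negative for a channel.

    Studies with a missing label for the channel appear in neither frame, so
    ``len(pos) + len(neg) + n_missing == table.n_studies``.
    """
    lab = table.labels(channel)
    pos = table.data[lab == 1.0]
    neg = table.data[lab == 0.0]
    return pos, neg


def read_score_table(
    path,
    channels: tuple[str, ...] | None = None,
    general_channel: str = GENERAL_CHANNEL,
) -> ScoreTable:
    """Read a cohort from delimited text (CSV, UTF-8, header row).

    Channel names are inferred from ``<channel>_score`` columns unless given
    explicitly. Empty cells and the token ``"NA"`` in label columns mark
    missing labels.
    """
    df = pd.read_csv(
        path,
        na_values=[MISSING_TOKEN],
        keep_default_na=True,
        float_precision="round_trip",
    )
    if channels is None:
        channels = tuple(
            c[: -len("_score")] for c in df.columns if c.endswith("_score")
        )
        if not channels:
            raise ScoreTableError(
                f"{path}: header declares no '<channel>_score' columns"
            )
    return ScoreTable(channels=channels, data=df, general_channel=general_channel)


def write_score_table(table: ScoreTable, path) -> None:
    """Write a cohort as CSV; inverse of :func:`read_score_table`.

    Scores are serialized at full precision (repr round-trip), missing labels
    as the ``"NA"`` sentinel.
    """
    table.data.to_csv(
        path,
        index=False,
        na_rep=MISSING_TOKEN,
        # shortest round-trip representation keeps scores bit-exact
        float_format=lambda x: np.format_float_positional(x, unique=True, trim="0"),
    )
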