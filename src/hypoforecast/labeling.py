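"""Class labeling anchored on event onsets, and the chronological split.

Training examples are feature rows (windows ending at a given minute):

* hypotensive stays contribute positives from the last
  ``positive_horizon_min`` minutes before the first event onset (rows
  ending in [onset - 15, onset - 1] by default) and, optionally, a
  matched negative block of the same width ending two hours before the
  positive horizon (rows ending in [onset - 150, onset - 136]);
* non-hypotensive stays contribute negatives anchored on a *pseudo-onset*
  drawn within +/- ``pseudo_onset_jitter_min`` minutes of the mean
  time-to-first-event of the TRAINING hypotensive subjects, so both groups
  are sampled at a comparable point of the ICU stay.

The cohort is split by subject at the median admission date: subjects
admitted at or before the median train the model, later admissions
validate it — emulating prospective deployment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LabelConfig:
    positive_horizon_min: int = 15
    negative_gap_min: int = 120
    pseudo_onset_jitter_min: int = 15
    include_hypo_negatives: bool = True
    include_nonhypo_negatives: bool = True

    def __post_init__(self) -> None:
        if self.positive_horizon_min <= 0 or self.negative_gap_min <= 0:
            raise ValueError("horizons must be positive")
        if self.pseudo_onset_jitter_min < 0:
            raise ValueError("pseudo_onset_jitter_min must be >= 0")
        if self.negative_gap_min <= self.positive_horizon_min:
            raise ValueError("negative_gap_min must exceed positive_horizon_min")


def label_hypotension_stay(
    features: pd.DataFrame, first_event_onset: int, config: LabelConfig = LabelConfig()
) -> pd.DataFrame:
    """Label one hypotensive stay's feature rows against its first onset.

    Returns the labeled subset with ``label`` ('positive'/'negative') and
    ``lead_time_min`` (onset minus row end) columns. Rows after onset, and
    rows between the negative block and the positive horizon, stay
    unlabeled (they are scored for trajectories but never trained on).
    """
    h = config.positive_horizon_min
    g = config.negative_gap_min
    end = features["end_minute"].to_numpy()
    pos = (end >= first_event_onset - h) & (end <= first_event_onset - 1)
    out = []
    pos_rows = features.loc[pos].copy()
    pos_rows["label"] = "positive"
    out.append(pos_rows)
    if config.include_hypo_negatives:
        neg_lo = first_event_onset - g - 2 * h
        neg_hi = first_event_onset - g - h - 1
        neg = (end >= neg_lo) & (end <= neg_hi)
        if not neg.any():
            warnings.warn(
                f"stay {features['stay_id'].iloc[0] if len(features) else '?'}: "
                "onset too early for a pre-event negative block",
                stacklevel=2,
            )
        neg_rows = features.loc[neg].copy()
        neg_rows["label"] = "negative"
        out.append(neg_rows)
    labeled = pd.concat(out, ignore_index=True)
    labeled["lead_time_min"] = first_event_onset - labeled["end_minute"]
    return labeled


def draw_pseudo_onset(
    mean_onset_from_admission: float, config: LabelConfig, rng: np.random.Generator
) -> int:
    """Pseudo-onset minute: uniform integer within the jitter of the mean."""
    j = config.pseudo_onset_jitter_min
    lo = int(round(mean_onset_from_admission)) - j
    hi = int(round(mean_onset_from_admission)) + j
    return int(rng.integers(lo, hi + 1))


def label_nonhypotension_stay(
    features: pd.DataFrame,
    mean_onset_from_admission: float,
    config: LabelConfig = LabelConfig(),
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, int | None]:
    """Negative-label one non-hypotensive stay around a drawn pseudo-onset.

    The mean onset MUST come from training-set hypotensive subjects only
    (enforced by the caller; see the pipeline). Stays too short to reach
    their pseudo-onset are skipped with a warning. Returns the labeled rows
    and the pseudo-onset (None when skipped).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pseudo = draw_pseudo_onset(mean_onset_from_admission, config, rng)
    end = features["end_minute"].to_numpy()
    if len(end) == 0 or end.max() < pseudo - 1:
        warnings.warn("stay shorter than its pseudo-onset; skipped", stacklevel=2)
        return features.iloc[0:0].assign(label="", lead_time_min=np.nan), None
    if not config.include_nonhypo_negatives:
        return features.iloc[0:0].assign(label="", lead_time_min=np.nan), pseudo
    h = config.positive_horizon_min
    sel = (end >= pseudo - h) & (end <= pseudo - 1)
    rows = features.loc[sel].copy()
    rows["label"] = "negative"
    rows["lead_time_min"] = pseudo - rows["end_minute"]
    return rows.reset_index(drop=True), pseudo


def chronological_split(assignments: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split subjects at the median admission datetime.

    ``assignments`` needs columns subject_id and admission_datetime (one
    row per subject). Subjects admitted at or before the median go to
    training, strictly later to validation. All admissions equal (or an
    empty side) is a degenerate split and raises.
    """
    df = assignments.drop_duplicates("subject_id")
    if len(df) < 2:
        raise ValueError("need at least 2 subjects to split")
    admissions = pd.to_datetime(df["admission_datetime"])
    median = admissions.median()
    train_mask = admissions <= median
    train = sorted(df.loc[train_mask, "subject_id"].astype(str))
    val = sorted(df.loc[~train_mask, "subject_id"].astype(str))
    if not train or not val:
        raise ValueError(
            "degenerate chronological split (tied admission dates); jitter admissions"
        )
    return train, val
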