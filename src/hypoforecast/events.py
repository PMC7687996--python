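"""Hypotension event detection and cohort classification.

A hypotension event is defined on the cleaned minute grid in three steps:

1. a minute is *below threshold* when SBP <= 90 mmHg AND MAP <= 60 mmHg
   (both inclusive; a minute with either pressure missing is not evaluable
   and counts as not below);
2. a 10-minute sliding window qualifies when at least 5 of its minutes are
   below threshold (the density criterion); the union of all qualifying
   windows' minutes forms candidate periods;
3. candidate periods separated by a gap of 2 minutes or less are combined
   into a single event.

Event onset is the first below-threshold minute of the merged period; the
end is the last minute covered by any qualifying window of that period.

Subjects with at least one event form the hypotension group, keyed on the
first event only; those who received a vasopressor, crystalloid bolus or
red-cell transfusion in the two hours before that first onset are excluded
to keep the onset attributable to spontaneous deterioration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import VitalSeries

INTERVENTION_TYPES = ("vasopressor", "crystalloid_bolus", "prbc_transfusion")

#: Exclusion lookback before the first event onset, minutes ("two hours prior").
EXCLUSION_WINDOW_MIN = 120


@dataclass(frozen=True)
class EventDefinition:
    sbp_max: float = 90.0
    map_max: float = 60.0
    window_len: int = 10
    min_below: int = 5
    merge_gap_max: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.min_below <= self.window_len):
            raise ValueError("min_below must be in (0, window_len]")
        if self.merge_gap_max < 0:
            raise ValueError("merge_gap_max must be >= 0")


@dataclass(frozen=True)
class HypotensionEvent:
    stay_id: str
    onset_min: int
    end_min: int

    def __post_init__(self) -> None:
        if self.onset_min > self.end_min:
            raise ValueError("onset_min must be <= end_min")


@dataclass(frozen=True)
class CohortAssignment:
    subject_id: str
    group: str  # hypotension | non-hypotension | excluded
    first_event: HypotensionEvent | None = None
    exclusion_reason: str | None = None


def below_threshold(series: VitalSeries, defn: EventDefinition = EventDefinition()) -> np.ndarray:
    """Per-minute boolean: SBP <= sbp_max AND MAP <= map_max, missing -> False."""
    sbp = series.data["sbp"].to_numpy(dtype=float)
    map_ = series.data["map"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        return (sbp <= defn.sbp_max) & (map_ <= defn.map_max)


def detect_from_below(
    below: np.ndarray, defn: EventDefinition = EventDefinition()
) -> list[tuple[int, int]]:
    """Run the window / union / merge procedure on a boolean minute mask.

    Returns (onset, end) pairs sorted by onset. Series shorter than the
    window length cannot contain a qualifying window and yield no events.
    """
    below = np.asarray(below, dtype=bool)
    n = len(below)
    w = defn.window_len
    if n < w:
        return []
    counts = np.convolve(below.astype(np.int64), np.ones(w, dtype=np.int64), mode="valid")
    starts = np.flatnonzero(counts >= defn.min_below)
    if starts.size == 0:
        return []
    # union of qualifying windows' minute spans via a difference array
    delta = np.zeros(n + 1, dtype=np.int64)
    np.add.at(delta, starts, 1)
    np.add.at(delta, starts + w, -1)
    covered = np.cumsum(delta[:n]) > 0
    idx = np.flatnonzero(covered)
    # merge periods separated by <= merge_gap_max uncovered minutes
    breaks = np.flatnonzero(np.diff(idx) > defn.merge_gap_max + 1)
    events: list[tuple[int, int]] = []
    for grp in np.split(idx, breaks + 1):
        a, b = int(grp[0]), int(grp[-1])
        below_in = np.flatnonzero(below[a : b + 1])
        onset = a + int(below_in[0])  # a qualifying window guarantees >=1 below minute
        events.append((onset, b))
    return events


def detect_hypotension_events(
    series: VitalSeries, defn: EventDefinition = EventDefinition()
) -> list[HypotensionEvent]:
    """Detect hypotension events in one cleaned, imputed stay."""
    return [
        HypotensionEvent(series.stay_id, onset, end)
        for onset, end in detect_from_below(below_threshold(series, defn), defn)
    ]


def classify_subjects(
    stays: pd.DataFrame,
    events: list[HypotensionEvent],
    interventions: pd.DataFrame | None = None,
    exclusion_window_min: int = EXCLUSION_WINDOW_MIN,
) -> list[CohortAssignment]:
    """Assign each subject to the hypotension / non-hypotension group.

    ``stays`` needs columns subject_id, stay_id and (optionally)
    admission_datetime, used to order a subject's stays in time when
    locating the first event. ``interventions`` needs columns subject_id,
    stay_id, minute, type. A hypotension-group subject with any listed
    intervention on the first-event stay within ``exclusion_window_min``
    minutes before onset (boundary inclusive: exactly two hours prior still
    excludes) is marked excluded. Subjects with zero events are
    non-hypotension regardless of interventions.
    """
    stays = stays.copy()
    known_stays = set(stays["stay_id"].astype(str))
    if interventions is not None and len(interventions):
        unknown = set(interventions["stay_id"].astype(str)) - known_stays
        if unknown:
            raise ValueError(f"interventions reference unknown stays: {sorted(unknown)}")

    events_by_stay: dict[str, list[HypotensionEvent]] = {}
    for ev in events:
        if ev.stay_id not in known_stays:
            raise ValueError(f"event references unknown stay {ev.stay_id}")
        events_by_stay.setdefault(ev.stay_id, []).append(ev)

    iv_by_stay: dict[str, list[tuple[int, str]]] = {}
    if interventions is not None:
        for _, row in interventions.iterrows():
            iv_by_stay.setdefault(str(row["stay_id"]), []).append(
                (int(row["minute"]), str(row["type"]))
            )

    has_admission = "admission_datetime" in stays.columns
    out: list[CohortAssignment] = []
    for subject_id, grp in stays.groupby("subject_id", sort=True):
        # order stays chronologically so "first event" is first in absolute time
        if has_admission:
            grp = grp.sort_values("admission_datetime", kind="stable")
        first: HypotensionEvent | None = None
        for stay_id in grp["stay_id"].astype(str):
            stay_events = sorted(events_by_stay.get(stay_id, []), key=lambda e: e.onset_min)
            if stay_events:
                first = stay_events[0]
                break
        if first is None:
            out.append(CohortAssignment(str(subject_id), "non-hypotension"))
            continue
        reason = None
        for minute, iv_type in iv_by_stay.get(first.stay_id, []):
            gap = first.onset_min - minute
            if 0 < gap <= exclusion_window_min:
                reason = f"{iv_type} {gap} min before first event onset"
                break
        if reason is not None:
            out.append(CohortAssignment(str(subject_id), "excluded", first, reason))
        else:
            out.append(CohortAssignment(str(subject_id), "hypotension", first))
    return out


def time_to_first_event_stats(assignments: list[CohortAssignment]) -> dict[str, float]:
    """Mean / SD / median / IQR of onset time (minutes from ICU admission)
    over the hypotension group. Records start at admission, so the onset
    minute IS the time to first event. SD is 0 for a single subject."""
    onsets = np.array(
        [a.first_event.onset_min for a in assignments if a.group == "hypotension"],
        dtype=float,
    )
    if onsets.size == 0:
        raise ValueError("no hypotension-group subjects")
    q1, q3 = np.percentile(onsets, [25, 75])
    return {
        "mean": float(onsets.mean()),
        "sd": float(onsets.std(ddof=1)) if onsets.size > 1 else 0.0,
        "median": float(np.median(onsets)),
        "iqr": float(q3 - q1),
        "n": int(onsets.size),
    }


def events_to_frame(events: list[HypotensionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.stay_id, e.onset_min, e.end_min) for e in events],
        columns=["stay_id", "onset_min", "end_min"],
    )


def assignments_to_frame(assignments: list[CohortAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append(
            (
                a.subject_id,
                a.group,
                a.first_event.onset_min if a.first_event else np.nan,
                a.exclusion_reason or "",
            )
        )
    return pd.DataFrame(rows, columns=["subject_id", "group", "first_onset_min", "exclusion_reason"])
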