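"""Discrimination, calibration and lead-time-resolved evaluation.

AUROC is the Mann-Whitney probability that a random positive outscores a
random negative (ties half credit); AUPRC is the step-wise average
precision (no trapezoidal interpolation, so small instances are exactly
reproducible by threshold enumeration). Calibration is the Brier score
with an equal-width reliability binning. Lead-time curves evaluate both
metrics on score slices taken a fixed number of minutes before each
stay's (pseudo-)onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, brier_score_loss, roc_auc_score


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return y


def auroc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties half)."""
    y = _check_binary(labels)
    if len(set(y)) < 2:
        raise ValueError("AUROC undefined with a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Step-wise average precision; equals prevalence for uninformative scores."""
    y = _check_binary(labels)
    if y.sum() == 0:
        raise ValueError("AUPRC undefined without positives")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def brier(scores, labels) -> float:
    """Mean squared difference between score and binary outcome."""
    y = _check_binary(labels)
    return float(brier_score_loss(y, np.asarray(scores, dtype=float)))


@dataclass
class CalibrationReport:
    brier: float
    bins: pd.DataFrame  # bin_lo, bin_hi, mean_predicted, observed_frequency, n


def calibration(scores, labels, n_bins: int = 10) -> CalibrationReport:
    """Brier score plus an equal-width reliability table over [0, 1]."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(s, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        n = int(sel.sum())
        rows.append(
            (
                edges[b],
                edges[b + 1],
                float(s[sel].mean()) if n else np.nan,
                float(y[sel].mean()) if n else np.nan,
                n,
            )
        )
    bins = pd.DataFrame(
        rows, columns=["bin_lo", "bin_hi", "mean_predicted", "observed_frequency", "n"]
    )
    return CalibrationReport(brier=brier(s, y), bins=bins)


def _value_at_lead(aligned: pd.Series, lead: int, tolerance: int = 1) -> float:
    """Score at a lead time, falling back to the nearest minute within the
    tolerance (earlier minute preferred on a tie) when the exact one is
    unscored."""
    if lead in aligned.index:
        return float(aligned.loc[lead])
    for off in range(1, tolerance + 1):
        if lead + off in aligned.index:  # lead+off = one minute earlier in time
            return float(aligned.loc[lead + off])
        if lead - off in aligned.index:
            return float(aligned.loc[lead - off])
    return float("nan")


def lead_time_curves(
    aligned_by_stay: dict[str, pd.Series],
    group_by_stay: dict[str, str],
    grid: list[int],
    tolerance: int = 1,
    min_per_class: int = 2,
) -> pd.DataFrame:
    """AUROC/AUPRC at each lead time of the grid.

    ``aligned_by_stay`` maps stay -> lead-time-indexed scores (see
    :func:`hypoforecast.trajectories.align_trajectory`); hypotension stays
    provide the positives, non-hypotension stays the negatives, sliced at
    exactly the lead time (within the +/- ``tolerance`` minute fallback).
    Lead times with fewer than ``min_per_class`` stays in either class are
    omitted (counts still reported).
    """
    rows = []
    for lead in grid:
        scores, labels = [], []
        for stay_id, aligned in aligned_by_stay.items():
            v = _value_at_lead(aligned, lead, tolerance)
            if np.isnan(v):
                continue
            scores.append(v)
            labels.append(1 if group_by_stay[stay_id] == "hypotension" else 0)
        y = np.array(labels)
        n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
        if n_pos >= min_per_class and n_neg >= min_per_class:
            rows.append((lead, auroc(scores, y), auprc(scores, y), n_pos, n_neg))
        else:
            rows.append((lead, np.nan, np.nan, n_pos, n_neg))
    return pd.DataFrame(rows, columns=["lead_min", "auroc", "auprc", "n_pos", "n_neg"])


def patient_level_auprc(
    scores_by_stay: dict[str, pd.Series],
    group_by_stay: dict[str, str],
    mode: str = "whole-stay",
    onset_by_stay: dict[str, int] | None = None,
    seed: int = 0,
    span_min: int = 60,
) -> float:
    """AUPRC over one aggregated (maximum) score per stay.

    ``whole-stay`` evaluates each stay's full scored span (pre-onset only
    for hypotension stays — the forecasting task ends at the event);
    ``random-hour`` evaluates the last pre-onset hour for hypotension stays
    and a seeded random one-hour span for non-hypotension stays, mirroring
    a spot-check deployment. Scores are minute-indexed Series.
    """
    if mode not in ("whole-stay", "random-hour"):
        raise ValueError("mode must be 'whole-stay' or 'random-hour'")
    rng = np.random.default_rng(seed)
    agg, labels = [], []
    for stay_id in sorted(scores_by_stay):
        s = scores_by_stay[stay_id]
        is_pos = group_by_stay[stay_id] == "hypotension"
        onset = (onset_by_stay or {}).get(stay_id)
        if is_pos and onset is not None:
            s = s[s.index < onset]
        if mode == "random-hour" and len(s):
            if is_pos and onset is not None:
                s = s[(s.index >= onset - span_min) & (s.index < onset)]
            else:
                last_start = max(int(s.index.max()) - span_min + 1, int(s.index.min()))
                start = int(rng.integers(int(s.index.min()), last_start + 1))
                s = s[(s.index >= start) & (s.index < start + span_min)]
        if len(s) == 0:
            continue
        agg.append(float(s.max()))
        labels.append(1 if is_pos else 0)
    return auprc(agg, labels)
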