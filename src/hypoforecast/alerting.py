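"""Alert generation from risk-score streams and operational metrics.

Two refinements stand between a raw risk score and a bedside alert:

1. a *stacked* second-stage classifier re-scores each minute from rolling
   summaries (mean / min / max / SD over the last 5, 10 and 30 minutes) of
   the first-stage risk scores plus time since admission — smoothing away
   transient score spikes that would otherwise fire false alerts;
2. a *lockout* policy: once an alert is emitted, no further alert may be
   emitted within the lockout period (greedy, referenced to the last
   EMITTED alert), capping alarm burden.

Operational metrics follow the alarm-fatigue framing: alerts per subject
per hour over the monitored span, alert-level PPV (fraction of alerts
followed by a real event), and subject-level sensitivity (fraction of
hypotensive subjects alerted at least once before onset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CVResult, ModelSpec, cross_validate

LOOKBACKS = (5, 10, 30)


@dataclass(frozen=True)
class AlertPolicy:
    threshold: float = 0.5
    lockout_min: int = 15

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.lockout_min < 0:
            raise ValueError("lockout_min must be >= 0")


@dataclass
class OperationalMetrics:
    alerts_per_subject_hour: float
    alert_level_ppv: float
    subject_sensitivity: float
    subject_miss_rate: float
    n_alerts: int
    n_true_positive_alerts: int
    monitored_hours: float


def stacked_feature_names(lookbacks: tuple[int, ...] = LOOKBACKS) -> list[str]:
    names = ["time_since_admission"]
    for w in lookbacks:
        names += [f"risk_w{w}_{s}" for s in ("mean", "min", "max", "sd")]
    return names


def build_stacked_features(
    scores: pd.DataFrame, lookbacks: tuple[int, ...] = LOOKBACKS
) -> pd.DataFrame:
    """Rolling risk-score summaries for the second-stage model, one stay set.

    ``scores`` is a (stay_id, minute, score) frame. For each stay the score
    stream is placed on its minute grid and, per lookback W, the mean, min,
    max and population SD (single score -> 0) over [minute-W+1, minute] are
    computed from PRESENT scores only. Rows are kept only where every
    lookback window holds at least one score. ``time_since_admission`` is
    the minute index (records start at admission).
    """
    out = []
    for stay_id, grp in scores.groupby("stay_id", sort=True):
        s = grp.set_index("minute")["score"].sort_index()
        full = s.reindex(range(int(s.index.min()), int(s.index.max()) + 1))
        cols = {"stay_id": stay_id, "minute": full.index.to_numpy()}
        ok = np.ones(len(full), dtype=bool)
        for w in lookbacks:
            roll = full.rolling(w, min_periods=1)
            cols[f"risk_w{w}_mean"] = roll.mean().to_numpy()
            cols[f"risk_w{w}_min"] = roll.min().to_numpy()
            cols[f"risk_w{w}_max"] = roll.max().to_numpy()
            cols[f"risk_w{w}_sd"] = roll.std(ddof=0).to_numpy()
            ok &= full.notna().rolling(w, min_periods=1).sum().to_numpy() >= 1
        df = pd.DataFrame(cols)
        df.insert(2, "time_since_admission", df["minute"].astype(float))
        out.append(df.loc[ok])
    if not out:
        return pd.DataFrame(columns=["stay_id", "minute", *stacked_feature_names(lookbacks)])
    return pd.concat(out, ignore_index=True)


def train_stacked(
    stacked: pd.DataFrame,
    y: np.ndarray,
    subjects: np.ndarray,
    spec: ModelSpec | None = None,
    k: int = 10,
) -> CVResult:
    """Subject-partitioned CV training of the second-stage classifier.

    ``stacked`` rows must already be restricted to labeled minutes (labels
    inherited from the first-stage labeling at the same stay-minutes).
    """
    spec = spec or ModelSpec(family="random-forest")
    X = stacked[stacked_feature_names()]
    return cross_validate(X, y, subjects, spec=spec, k=k)


def raw_exceedances(scores: pd.Series, threshold: float) -> list[int]:
    """Minutes whose score meets the threshold (inclusive: score >= cutoff)."""
    s = scores.dropna()
    return [int(m) for m in s.index[s.to_numpy() >= threshold]]


def apply_lockout(candidate_minutes: list[int], lockout_min: int) -> list[int]:
    """Greedy lockout: emit a candidate iff no alert was emitted within the
    preceding ``lockout_min`` minutes. Idempotent; output spacing is
    strictly greater than the lockout."""
    emitted: list[int] = []
    last: int | None = None
    for t in sorted(candidate_minutes):
        if last is None or t - last > lockout_min:
            emitted.append(t)
            last = t
    return emitted


def generate_alerts(
    scores_by_stay: dict[str, pd.Series],
    policy: AlertPolicy,
    onset_by_stay: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Threshold + lockout alerts per stay.

    For first-event analysis, minutes at or after a stay's first onset are
    excluded from alerting (``onset_by_stay``). Returns (stay_id, minute,
    score) rows of emitted alerts.
    """
    rows = []
    for stay_id in sorted(scores_by_stay):
        s = scores_by_stay[stay_id]
        onset = (onset_by_stay or {}).get(stay_id)
        if onset is not None:
            s = s[s.index < onset]
        for t in apply_lockout(raw_exceedances(s, policy.threshold), policy.lockout_min):
            rows.append((stay_id, t, float(s.loc[t])))
    return pd.DataFrame(rows, columns=["stay_id", "minute", "score"])


def adjudicate_and_summarize(
    alerts: pd.DataFrame,
    onset_by_stay: dict[str, int | None],
    monitored_minutes_by_stay: dict[str, int],
    true_positive_horizon_min: int | None = None,
) -> OperationalMetrics:
    """Adjudicate alerts against first-event onsets and summarize.

    An alert is a true positive iff its stay has a first event with onset
    strictly after the alert minute (and, when a finite horizon is set,
    within ``true_positive_horizon_min`` minutes). Alerts in stays without
    an event are false positives. The alert rate is normalized by total
    monitored subject-hours; sensitivity is the fraction of event stays
    with at least one true-positive alert.
    """
    total_minutes = sum(monitored_minutes_by_stay.values())
    if total_minutes <= 0:
        raise ValueError("zero monitored time")
    hours = total_minutes / 60.0

    n_tp = 0
    tp_stays: set[str] = set()
    for _, row in alerts.iterrows():
        onset = onset_by_stay.get(str(row["stay_id"]))
        minute = int(row["minute"])
        is_tp = (
            onset is not None
            and minute < onset
            and (true_positive_horizon_min is None or onset - minute <= true_positive_horizon_min)
        )
        if is_tp:
            n_tp += 1
            tp_stays.add(str(row["stay_id"]))
    n_alerts = len(alerts)
    event_stays = [s for s, o in onset_by_stay.items() if o is not None]
    sens = len(tp_stays) / len(event_stays) if event_stays else float("nan")
    return OperationalMetrics(
        alerts_per_subject_hour=n_alerts / hours,
        alert_level_ppv=n_tp / n_alerts if n_alerts else float("nan"),
        subject_sensitivity=sens,
        subject_miss_rate=1.0 - sens if event_stays else float("nan"),
        n_alerts=n_alerts,
        n_true_positive_alerts=n_tp,
        monitored_hours=hours,
    )


def threshold_sweep(
    scores_by_stay: dict[str, pd.Series],
    onset_by_stay: dict[str, int | None],
    monitored_minutes_by_stay: dict[str, int],
    thresholds: np.ndarray,
    lockout_min: int = 15,
) -> pd.DataFrame:
    """Detected-fraction vs PPV vs alert-rate curve over score thresholds."""
    rows = []
    onsets_only = {s: o for s, o in onset_by_stay.items() if o is not None}
    for thr in thresholds:
        alerts = generate_alerts(
            scores_by_stay, AlertPolicy(threshold=float(thr), lockout_min=lockout_min), onsets_only
        )
        m = adjudicate_and_summarize(alerts, onset_by_stay, monitored_minutes_by_stay)
        rows.append(
            (
                float(thr),
                m.alerts_per_subject_hour,
                m.alert_level_ppv,
                m.subject_sensitivity,
                m.n_alerts,
            )
        )
    return pd.DataFrame(
        rows, columns=["threshold", "alerts_per_hour", "ppv", "detected_fraction", "n_alerts"]
    )
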