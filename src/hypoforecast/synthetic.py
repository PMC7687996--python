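"""Synthetic ICU vital-sign cohort generator.

Produces minute-gridded multichannel vital signs with the statistical
structure the downstream analysis assumes: subject-specific baselines with
AR(1) minute-scale autocorrelation, a programmable decompensation drift in
the hypotensive subgroup that provably satisfies the hypotension event
definition at a programmed onset minute, burst missingness, out-of-range
monitor artifacts, intervention records, and admission dates spread over a
configurable window so a chronological split is well defined.

Signal shape for a hypotensive subject
--------------------------------------
During the ``drift_onset_lead_min`` minutes before the programmed onset,
SBP ramps linearly down by ``drift_depth_mmhg`` while DBP declines only
mildly and HR rises, so MAP stays above its 60 mmHg threshold until onset —
this leaves a learnable multi-channel pre-event signature without creating
premature events. At onset DBP steps down to its event level, pushing MAP
below threshold; pressures then hold for ``event_hold_min`` minutes and
recover linearly. The first 10 post-onset minutes are capped at SBP <= 89 /
MAP <= 59 so the clean series satisfies the event definition from exactly
the programmed minute; outside the decompensation episode (and for every
non-hypotensive subject) MAP is floored at 61 mmHg so clean series can
never produce spurious events.

Everything is deterministic given ``seed``: per-subject generators are
spawned from a single :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .preprocess import CHANNELS, DEFAULT_BOUNDS, VitalSeries, write_vitals


class SimConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


_DEFAULT_MEANS = {"hr": 80.0, "rr": 16.0, "spo2": 97.5, "sbp": 120.0, "dbp": 70.0}
_DEFAULT_SDS = {"hr": 3.0, "rr": 1.5, "spo2": 0.8, "sbp": 5.0, "dbp": 4.0}


@dataclass
class SimConfig:
    """Cohort-level generator settings (defaults are the study conditions).

    24-hour records at 1/min sampling, half the cohort decompensating, a
    90-minute pre-onset drift of 35 mmHg systolic depth, 5 % burst
    missingness and 0.2 % artifact cells reflect a plausible monitored ICU
    population; admission dates spread over 60 days give the chronological
    split a meaningful median.
    """

    n_subjects: int = 200
    frac_hypotensive: float = 0.5
    record_len_min: int = 1440
    baseline_means: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    baseline_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SDS))
    ar_coefficient: float = 0.9
    drift_onset_lead_min: int = 90
    drift_depth_mmhg: float = 35.0
    missing_rate: float = 0.05
    missing_burst_max_min: int = 5
    artifact_rate: float = 0.002
    admission_date_spread_days: int = 60
    seed: int = 0
    # secondary shape parameters (onset bounds default from the record length)
    onset_earliest_min: int | None = None
    onset_latest_min: int | None = None
    event_hold_min: int = 30
    recovery_min: int = 60
    hr_drift_bpm: float = 10.0
    dbp_predrift_mmhg: float = 5.0
    event_map_mmhg: float = 56.0
    n_intervention_subjects: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise SimConfigError("n_subjects must be >= 1")
        for name in ("frac_hypotensive", "missing_rate", "artifact_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise SimConfigError("ar_coefficient must be in [0, 1)")
        if self.record_len_min <= self.drift_onset_lead_min:
            raise SimConfigError("record_len_min must exceed drift_onset_lead_min")
        if self.missing_burst_max_min < 1:
            raise SimConfigError("missing_burst_max_min must be >= 1")
        if self.admission_date_spread_days < 0:
            raise SimConfigError("admission_date_spread_days must be >= 0")
        if self.frac_hypotensive > 0:
            lo, hi = self.onset_range()
            if not self.drift_onset_lead_min <= lo <= hi < self.record_len_min:
                raise SimConfigError(
                    "onset_earliest_min/onset_latest_min must satisfy "
                    "drift_onset_lead_min <= earliest <= latest < record_len_min"
                )
        if self.record_len_min < 60:
            raise SimConfigError("record_len_min must be >= 60")
        for ch in ("hr", "rr", "spo2", "sbp", "dbp"):
            if ch not in self.baseline_means or ch not in self.baseline_sd:
                raise SimConfigError(f"baseline_means/baseline_sd must define channel {ch}")
            mean = self.baseline_means[ch]
            if DEFAULT_BOUNDS.violates(ch, np.array([float(mean)]))[0]:
                raise SimConfigError(f"baseline_means[{ch!r}]={mean} outside plausibility bounds")

    def onset_range(self) -> tuple[int, int]:
        """Programmed-onset bounds, defaulting from the record length: no
        earlier than a quarter of the stay (and never before the drift can
        complete), and late enough to fit the guaranteed 10 below-threshold
        minutes."""
        lo = self.onset_earliest_min
        if lo is None:
            lo = max(self.drift_onset_lead_min, self.record_len_min // 4)
        hi = self.onset_latest_min
        if hi is None:
            hi = self.record_len_min - max(self.event_hold_min, 10)
        return lo, hi


@dataclass
class SubjectTruth:
    """Ground truth for one generated subject (one ICU stay)."""

    subject_id: str
    stay_id: str
    group: str  # hypotensive | non-hypotensive
    admission_datetime: pd.Timestamp
    programmed_onset_min: int | None = None
    intervention_times: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.group == "hypotensive") != (self.programmed_onset_min is not None):
            raise ValueError("programmed_onset_min present iff group is hypotensive")


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    x0 = rng.normal(0.0, sd)
    out = lfilter([1.0], [1.0, -phi], eps, zi=[phi * x0])[0]
    return out


def _subject_series(cfg: SimConfig, rng: np.random.Generator, onset: int | None) -> pd.DataFrame:
    T = cfg.record_len_min
    mu, sd, phi = cfg.baseline_means, cfg.baseline_sd, cfg.ar_coefficient
    t = np.arange(T)

    mean_hr = np.full(T, mu["hr"])
    mean_rr = np.full(T, mu["rr"])
    mean_spo2 = np.full(T, mu["spo2"])
    mean_sbp = np.full(T, mu["sbp"])
    mean_dbp = np.full(T, mu["dbp"])

    if onset is not None:
        lead = cfg.drift_onset_lead_min
        ramp0 = onset - lead
        sbp_event = mu["sbp"] - cfg.drift_depth_mmhg
        # DBP level that puts MAP = (SBP + 2 DBP)/3 at the event target
        dbp_event = max(15.0, (3.0 * cfg.event_map_mmhg - sbp_event) / 2.0)
        frac = np.clip((t - ramp0) / lead, 0.0, 1.0)  # 0 before ramp, 1 at onset
        in_pre = t < onset
        mean_sbp = np.where(in_pre, mu["sbp"] - frac * cfg.drift_depth_mmhg, mean_sbp)
        mean_dbp = np.where(in_pre, mu["dbp"] - frac * cfg.dbp_predrift_mmhg, mean_dbp)
        mean_hr = np.where(in_pre, mu["hr"] + frac * cfg.hr_drift_bpm, mean_hr)
        mean_spo2 = np.where(in_pre, mu["spo2"] - frac * 1.5, mean_spo2)
        hold_end = min(onset + cfg.event_hold_min, T)
        in_hold = (t >= onset) & (t < hold_end)
        mean_sbp[in_hold] = sbp_event
        mean_dbp[in_hold] = dbp_event
        mean_hr[in_hold] = mu["hr"] + cfg.hr_drift_bpm
        mean_spo2[in_hold] = mu["spo2"] - 1.5
        rec_end = min(hold_end + cfg.recovery_min, T)
        in_rec = (t >= hold_end) & (t < rec_end)
        if in_rec.any():
            rfrac = (t[in_rec] - hold_end) / cfg.recovery_min
            mean_sbp[in_rec] = sbp_event + rfrac * (mu["sbp"] - sbp_event)
            mean_dbp[in_rec] = dbp_event + rfrac * (mu["dbp"] - dbp_event)
            mean_hr[in_rec] = mu["hr"] + (1 - rfrac) * cfg.hr_drift_bpm
            mean_spo2[in_rec] = mu["spo2"] - (1 - rfrac) * 1.5

    hr = mean_hr + _ar1(rng, T, sd["hr"], phi)
    rr = mean_rr + _ar1(rng, T, sd["rr"], phi)
    spo2 = np.minimum(mean_spo2 + _ar1(rng, T, sd["spo2"], phi), 100.0)
    sbp = mean_sbp + _ar1(rng, T, sd["sbp"], phi)
    dbp = mean_dbp + _ar1(rng, T, sd["dbp"], phi)
    map_ = (sbp + 2.0 * dbp) / 3.0 + rng.normal(0.0, 1.0, size=T)

    # hard guarantees against spurious / mistimed events on the clean series
    if onset is None:
        map_ = np.maximum(map_, 61.0)
    else:
        episode = (t >= onset) & (t < min(onset + cfg.event_hold_min + cfg.recovery_min, T))
        map_ = np.where(episode, map_, np.maximum(map_, 61.0))
        guarantee = (t >= onset) & (t < onset + 10)
        sbp = np.where(guarantee, np.minimum(sbp, 89.0), sbp)
        map_ = np.where(guarantee, np.minimum(map_, 59.0), map_)

    df = pd.DataFrame(
        {"hr": hr, "rr": rr, "spo2": spo2, "sbp": sbp, "dbp": dbp, "map": map_},
        index=pd.RangeIndex(T, name="minute"),
    )
    return df


def generate_cohort(config: SimConfig) -> tuple[list[VitalSeries], list[SubjectTruth]]:
    """Generate a full synthetic cohort (vitals + ground truth).

    Deterministic given ``config.seed``. Missingness and artifacts are
    injected after the clean physiologic signal is built, so the programmed
    event structure holds on the pre-injection series.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss)
    n_hypo = int(round(config.n_subjects * config.frac_hypotensive))
    hypo_flags = np.zeros(config.n_subjects, dtype=bool)
    hypo_flags[:n_hypo] = True

    base_date = pd.Timestamp("2025-01-01 00:00:00")
    spread_min = config.admission_date_spread_days * 24 * 60
    admit_offsets = (
        master.integers(0, spread_min + 1, size=config.n_subjects)
        if spread_min > 0
        else np.zeros(config.n_subjects, dtype=int)
    )

    child_seeds = ss.spawn(config.n_subjects)
    series_list: list[VitalSeries] = []
    truths: list[SubjectTruth] = []
    intervened = 0
    for i in range(config.n_subjects):
        rng = np.random.default_rng(child_seeds[i])
        subject_id = f"s{i:04d}"
        stay_id = f"{subject_id}-1"
        onset: int | None = None
        if hypo_flags[i]:
            lo, hi = config.onset_range()
            onset = int(rng.integers(lo, hi + 1))
        data = _subject_series(config, rng, onset)
        series = VitalSeries(
            subject_id=subject_id,
            stay_id=stay_id,
            data=data,
            admission_datetime=base_date + pd.Timedelta(minutes=int(admit_offsets[i])),
        )
        interventions: list[tuple[str, int]] = []
        if hypo_flags[i] and intervened < config.n_intervention_subjects:
            # a pre-event intervention inside the 2-h exclusion window
            interventions.append(("vasopressor", onset - 60))
            intervened += 1
        if config.missing_rate > 0:
            series = inject_missingness(
                series,
                config.missing_rate,
                config.missing_burst_max_min,
                int(rng.integers(2**31)),
            )
        if config.artifact_rate > 0:
            series, _ = inject_artifacts(series, config.artifact_rate, int(rng.integers(2**31)))
        series_list.append(series)
        truths.append(
            SubjectTruth(
                subject_id=subject_id,
                stay_id=stay_id,
                group="hypotensive" if hypo_flags[i] else "non-hypotensive",
                admission_datetime=series.admission_datetime,
                programmed_onset_min=onset,
                intervention_times=interventions,
            )
        )
    return series_list, truths


def inject_missingness(
    series: VitalSeries, rate: float, burst_max: int, seed: int
) -> VitalSeries:
    """Mask whole minutes (all channels) in bursts of length <= burst_max.

    Bursts are placed until the masked fraction reaches ``rate``; overlaps
    can overshoot by at most one burst, so for records of >= 1000 minutes
    the realized fraction stays well within 20 % relative of the request.
    ``rate`` = 0 returns an untouched copy; ``rate`` >= 1 is rejected.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must be in [0, 1)")
    out = series.copy()
    if rate == 0.0:
        return out
    if burst_max < 1:
        raise ValueError("burst_max must be >= 1")
    rng = np.random.default_rng(seed)
    T = out.n_minutes
    target = rate * T
    mask = np.zeros(T, dtype=bool)
    while mask.sum() < target:
        length = int(rng.integers(1, burst_max + 1))
        start = int(rng.integers(0, max(T - length, 0) + 1))
        mask[start : start + length] = True
    out.data.loc[out.data.index[mask], list(CHANNELS)] = np.nan
    return out


#: Out-of-range generators per channel; every value violates a plausibility bound.
_ARTIFACT_RANGES: dict[str, tuple[float, float]] = {
    "sbp": (400.0, 500.0),  # half-open (low, high]
    "dbp": (400.0, 500.0),
    "map": (400.0, 500.0),
    "hr": (400.0, 480.0),
    "rr": (100.0, 160.0),
    "spo2": (0.0, 10.0),  # strictly below 10 %
}


def inject_artifacts(
    series: VitalSeries, rate: float, seed: int
) -> tuple[VitalSeries, list[tuple[int, str]]]:
    """Replace a random set of observed cells with out-of-range values.

    Each observed (minute, channel) cell is independently corrupted with
    probability ``rate``; injected values are drawn strictly outside the
    plausibility bounds (for pressures, from (400, 500] mmHg; for SpO2,
    below 10 %), so artifact removal blanks exactly the returned positions.
    Returns the corrupted series and the injected (minute, channel) list.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("artifact rate must be in [0, 1)")
    out = series.copy()
    injected: list[tuple[int, str]] = []
    if rate == 0.0:
        return out, injected
    rng = np.random.default_rng(seed)
    hit = rng.random((out.n_minutes, len(CHANNELS))) < rate
    minutes = out.data.index.to_numpy()
    for j, ch in enumerate(CHANNELS):
        vals = out.data[ch].to_numpy(dtype=float).copy()
        sel = hit[:, j] & ~np.isnan(vals)
        if not sel.any():
            continue
        lo, hi = _ARTIFACT_RANGES[ch]
        draws = rng.uniform(lo, hi, size=int(sel.sum()))
        if ch != "spo2":
            draws = np.nextafter(np.maximum(draws, np.nextafter(lo, hi)), hi)  # strictly > lo
        else:
            draws = np.minimum(draws, np.nextafter(10.0, 0.0))  # strictly < 10
        vals[sel] = draws
        out.data[ch] = vals
        injected.extend((int(m), ch) for m in minutes[sel])
    injected.sort()
    return out, injected


# ---------------------------------------------------------------------------
# Cohort CSV export
# ---------------------------------------------------------------------------

def write_cohort(series_list: list[VitalSeries], truths: list[SubjectTruth], outdir) -> None:
    """Write vitals.csv, subjects.csv and interventions.csv to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vitals(series_list, outdir / "vitals.csv")
    sub_rows = []
    iv_rows = []
    for tr in truths:
        sub_rows.append(
            (
                tr.subject_id,
                tr.stay_id,
                tr.admission_datetime.isoformat(),
                tr.group,
                tr.programmed_onset_min if tr.programmed_onset_min is not None else "",
            )
        )
        for iv_type, minute in tr.intervention_times:
            iv_rows.append((tr.subject_id, tr.stay_id, minute, iv_type))
    pd.DataFrame(
        sub_rows,
        columns=["subject_id", "stay_id", "admission_datetime", "group", "programmed_onset_min"],
    ).to_csv(outdir / "subjects.csv", index=False)
    pd.DataFrame(iv_rows, columns=["subject_id", "stay_id", "minute", "type"]).to_csv(
        outdir / "interventions.csv", index=False
    )


def interventions_frame(truths: list[SubjectTruth]) -> pd.DataFrame:
    rows = [
        (tr.subject_id, tr.stay_id, minute, iv_type)
        for tr in truths
        for iv_type, minute in tr.intervention_times
    ]
    return pd.DataFrame(rows, columns=["subject_id", "stay_id", "minute", "type"])
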