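"""Vital-sign ingestion, plausibility cleaning and causal imputation.

Minute-by-minute ICU vital signs arrive as long-format CSV tables (one row
per stay-minute). This module regularizes each stay onto a 0-based 1-minute
grid, removes physiologically implausible values (strict out-of-range
exclusion), and fills short gaps with a moving average of the three most
recent available values — never using future data, so every downstream
feature remains causal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Channel order used everywhere in the package.
CHANNELS: tuple[str, ...] = ("hr", "rr", "spo2", "sbp", "dbp", "map")

VITALS_COLUMNS = ("subject_id", "stay_id", "minute") + CHANNELS


class ParseError(ValueError):
    """Raised when a vitals table violates the expected dialect."""


@dataclass
class VitalSeries:
    """One ICU stay's minute-gridded multichannel vital signs.

    ``data`` is indexed by minute (0-based, unit step) with one float column
    per channel in :data:`CHANNELS`; missing observations are NaN.
    """

    subject_id: str
    stay_id: str
    data: pd.DataFrame
    admission_datetime: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        idx = self.data.index.to_numpy()
        if len(idx) and not np.array_equal(idx, np.arange(idx[0], idx[0] + len(idx))):
            raise ValueError("minute index must be regular with unit step")
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing channels: {missing}")

    @property
    def n_minutes(self) -> int:
        return len(self.data)

    def copy(self) -> "VitalSeries":
        return dataclasses.replace(self, data=self.data.copy())


@dataclass(frozen=True)
class PlausibilityBounds:
    """Open per-channel exclusion bounds: values strictly outside are removed.

    ``None`` means unbounded on that side. Defaults follow standard adult
    ICU plausibility limits: arterial pressures outside (10, 400) mmHg,
    respiratory rate outside (1, 100) /min, heart rate outside (10, 400)
    bpm, and SpO2 below 10 % are treated as monitor artifacts.
    """

    bounds: dict[str, tuple[float | None, float | None]] = field(
        default_factory=lambda: {
            "sbp": (10.0, 400.0),
            "dbp": (10.0, 400.0),
            "map": (10.0, 400.0),
            "rr": (1.0, 100.0),
            "hr": (10.0, 400.0),
            "spo2": (10.0, None),
        }
    )

    def __post_init__(self) -> None:
        for ch, (lo, hi) in self.bounds.items():
            if lo is not None and hi is not None and not lo < hi:
                raise ValueError(f"bounds for {ch}: low must be < high")

    def violates(self, channel: str, values: np.ndarray) -> np.ndarray:
        """Boolean mask of values strictly outside the channel's bounds."""
        lo, hi = self.bounds.get(channel, (None, None))
        out = np.zeros(len(values), dtype=bool)
        with np.errstate(invalid="ignore"):
            if lo is not None:
                out |= values < lo
            if hi is not None:
                out |= values > hi
        return out & ~np.isnan(values)


DEFAULT_BOUNDS = PlausibilityBounds()


@dataclass(frozen=True)
class ImputationConfig:
    """Causal gap-filling policy.

    lookback_points
        How many of the most recent available values are averaged (3).
    max_gap_min
        Gaps of this length or longer are left missing; strictly shorter
        runs are filled.
    """

    lookback_points: int = 3
    max_gap_min: int = 10

    def __post_init__(self) -> None:
        if self.lookback_points < 1:
            raise ValueError("lookback_points must be >= 1")
        if self.max_gap_min < 1:
            raise ValueError("max_gap_min must be >= 1")


# ---------------------------------------------------------------------------
# Reading / writing the cohort CSV dialect
# ---------------------------------------------------------------------------

def read_vitals(path, subjects_path=None) -> list[VitalSeries]:
    """Read a long-format vitals CSV into one :class:`VitalSeries` per stay.

    The table must carry exactly the columns ``subject_id, stay_id, minute,
    hr, rr, spo2, sbp, dbp, map``. Within each stay, minutes must be
    strictly increasing in file order and unique; the grid is then filled so
    every minute from 0 to the last observed minute exists (inserted minutes
    are fully missing). ``subjects_path`` optionally supplies admission
    datetimes (CSV with subject_id, stay_id, admission_datetime).
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "stay_id": str})
    if set(df.columns) != set(VITALS_COLUMNS):
        unknown = set(df.columns) - set(VITALS_COLUMNS)
        missing = set(VITALS_COLUMNS) - set(df.columns)
        raise ParseError(f"unexpected columns (unknown={sorted(unknown)}, missing={sorted(missing)})")
    if len(df) == 0:
        return []
    minutes = pd.to_numeric(df["minute"], errors="coerce")
    bad = minutes.isna() | (minutes != minutes.round()) | (minutes < 0)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ParseError(f"malformed minute value at line {line}")
    df["minute"] = minutes.astype(int)

    admissions: dict[str, pd.Timestamp] = {}
    if subjects_path is not None:
        sub = pd.read_csv(subjects_path, dtype={"subject_id": str, "stay_id": str})
        for _, row in sub.iterrows():
            admissions[row["stay_id"]] = pd.Timestamp(row["admission_datetime"])

    out: list[VitalSeries] = []
    for (subject_id, stay_id), grp in df.groupby(["subject_id", "stay_id"], sort=True):
        mins = grp["minute"].to_numpy()
        if len(mins) > 1 and not (np.diff(mins) > 0).all():
            first_bad = int(grp.index[np.flatnonzero(np.diff(mins) <= 0)[0] + 1]) + 2
            raise ParseError(
                f"non-monotone or duplicate minute for stay {stay_id} at line {first_bad}"
            )
        chan = grp.set_index("minute")[list(CHANNELS)].astype(float)
        chan = chan.reindex(range(0, int(mins.max()) + 1))
        chan.index.name = "minute"
        out.append(
            VitalSeries(
                subject_id=str(subject_id),
                stay_id=str(stay_id),
                data=chan,
                admission_datetime=admissions.get(str(stay_id)),
            )
        )
    return out


def write_vitals(series_list: list[VitalSeries], path) -> None:
    """Write stays back to the long-format CSV dialect (missing = empty cell)."""
    frames = []
    for s in series_list:
        df = s.data.reset_index()
        df.insert(0, "stay_id", s.stay_id)
        df.insert(0, "subject_id", s.subject_id)
        frames.append(df)
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        pd.DataFrame(columns=list(VITALS_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def remove_artifacts(
    series: VitalSeries, bounds: PlausibilityBounds = DEFAULT_BOUNDS
) -> tuple[VitalSeries, dict[str, int]]:
    """Blank values strictly outside the plausibility bounds.

    Bounds are strict: a value exactly at a bound (SBP = 400, SpO2 = 10) is
    kept. Returns the cleaned series and the per-channel removal counts.
    Idempotent: cleaning an already-clean series removes nothing.
    """
    out = series.copy()
    counts: dict[str, int] = {}
    for ch in CHANNELS:
        vals = out.data[ch].to_numpy()
        bad = bounds.violates(ch, vals)
        counts[ch] = int(bad.sum())
        if bad.any():
            vals = vals.copy()
            vals[bad] = np.nan
            out.data[ch] = vals
    return out, counts


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def _impute_channel(x: np.ndarray, lookback: int, max_gap: int) -> np.ndarray:
    """Fill missing runs shorter than ``max_gap`` with the mean of the most
    recent ``lookback`` available values, cascading left to right."""
    out = x.copy()
    isna = np.isnan(x)
    n = len(x)
    recent: list[float] = []  # trailing window of available (observed or filled) values
    i = 0
    while i < n:
        if not isna[i]:
            recent.append(out[i])
            if len(recent) > lookback:
                recent.pop(0)
            i += 1
            continue
        j = i
        while j < n and isna[j]:
            j += 1
        run_len = j - i
        if run_len < max_gap and recent:
            for t in range(i, j):
                out[t] = float(np.mean(recent))
                recent.append(out[t])
                if len(recent) > lookback:
                    recent.pop(0)
        # runs >= max_gap (or with no past data) stay missing and do not
        # contribute to the lookback buffer
        i = j
    return out


def impute_missing(
    series: VitalSeries, config: ImputationConfig = ImputationConfig()
) -> VitalSeries:
    """Causal moving-average gap filling.

    Each missing run strictly shorter than ``max_gap_min`` is filled left to
    right, every filled minute being the mean of the three most recent
    available values (observed or already filled — the signal-stability
    assumption). Runs of ``max_gap_min`` or more, and leading gaps with no
    past data, are left missing. No future value is ever consulted, so
    truncating the series after minute t cannot change any fill at <= t.
    """
    out = series.copy()
    for ch in CHANNELS:
        out.data[ch] = _impute_channel(
            out.data[ch].to_numpy(dtype=float), config.lookback_points, config.max_gap_min
        )
    return out


def imputation_quality(
    series: VitalSeries,
    mask_spec: list[tuple[str, int, int]],
    config: ImputationConfig = ImputationConfig(),
) -> dict[str, dict[str, float]]:
    """Masked-segment validation of the imputation rule.

    ``mask_spec`` lists (channel, start_minute, length) segments that must be
    fully observed in the input; each is blanked, the series re-imputed, and
    the fills compared with the held-out truth. Masks of length
    >= ``max_gap_min`` are not imputable and are excluded from the summary.
    Returns per-channel ``{"rmse", "bias", "n"}``.
    """
    usable = []
    for ch, start, length in mask_spec:
        if ch not in CHANNELS:
            raise ValueError(f"unknown channel {ch!r}")
        seg = series.data[ch].iloc[start : start + length]
        if len(seg) != length or seg.isna().any():
            raise ValueError(f"mask ({ch}, {start}, {length}) does not cover a complete segment")
        if length < config.max_gap_min:
            usable.append((ch, start, length))
    if not usable:
        raise ValueError("no maskable segment shorter than max_gap_min")

    masked = series.copy()
    for ch, start, length in usable:
        col = masked.data[ch].to_numpy()
        col[start : start + length] = np.nan
        masked.data[ch] = col
    refilled = impute_missing(masked, config)

    report: dict[str, dict[str, float]] = {}
    for ch in sorted({m[0] for m in usable}):
        errs = []
        for mch, start, length in usable:
            if mch != ch:
                continue
            truth = series.data[ch].iloc[start : start + length].to_numpy()
            pred = refilled.data[ch].iloc[start : start + length].to_numpy()
            ok = ~np.isnan(pred)
            errs.append((pred - truth)[ok])
        e = np.concatenate(errs) if errs else np.array([])
        report[ch] = {
            "rmse": float(np.sqrt(np.mean(e**2))) if e.size else float("nan"),
            "bias": float(np.mean(e)) if e.size else float("nan"),
            "n": int(e.size),
        }
    return report
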