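"""Per-minute multi-window feature engineering.

For every minute t of a cleaned stay and every window length W in
{5, 10, 30, 60}, features are computed on the closed span [t-W+1, t]
(windows end at the current minute; nothing after t is ever read):

* statistics over the present values — sample variance (n-1 denominator),
  quartiles and median by linear interpolation, mean, min, max;
* magnitudes of the leading non-constant discrete-Fourier coefficients of
  the demeaned window (residual gaps mean-filled first);
* the exponentially weighted moving average of the present values,
  s_t = alpha*x_t + (1-alpha)*s_{t-1} seeded at the first present value.

A feature row exists at minute t only when every required window meets the
``min_completeness`` fraction of non-missing minutes on every channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import CHANNELS, VitalSeries

STAT_SET = ("variance", "q1", "q3", "mean", "median", "min", "max")


@dataclass(frozen=True)
class FeatureConfig:
    window_lengths: tuple[int, ...] = (5, 10, 30, 60)
    stat_set: tuple[str, ...] = STAT_SET
    dft_coeffs: int = 5
    ewma_alpha: float = 0.3
    min_completeness: float = 0.5
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        if any(w < 2 for w in self.window_lengths):
            raise ValueError("all window lengths must be >= 2")
        if not 0.0 < self.ewma_alpha <= 1.0:
            raise ValueError("ewma_alpha must be in (0, 1]")
        if not 0.0 < self.min_completeness <= 1.0:
            raise ValueError("min_completeness must be in (0, 1]")
        unknown = set(self.stat_set) - set(STAT_SET)
        if unknown:
            raise ValueError(f"unknown statistics: {sorted(unknown)}")

    @property
    def n_features(self) -> int:
        return len(self.channels) * len(self.window_lengths) * (
            len(self.stat_set) + self.dft_coeffs + 1
        )


def feature_names(config: FeatureConfig = FeatureConfig()) -> list[str]:
    """Deterministic ordered feature-column names."""
    names = []
    for ch in config.channels:
        for w in config.window_lengths:
            for stat in config.stat_set:
                names.append(f"{ch}_w{w}_{stat}")
            for k in range(1, config.dft_coeffs + 1):
                names.append(f"{ch}_w{w}_dft{k}")
            names.append(f"{ch}_w{w}_ewma")
    return names


# ---------------------------------------------------------------------------
# Single-window reference operations
# ---------------------------------------------------------------------------

def window_stats(values: np.ndarray, stat_set: tuple[str, ...] = STAT_SET) -> dict[str, float]:
    """Statistics over the present values of one window.

    Variance is the sample variance (n-1); quartiles use linear
    interpolation between order statistics. NaN results are possible when
    fewer than two values are present (variance).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("window has no present values")
    out = {
        "variance": float(np.var(v, ddof=1)) if v.size > 1 else float("nan"),
        "q1": float(np.percentile(v, 25)),
        "q3": float(np.percentile(v, 75)),
        "mean": float(np.mean(v)),
        "median": float(np.median(v)),
        "min": float(np.min(v)),
        "max": float(np.max(v)),
    }
    return {k: out[k] for k in stat_set}


def dft_features(values: np.ndarray, n_coeffs: int | None = 5) -> np.ndarray:
    """Magnitudes of the lowest non-constant DFT coefficients of one window.

    Residual missing values are filled with the window mean before the
    transform; the window is then demeaned, so the constant (DC) term is
    zero and excluded. Only distinct frequencies are reported (a real
    window of length N has floor(N/2) of them); the result is zero-padded
    when the window is too short to hold ``n_coeffs``. ``n_coeffs=None``
    returns all N-1 non-DC magnitudes of the full two-sided transform
    (mirrored conjugates included), which satisfies Parseval's identity
    sum |X_k|^2 / N = sum (x - mean)^2.
    """
    v = np.asarray(values, dtype=float)
    present = ~np.isnan(v)
    if not present.any():
        raise ValueError("window has no present values")
    mu = v[present].mean()
    filled = np.where(present, v, mu)
    spec = np.abs(np.fft.fft(filled - mu))
    if n_coeffs is None:
        return spec[1:]
    out = np.zeros(n_coeffs)
    take = min(n_coeffs, len(v) // 2)
    out[:take] = spec[1 : 1 + take]
    return out


def ewma(values: np.ndarray, alpha: float) -> float:
    """Final exponentially weighted moving average over the present values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("window has no present values")
    s = v[0]
    for x in v[1:]:
        s = alpha * x + (1.0 - alpha) * s
    return float(s)


# ---------------------------------------------------------------------------
# Vectorized per-stay matrix
# ---------------------------------------------------------------------------

def _ewma_sliding(V: np.ndarray, mask: np.ndarray, alpha: float) -> np.ndarray:
    """EWMA over present values for each row of a sliding-window view.

    The recursion over the m present values of a window unrolls to weights
    alpha*(1-alpha)^(m-k) for the k-th present value (k>=2) and
    (1-alpha)^(m-1) for the first, which vectorizes across windows.
    """
    m = mask.sum(axis=1)
    k = np.cumsum(mask, axis=1)
    with np.errstate(invalid="ignore"):
        w = alpha * (1.0 - alpha) ** (m[:, None] - k)
        first = (1.0 - alpha) ** np.maximum(m - 1, 0)
        w = np.where(k == 1, first[:, None], w)
    s = np.sum(np.where(mask, V, 0.0) * w * mask, axis=1)
    s[m == 0] = np.nan
    return s


def _dft_sliding(V: np.ndarray, mask: np.ndarray, n_coeffs: int) -> np.ndarray:
    """Leading non-DC DFT magnitudes for each row of a sliding-window view."""
    m = mask.sum(axis=1)
    safe_m = np.maximum(m, 1)
    mu = np.where(mask, V, 0.0).sum(axis=1) / safe_m
    dem = np.where(mask, V - mu[:, None], 0.0)
    spec = np.abs(np.fft.rfft(dem, axis=1))
    out = np.zeros((V.shape[0], n_coeffs))
    take = min(n_coeffs, spec.shape[1] - 1)
    if take > 0:
        out[:, :take] = spec[:, 1 : 1 + take]
    out[m == 0] = np.nan
    return out


def build_feature_matrix(
    series: VitalSeries, config: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """One feature row per minute with sufficient data in every window.

    Returns a DataFrame with ``stay_id``, ``end_minute`` and the ordered
    feature columns of :func:`feature_names`. Rows appear only from minute
    max(window_lengths)-1 onward and only where each (channel, window)
    completeness is at least ``min_completeness``.
    """
    T = series.n_minutes
    names = feature_names(config)
    w_max = max(config.window_lengths)
    if T < w_max:
        return pd.DataFrame(columns=["stay_id", "end_minute", *names])

    cols: dict[str, np.ndarray] = {}
    valid = np.zeros(T, dtype=bool)
    valid[w_max - 1 :] = True

    data = {ch: series.data[ch].to_numpy(dtype=float) for ch in config.channels}
    quantile_stats = {"q1": 0.25, "q3": 0.75, "median": 0.5}

    for ch in config.channels:
        x = data[ch]
        col = series.data[ch]
        for w in config.window_lengths:
            present_count = col.notna().rolling(w).sum().to_numpy()
            with np.errstate(invalid="ignore"):
                ok = (present_count / w) >= config.min_completeness
            ok &= ~np.isnan(present_count)
            valid &= np.where(np.isnan(present_count), False, ok)

            roll = col.rolling(w, min_periods=1)
            for stat in config.stat_set:
                if stat == "variance":
                    vals = roll.var(ddof=1)
                elif stat in quantile_stats:
                    vals = roll.quantile(quantile_stats[stat], interpolation="linear")
                elif stat == "mean":
                    vals = roll.mean()
                elif stat == "min":
                    vals = roll.min()
                else:
                    vals = roll.max()
                cols[f"{ch}_w{w}_{stat}"] = vals.to_numpy()

            V = sliding_window_view(x, w)  # row r ends at minute r + w - 1
            mask = ~np.isnan(V)
            mags = _dft_sliding(V, mask, config.dft_coeffs)
            full_mags = np.full((T, config.dft_coeffs), np.nan)
            full_mags[w - 1 :] = mags
            for k in range(1, config.dft_coeffs + 1):
                cols[f"{ch}_w{w}_dft{k}"] = full_mags[:, k - 1]
            sm = _ewma_sliding(V, mask, config.ewma_alpha)
            full_ewma = np.full(T, np.nan)
            full_ewma[w - 1 :] = sm
            cols[f"{ch}_w{w}_ewma"] = full_ewma

    out = pd.DataFrame({name: cols[name] for name in names})
    out.insert(0, "end_minute", np.arange(T))
    out.insert(0, "stay_id", series.stay_id)
    out = out.loc[valid].reset_index(drop=True)
    return out


def build_cohort_matrix(
    series_list: list[VitalSeries], config: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """Concatenated feature matrices for a list of stays."""
    frames = [build_feature_matrix(s, config) for s in series_list]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=["stay_id", "end_minute", *feature_names(config)])
    return pd.concat(frames, ignore_index=True)
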