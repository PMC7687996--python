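"""Event-aligned risk-score trajectories and group summaries.

Each stay's per-minute risk scores are re-indexed by *lead time* — minutes
remaining until the stay's alignment origin (first event onset for
hypotension stays, pseudo-onset for controls) — so both groups share a
common axis. Group summaries report the mean score and a normal 95 %
confidence band at each lead time, together with the number of
contributing stays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Half-width multiplier of the normal-approximation 95 % confidence band.
Z95 = 1.96


def align_trajectory(scores: pd.Series, origin_minute: int) -> pd.Series:
    """Re-index minute-indexed scores by lead time (origin - minute).

    Only minutes at or before the origin are kept (lead time >= 0);
    unscored minutes are simply absent. An origin before the first scored
    minute yields an empty alignment.
    """
    s = scores[scores.index <= origin_minute]
    out = pd.Series(s.to_numpy(), index=(origin_minute - s.index.to_numpy()), name="score")
    out.index.name = "lead_min"
    return out.sort_index()


def group_summary(
    aligned_by_stay: dict[str, pd.Series],
    group_by_stay: dict[str, str],
    grid: list[int] | np.ndarray,
) -> pd.DataFrame:
    """Mean and 95 % CI of the risk score per group per lead time.

    Lead times where a group has fewer than 2 contributing stays are
    omitted for that group (n is still reported as observed). Returns a
    DataFrame with columns group, lead_min, mean, ci_lo, ci_hi, n.
    """
    rows = []
    groups = sorted(set(group_by_stay.values()))
    for grp in groups:
        stays = [s for s, g in group_by_stay.items() if g == grp and s in aligned_by_stay]
        for lead in grid:
            vals = np.array(
                [
                    float(aligned_by_stay[s].loc[lead])
                    for s in stays
                    if lead in aligned_by_stay[s].index
                ]
            )
            n = len(vals)
            if n < 2:
                continue
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(n))
            rows.append((grp, int(lead), mean, mean - Z95 * se, mean + Z95 * se, n))
    return pd.DataFrame(rows, columns=["group", "lead_min", "mean", "ci_lo", "ci_hi", "n"])


def plot_group_summary(summary: pd.DataFrame, path) -> None:
    """Save the event-aligned mean-trajectory figure (mean with CI band,
    lead time decreasing toward the event on the right)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for grp, sub in summary.groupby("group"):
        sub = sub.sort_values("lead_min", ascending=False)
        x = -sub["lead_min"]
        ax.plot(x, sub["mean"], label=grp)
        ax.fill_between(x, sub["ci_lo"], sub["ci_hi"], alpha=0.25)
    ax.set_xlabel("minutes before (pseudo-)onset")
    ax.set_ylabel("mean risk score")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
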