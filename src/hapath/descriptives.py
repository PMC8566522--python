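"""Descriptive home-advantage summaries on game-pairs tables.

Per-game means by venue and crowd period, overall or per league, with
standard errors of the mean; plus the derived reduction statistics used when
comparing periods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hapath.errors import DegenerateDataError


def _cell_stats(group: pd.DataFrame, metric: str) -> tuple[float, float, int]:
    x = group[metric].to_numpy(dtype=float)
    n = len(x)
    se = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return float(x.mean()), se, n


def ha_summary(
    pairs: pd.DataFrame, metric: str = "points", by_league: bool = False
) -> pd.DataFrame:
    """Home/away per-game means and their difference, by period.

    Returns one row per (scope, period) with home mean, away mean, the
    home-minus-away difference and each mean's standard error
    (sample SD / sqrt(n)).  Periods or scopes absent from the data are
    absent from the output.
    """
    if metric not in pairs.columns:
        raise KeyError(f"unknown metric column {metric!r}")
    scopes = (
        [(lg, df) for lg, df in pairs.groupby("league_id", sort=True)]
        if by_league
        else [("overall", pairs)]
    )
    rows = []
    for scope, scoped in scopes:
        for period, chunk in scoped.groupby("period", sort=True):
            home = chunk[chunk["venue"] == "home"]
            away = chunk[chunk["venue"] == "away"]
            if home.empty or away.empty:
                continue
            h_mean, h_se, h_n = _cell_stats(home, metric)
            a_mean, a_se, _ = _cell_stats(away, metric)
            rows.append(
                {
                    "scope": scope,
                    "metric": metric,
                    "period": period,
                    "home_mean": h_mean,
                    "away_mean": a_mean,
                    "difference": h_mean - a_mean,
                    "home_se": h_se,
                    "away_se": a_se,
                    "n_games": h_n,
                }
            )
    return pd.DataFrame(rows)


def percent_reduction(pre_value: float, post_value: float) -> float:
    """Percentage drop from a pre-period value to a post-period value:
    ``(pre - post) / pre * 100``.

    Raises
    ------
    DegenerateDataError
        If ``pre_value`` is zero (reduction undefined).
    """
    if pre_value == 0:
        raise DegenerateDataError("percent reduction undefined for pre_value = 0")
    return (pre_value - post_value) / pre_value * 100.0


def advantage_change(home_change: float, away_change: float) -> float:
    """Change in the home-minus-away advantage between periods.

    Inputs are each side's signed post-minus-pre change in a per-game
    metric.  Returns ``away_change - home_change``, i.e. the pre-period
    advantage minus the post-period advantage; positive means the home
    advantage shrank.
    """
    return away_change - home_change


def share_percent(part: float, total: float) -> float:
    """Share of a total as a percentage."""
    if total <= 0:
        raise DegenerateDataError("total must be positive")
    return part / total * 100.0


def plot_ha(summary: pd.DataFrame, ax=None):
    """Grouped bar plot of home/away means by period for one metric."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    periods = list(summary["period"])
    x = np.arange(len(periods))
    width = 0.35
    ax.bar(x - width / 2, summary["home_mean"], width,
           yerr=summary["home_se"], label="home", capsize=3)
    ax.bar(x + width / 2, summary["away_mean"], width,
           yerr=summary["away_se"], label="away", capsize=3)
    ax.set_xticks(x)
    ax.set_xticklabels(periods)
    metric = summary["metric"].iloc[0] if len(summary) else ""
    ax.set_ylabel(f"{metric} per game")
    ax.legend()
    return ax
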