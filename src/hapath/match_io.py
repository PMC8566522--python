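"""Match-table data model and transformations.

The canonical unit is one played match, stored as one CSV row with both
sides' indicators (goals, corners, shots, shots on target, fouls, yellow and
red cards), covariates (strength rating, match importance) and a crowd-period
flag.  Two derived granularities are provided:

* the *game-pairs* table, with one row per team per match (venue as a
  factor), and
* the *team aggregate* table, with one row per team x venue x period cell
  holding per-game means.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from hapath.errors import SchemaError

logger = logging.getLogger(__name__)

#: Crowd-period levels: ``crowd`` = spectators present, ``no_crowd`` = behind
#: closed doors.
PERIODS = ("crowd", "no_crowd")

#: Venue levels in the game-pairs table.
VENUES = ("home", "away")

#: Per-side count indicators, in canonical order.
SIDE_INDICATORS = (
    "goals",
    "corners",
    "shots",
    "shots_on_target",
    "fouls",
    "yellows",
    "reds",
)

#: Per-side real-valued covariates.
SIDE_COVARIATES = ("rating", "importance")

#: Canonical match-CSV column order.
MATCH_COLUMNS = (
    "league_id",
    "match_id",
    "round",
    "period",
    "home_team",
    "away_team",
    *[f"{side}_{ind}" for ind in SIDE_INDICATORS for side in ("home", "away")],
    *[f"{side}_{cov}" for cov in SIDE_COVARIATES for side in ("home", "away")],
)

#: Columns of the game-pairs table.
PAIR_COLUMNS = (
    "league_id",
    "match_id",
    "round",
    "period",
    "team_id",
    "opponent_id",
    "venue",
    "points",
    "goals_for",
    "goals_against",
    "corners",
    "shots",
    "shots_on_target",
    "fouls",
    "yellows",
    "reds",
    "rating",
    "importance",
    "opp_rating",
    "opp_importance",
)

#: Indicator columns of a game-pairs row that enter the latent constructs.
PAIR_INDICATORS = (
    "points",
    "goals_for",
    "corners",
    "shots",
    "shots_on_target",
    "fouls",
    "yellows",
    "reds",
)


def derive_points(goals_for: int, goals_against: int) -> int:
    """League points from a final score: 3 for a win, 1 for a draw, 0 for a
    loss.

    Raises
    ------
    ValueError
        If either goal count is negative.
    """
    if goals_for < 0 or goals_against < 0:
        raise ValueError("goal counts must be non-negative")
    if goals_for > goals_against:
        return 3
    if goals_for == goals_against:
        return 1
    return 0


def validate_matches(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a match table against the canonical schema.

    Rows with missing values in any model indicator are dropped (listwise
    deletion) with a logged count.  Returns the validated frame.

    Raises
    ------
    SchemaError
        If a mandatory column is absent.
    ValueError
        If the ``period`` column has values outside ``PERIODS``, a side plays
        itself, counts are negative, or shots on target exceed shots.
    """
    missing = [c for c in MATCH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"match table missing mandatory columns: {missing}")
    df = df.loc[:, list(MATCH_COLUMNS)].copy()

    bad_period = ~df["period"].isin(PERIODS)
    if bad_period.any():
        raise ValueError(
            f"unparseable period values: {sorted(df.loc[bad_period, 'period'].unique())}"
        )

    indicator_cols = [
        f"{side}_{ind}" for ind in SIDE_INDICATORS for side in ("home", "away")
    ]
    n_before = len(df)
    df = df.dropna(subset=indicator_cols)
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("listwise deletion: dropped %d row(s) with missing indicators",
                    n_dropped)

    if (df["home_team"] == df["away_team"]).any():
        raise ValueError("a team cannot play itself")
    counts = df[indicator_cols].to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("count indicators must be non-negative")
    for side in ("home", "away"):
        if (df[f"{side}_shots_on_target"] > df[f"{side}_shots"]).any():
            raise ValueError(f"{side}: shots_on_target exceeds shots")
    df[indicator_cols] = df[indicator_cols].astype(int)
    return df.reset_index(drop=True)


def read_matches(path) -> pd.DataFrame:
    """Read and validate a canonical match CSV."""
    return validate_matches(pd.read_csv(path))


def write_matches(df: pd.DataFrame, path) -> None:
    """Write a match table in the canonical column order."""
    df.loc[:, list(MATCH_COLUMNS)].to_csv(path, index=False)


def assign_period_by_round(df: pd.DataFrame, cutoff_round: dict | int) -> pd.DataFrame:
    """Set the ``period`` column from a round threshold.

    ``cutoff_round`` may be a single ordinal or a ``{league_id: ordinal}``
    mapping; rounds at or beyond the threshold are labelled ``no_crowd``.
    """
    df = df.copy()
    if isinstance(cutoff_round, dict):
        cut = df["league_id"].map(cutoff_round)
        if cut.isna().any():
            raise ValueError("cutoff_round mapping missing some leagues")
    else:
        cut = cutoff_round
    df["period"] = np.where(df["round"] >= cut, "no_crowd", "crowd")
    return df


def to_game_pairs(matches: pd.DataFrame) -> pd.DataFrame:
    """Expand a match table into the game-pairs representation.

    Every match contributes exactly two rows, one from each side's
    perspective, with venue as a factor and the opponent's covariates
    attached.
    """
    halves = []
    for venue, own, opp in (("home", "home", "away"), ("away", "away", "home")):
        half = pd.DataFrame(
            {
                "league_id": matches["league_id"],
                "match_id": matches["match_id"],
                "round": matches["round"],
                "period": matches["period"],
                "team_id": matches[f"{own}_team"],
                "opponent_id": matches[f"{opp}_team"],
                "venue": venue,
                "goals_for": matches[f"{own}_goals"],
                "goals_against": matches[f"{opp}_goals"],
                "corners": matches[f"{own}_corners"],
                "shots": matches[f"{own}_shots"],
                "shots_on_target": matches[f"{own}_shots_on_target"],
                "fouls": matches[f"{own}_fouls"],
                "yellows": matches[f"{own}_yellows"],
                "reds": matches[f"{own}_reds"],
                "rating": matches[f"{own}_rating"],
                "importance": matches[f"{own}_importance"],
                "opp_rating": matches[f"{opp}_rating"],
                "opp_importance": matches[f"{opp}_importance"],
            }
        )
        halves.append(half)
    pairs = pd.concat(halves, ignore_index=True)
    pairs["points"] = [
        derive_points(gf, ga)
        for gf, ga in zip(pairs["goals_for"], pairs["goals_against"])
    ]
    pairs = pairs.sort_values(["match_id", "venue"], ascending=[True, False],
                              kind="stable").reset_index(drop=True)
    return pairs.loc[:, list(PAIR_COLUMNS)]


#: Columns averaged when aggregating game pairs to team cells.
AGGREGATE_MEAN_COLUMNS = (
    "points",
    "goals_for",
    "goals_against",
    "corners",
    "shots",
    "shots_on_target",
    "fouls",
    "yellows",
    "reds",
    "rating",
    "importance",
    "opp_rating",
    "opp_importance",
)


def aggregate_team_venue_period(
    pairs: pd.DataFrame, value_columns: tuple[str, ...] = AGGREGATE_MEAN_COLUMNS
) -> pd.DataFrame:
    """Unweighted per-game means per team x venue x period cell.

    Cells absent from the data are absent from the output; an empty input
    yields an empty output.  ``points`` and ``goals_for`` means are also
    exposed as ``points_pg`` and ``goals_pg``.
    """
    if pairs.empty:
        cols = ["team_id", "league_id", "venue", "period", "n_games",
                *value_columns, "points_pg", "goals_pg"]
        return pd.DataFrame(columns=cols)
    keys = ["team_id", "league_id", "venue", "period"]
    grouped = pairs.groupby(keys, sort=True, observed=True)
    agg = grouped[list(value_columns)].mean()
    agg["n_games"] = grouped.size()
    agg = agg.reset_index()
    if "points" in agg.columns:
        agg["points_pg"] = agg["points"]
    if "goals_for" in agg.columns:
        agg["goals_pg"] = agg["goals_for"]
    return agg
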