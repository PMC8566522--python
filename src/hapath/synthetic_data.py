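"""Simulator for paired match tables with a known structural model.

Matches are generated league by league on round-robin schedules.  For each
side of each match three latent constructs — team performance, referee
decisions, outcome — follow Gaussian structural equations whose path
coefficients differ between the crowd and no-crowd periods, with team and
league random intercepts.  Observed count indicators are rounded,
truncated-at-zero transforms of the latents around per-indicator baseline
rates; goals are Poisson with a log-mean shifted by the outcome latent, and
points follow deterministically from the paired scores.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hapath import match_io
from hapath.errors import ConfigurationError

#: Indicators attached to each latent construct.
CONSTRUCT_INDICATORS = {
    "performance": ("corners", "shots", "shots_on_target"),
    "referee": ("fouls", "yellows", "reds"),
}


@dataclass
class StructuralParams:
    """Structural path coefficients, one value per crowd regime.

    ``a1``: venue -> team performance; ``a2``: venue -> referee decisions;
    ``d``: team performance -> referee decisions; ``b1``/``b2``: mediator ->
    outcome; ``c``: direct venue -> outcome; ``gamma_*``: control-covariate
    coefficients (applied to the performance equation).  The ``_pre`` suffix
    is the crowd period, ``_post`` the no-crowd period.
    """

    a1_pre: float = 0.0
    a1_post: float = 0.0
    a2_pre: float = 0.0
    a2_post: float = 0.0
    d_pre: float = 0.0
    d_post: float = 0.0
    b1_pre: float = 0.0
    b1_post: float = 0.0
    b2_pre: float = 0.0
    b2_post: float = 0.0
    c_pre: float = 0.0
    c_post: float = 0.0
    gamma_rating: float = 0.0
    gamma_importance: float = 0.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ConfigurationError(f"StructuralParams.{f.name} must be finite")

    def per_period(self, name: str) -> tuple[float, float]:
        """Return ``(pre, post)`` values for a path symbol such as ``a1``."""
        return getattr(self, f"{name}_pre"), getattr(self, f"{name}_post")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StructuralParams":
        return cls(**d)


def _default_loadings() -> dict:
    return {
        "corners": 0.8,
        "shots": 0.85,
        "shots_on_target": 0.8,
        "fouls": 0.8,
        "yellows": 0.75,
        "reds": 0.5,
    }


def _default_noise() -> dict:
    return {k: 0.6 for k in _default_loadings()}


def _default_rates() -> dict:
    return {
        "corners": 5.0,
        "shots": 12.0,
        "shots_on_target": 4.0,
        "fouls": 12.0,
        "yellows": 2.0,
        "reds": 0.12,
        "goals": 1.35,
    }


@dataclass
class SimulationConfig:
    """Full description of one synthetic season.

    ``post_share`` is the target fraction of matches played in the no-crowd
    period; the split is chronological (late rounds lose the crowd).
    ``goal_slope`` scales how strongly the outcome latent shifts the Poisson
    log-mean of a side's goals.
    """

    n_leagues: int = 4
    teams_per_league: int = 10
    rounds: int = 18
    post_share: float = 0.26
    seed: int = 0
    true_paths: StructuralParams = field(default_factory=StructuralParams)
    team_sd: float = 0.3
    league_sd: float = 0.2
    indicator_loadings: dict = field(default_factory=_default_loadings)
    indicator_noise: dict = field(default_factory=_default_noise)
    baseline_rates: dict = field(default_factory=_default_rates)
    goal_slope: float = 0.35

    def __post_init__(self):
        if self.n_leagues < 1:
            raise ConfigurationError("n_leagues must be >= 1")
        if self.teams_per_league < 2:
            raise ConfigurationError("teams_per_league must be >= 2")
        if self.rounds < 1:
            raise ConfigurationError("rounds must be >= 1")
        if not 0.0 < self.post_share < 1.0:
            raise ConfigurationError("post_share must lie in (0, 1)")
        if self.team_sd < 0 or self.league_sd < 0:
            raise ConfigurationError("random-intercept SDs must be >= 0")
        for k, v in self.baseline_rates.items():
            if v <= 0:
                raise ConfigurationError(f"baseline_rates[{k!r}] must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        tp = d.get("true_paths", {})
        if isinstance(tp, dict):
            d["true_paths"] = StructuralParams.from_dict(tp)
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _round_robin(n_teams: int, rounds: int) -> list[list[tuple[int, int]]]:
    """Circle-method schedule: list of rounds, each a list of (home, away)
    index pairs.  Venues alternate between successive meetings."""
    teams = list(range(n_teams))
    bye = None
    if n_teams % 2 == 1:
        teams.append(-1)
        bye = -1
    n = len(teams)
    base = teams[1:]
    schedule = []
    for r in range(rounds):
        rot = base[-(r % (n - 1)):] + base[: -(r % (n - 1))] if r % (n - 1) else base
        order = [teams[0]] + rot
        games = []
        for i in range(n // 2):
            t1, t2 = order[i], order[n - 1 - i]
            if bye in (t1, t2):
                continue
            # alternate venue by round parity and by full-cycle count
            flip = (r % 2 == 1) ^ (r // (n - 1) % 2 == 1)
            games.append((t2, t1) if flip else (t1, t2))
        schedule.append(games)
    return schedule


def simulate_matches(
    config: SimulationConfig, return_latents: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a match table with known ground-truth structure.

    Parameters
    ----------
    config
        Validated :class:`SimulationConfig`.
    return_latents
        When true, also return a frame of the generating latent values with
        one row per (match, venue), mergeable onto the game-pairs table.

    Returns
    -------
    matches : pandas.DataFrame
        Canonical match table (see :mod:`hapath.match_io`), with the seed
        recorded in ``matches.attrs['seed']``.
    latents : pandas.DataFrame, optional
        Columns ``match_id, venue, team_id, latent_performance,
        latent_referee, latent_outcome``.
    """
    rng = np.random.default_rng(config.seed)
    p = config.true_paths

    teams = []
    for lg in range(config.n_leagues):
        for t in range(config.teams_per_league):
            teams.append((f"L{lg:02d}", f"L{lg:02d}T{t:02d}"))
    team_index = {tid: i for i, (_, tid) in enumerate(teams)}
    league_ids = sorted({lg for lg, _ in teams})
    league_index = {lid: i for i, lid in enumerate(league_ids)}

    # team/league random intercepts, one per construct
    constructs = ("performance", "referee", "outcome")
    u_team = {
        k: rng.normal(0.0, config.team_sd, size=len(teams)) for k in constructs
    }
    u_league = {
        k: rng.normal(0.0, config.league_sd, size=len(league_ids)) for k in constructs
    }

    # covariates: ratings per team around a league-centred mean; importance
    # per match side uniform on a positive range
    league_centre = rng.normal(70.0, 4.0, size=len(league_ids))
    team_rating = np.array(
        [rng.normal(league_centre[league_index[lg]], 8.0) for lg, _ in teams]
    )
    rating_z_all = (team_rating - team_rating.mean()) / team_rating.std()

    cutoff = int(np.ceil(config.rounds * (1.0 - config.post_share)))
    cutoff = min(max(cutoff, 1), config.rounds)  # keep both periods non-empty
    if config.rounds == 1:
        cutoff = 1

    rows = []
    latent_rows = []
    match_counter = 0
    for lg_i, lid in enumerate(league_ids):
        schedule = _round_robin(config.teams_per_league, config.rounds)
        for r, games in enumerate(schedule):
            period = "crowd" if r < cutoff else "no_crowd"
            post = period == "no_crowd"
            a1 = p.a1_post if post else p.a1_pre
            a2 = p.a2_post if post else p.a2_pre
            d = p.d_post if post else p.d_pre
            b1 = p.b1_post if post else p.b1_pre
            b2 = p.b2_post if post else p.b2_pre
            c = p.c_post if post else p.c_pre
            for hi, ai in games:
                home = f"{lid}T{hi:02d}"
                away = f"{lid}T{ai:02d}"
                mid = f"M{match_counter:06d}"
                match_counter += 1
                imp = rng.uniform(0.0, 100.0, size=2)
                imp_z = (imp - 50.0) / (100.0 / np.sqrt(12.0))
                side_vals = {}
                for side, tid, venue_flag, iz in (
                    ("home", home, 1.0, imp_z[0]),
                    ("away", away, 0.0, imp_z[1]),
                ):
                    ti = team_index[tid]
                    rz = rating_z_all[ti]
                    tp = (
                        a1 * venue_flag
                        + p.gamma_rating * rz
                        + p.gamma_importance * iz
                        + u_team["performance"][ti]
                        + u_league["performance"][lg_i]
                        + rng.normal()
                    )
                    rd = (
                        a2 * venue_flag
                        + d * tp
                        + u_team["referee"][ti]
                        + u_league["referee"][lg_i]
                        + rng.normal()
                    )
                    out = (
                        c * venue_flag
                        + b1 * tp
                        + b2 * rd
                        + u_team["outcome"][ti]
                        + u_league["outcome"][lg_i]
                        + rng.normal()
                    )
                    inds = {}
                    for construct, latent in (("performance", tp), ("referee", rd)):
                        for name in CONSTRUCT_INDICATORS[construct]:
                            base = config.baseline_rates[name]
                            scale = np.sqrt(base)
                            lam = config.indicator_loadings[name]
                            sig = config.indicator_noise[name]
                            val = base + scale * (lam * latent + sig * rng.normal())
                            inds[name] = max(0, int(round(val)))
                    inds["shots_on_target"] = min(
                        inds["shots_on_target"], inds["shots"]
                    )
                    lam_goal = config.baseline_rates["goals"] * np.exp(
                        config.goal_slope * out
                    )
                    inds["goals"] = int(rng.poisson(lam_goal))
                    side_vals[side] = (tid, inds, imp[0 if side == "home" else 1])
                    latent_rows.append(
                        {
                            "match_id": mid,
                            "venue": side,
                            "team_id": tid,
                            "latent_performance": tp,
                            "latent_referee": rd,
                            "latent_outcome": out,
                        }
                    )
                row = {
                    "league_id": lid,
                    "match_id": mid,
                    "round": r + 1,
                    "period": period,
                    "home_team": home,
                    "away_team": away,
                }
                for side in ("home", "away"):
                    tid, inds, importance = side_vals[side]
                    for name in match_io.SIDE_INDICATORS:
                        row[f"{side}_{name}"] = inds[name]
                    row[f"{side}_rating"] = round(team_rating[team_index[tid]], 3)
                    row[f"{side}_importance"] = round(importance, 3)
                rows.append(row)

    matches = pd.DataFrame(rows, columns=list(match_io.MATCH_COLUMNS))
    matches = match_io.validate_matches(matches)
    matches.attrs["seed"] = config.seed
    if return_latents:
        return matches, pd.DataFrame(latent_rows)
    return matches


def ground_truth_effects(
    params: StructuralParams, include_serial_in_total: bool = False
) -> pd.DataFrame:
    """Closed-form effect decomposition implied by structural parameters.

    Returns a tidy frame with one row per (quantity, period) plus the
    post-minus-pre delta rows.  Written independently of
    :func:`hapath.effects.compose_effects` so the two can cross-check each
    other.
    """
    rows = []
    values = {}
    for period in ("pre", "post"):
        a1 = getattr(params, f"a1_{period}")
        a2 = getattr(params, f"a2_{period}")
        d = getattr(params, f"d_{period}")
        b1 = getattr(params, f"b1_{period}")
        b2 = getattr(params, f"b2_{period}")
        c = getattr(params, f"c_{period}")
        q = {
            "direct": c,
            "indirect_via_performance": a1 * b1,
            "indirect_via_referee": a2 * b2,
            "serial_indirect": a1 * d * b2,
            "indirect_on_referee_via_performance": a1 * d,
            "total_on_referee": a2 + a1 * d,
        }
        q["total_on_outcome"] = (
            c
            + q["indirect_via_performance"]
            + q["indirect_via_referee"]
            + (q["serial_indirect"] if include_serial_in_total else 0.0)
        )
        values[period] = q
        rows.extend(
            {"quantity": k, "period": period, "estimate": v} for k, v in q.items()
        )
    for k in values["pre"]:
        rows.append(
            {
                "quantity": k,
                "period": "delta",
                "estimate": values["post"][k] - values["pre"][k],
            }
        )
    return pd.DataFrame(rows, columns=["quantity", "period", "estimate"])
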