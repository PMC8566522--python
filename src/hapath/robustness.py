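"""Robustness harnesses: leave-one-league-out refits and the
home-minus-away difference specification."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from hapath import effects as effects_mod
from hapath import ham_model
from hapath.errors import ConfigurationError, IntegrityError

#: Headline deltas tracked in the stability summary.
HEADLINE_DELTAS = (
    "a1",
    "a2",
    "d",
    "indirect_via_performance",
    "indirect_via_referee",
    "total_on_outcome",
    "total_on_referee",
)


@dataclasses.dataclass
class RobustnessReport:
    """One effect report per variant plus a stability summary."""

    variants: dict[str, pd.DataFrame]
    draws: dict[str, ham_model.PathDraws]
    stability: pd.DataFrame

    def any_sign_reversal(self) -> bool:
        return bool(self.stability["sign_reversal"].any())


def _stability_table(
    variants: dict[str, pd.DataFrame], reference: pd.DataFrame
) -> pd.DataFrame:
    rows = []
    for quantity in HEADLINE_DELTAS:
        ref = reference[
            (reference["quantity"] == quantity) & (reference["period"] == "delta")
        ].iloc[0]
        ests = {
            label: float(
                rep.loc[
                    (rep["quantity"] == quantity) & (rep["period"] == "delta"),
                    "estimate",
                ].iloc[0]
            )
            for label, rep in variants.items()
        }
        vals = np.array(list(ests.values()))
        reversal = bool(
            ref["significant"] and np.any(np.sign(vals) != np.sign(ref["estimate"]))
        )
        rows.append(
            {
                "quantity": quantity,
                "reference_delta": float(ref["estimate"]),
                "min_delta": float(vals.min()),
                "max_delta": float(vals.max()),
                "range": float(vals.max() - vals.min()),
                "sign_reversal": reversal,
            }
        )
    return pd.DataFrame(rows)


def leave_one_league_out(
    scored_pairs: pd.DataFrame, spec: ham_model.ModelSpec
) -> RobustnessReport:
    """Refit the model once per league, each time excluding that league.

    Every refit reuses the main fit's seed and estimation settings for
    comparability.  Raises for single-league data.
    """
    leagues = sorted(scored_pairs["league_id"].unique())
    if len(leagues) < 2:
        raise ConfigurationError("leave-one-league-out needs at least 2 leagues")
    reference_draws = ham_model.fit_ham(scored_pairs, spec)
    reference = effects_mod.compose_effects(reference_draws)
    variants = {}
    draws = {}
    for league in leagues:
        subset = scored_pairs[scored_pairs["league_id"] != league]
        fit = ham_model.fit_ham(subset, spec)
        label = f"drop_{league}"
        draws[label] = fit
        variants[label] = effects_mod.compose_effects(fit)
    return RobustnessReport(
        variants=variants,
        draws=draws,
        stability=_stability_table(variants, reference),
    )


def difference_frame(scored_pairs: pd.DataFrame) -> pd.DataFrame:
    """Home-minus-away differences per match.

    Collapses each game pair into one row: score and covariate differences
    (home minus away), the crowd flag, and the home team/league for the
    random terms.  The venue factor disappears; its role is taken by the
    equation intercepts.
    """
    home = scored_pairs[scored_pairs["venue"] == "home"].set_index("match_id")
    away = scored_pairs[scored_pairs["venue"] == "away"].set_index("match_id")
    if len(home) != len(away) or not home.index.sort_values().equals(
        away.index.sort_values()
    ):
        raise IntegrityError("pairs table is not fully paired by match_id")
    away = away.reindex(home.index)
    diff = pd.DataFrame(
        {
            "match_id": home.index,
            "league_id": home["league_id"].to_numpy(),
            "team_id": home["team_id"].to_numpy(),
            "period": home["period"].to_numpy(),
            "rating": (home["rating"] - away["rating"]).to_numpy(),
            "importance": (home["importance"] - away["importance"]).to_numpy(),
        }
    )
    for construct in ham_model.EQUATIONS:
        col = f"score_{construct}"
        diff[col] = (home[col] - away[col]).to_numpy()
    return diff.reset_index(drop=True)


def fit_difference_spec(
    scored_pairs: pd.DataFrame, spec: ham_model.ModelSpec
) -> tuple[pd.DataFrame, ham_model.PathDraws]:
    """Fit the difference specification and compose its effects.

    In the difference model the equation intercept is the venue effect, so
    the intercept and its crowd interaction are relabelled to the usual path
    symbols (a1/a2/c and their deltas) before effect composition.
    """
    diff = difference_frame(scored_pairs)
    frame = diff.copy()
    frame["venue_flag"] = 0.0  # venue factor dropped; intercept carries it
    frame["nocrowd_flag"] = (frame["period"] == "no_crowd").astype(float)
    for cov in ("rating", "importance"):
        x = frame[cov].to_numpy(dtype=float)
        sd = x.std()
        frame[f"{cov}_z"] = 0.0 if sd == 0 else (x - x.mean()) / sd

    draws = ham_model.fit_ham(frame, spec)
    # venue columns are identically zero here; their draws are prior noise
    params = {
        k: v
        for k, v in draws.params.items()
        if k not in {"a1", "a1_delta", "a2", "a2_delta", "c", "c_delta"}
    }
    relabel = {
        "intercept_performance": "a1",
        "intercept_performance_delta": "a1_delta",
        "intercept_referee": "a2",
        "intercept_referee_delta": "a2_delta",
        "intercept_outcome": "c",
        "intercept_outcome_delta": "c_delta",
    }
    params = {relabel.get(k, k): v for k, v in params.items()}
    relabelled = ham_model.PathDraws(
        params,
        diagnostics=draws.diagnostics,
        converged=draws.converged,
        interval_level=draws.interval_level,
        equations=draws.equations,
        meta={**draws.meta, "variant": "difference_spec"},
    )
    return effects_mod.compose_effects(relabelled), relabelled
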