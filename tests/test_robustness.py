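import numpy as np
import pandas as pd
import pytest

from hapath import ham_model, match_io, robustness, synthetic_data
from hapath.errors import ConfigurationError, IntegrityError
from tests.conftest import quick_estimation


@pytest.fixture(scope="module")
def truth_scored(small_sim):
    return ham_model.attach_true_latents(small_sim["pairs"], small_sim["latents"])


def _boot_spec(seed=0):
    return ham_model.ModelSpec(
        granularity="team_aggregate",
        estimation=quick_estimation(seed=seed, engine="bootstrap"),
    )


class TestLeaveOneLeagueOut:
    def test_variant_structure(self, truth_scored):
        three = truth_scored[truth_scored["league_id"].isin(["L00", "L01", "L02"])]
        report = robustness.leave_one_league_out(three, _boot_spec())
        assert len(report.variants) == 3
        for league in ("L00", "L01", "L02"):
            assert f"drop_{league}" in report.variants

    def test_reconstitution(self, truth_scored):
        leagues = sorted(truth_scored["league_id"].unique())
        for league in leagues:
            kept = truth_scored[truth_scored["league_id"] != league]
            dropped = truth_scored[truth_scored["league_id"] == league]
            rebuilt = pd.concat([kept, dropped]).sort_index()
            pd.testing.assert_frame_equal(rebuilt, truth_scored)

    def test_homogeneous_variants_agree(self, truth_scored):
        report = robustness.leave_one_league_out(truth_scored, _boot_spec())
        summaries = {
            label: d.summary().set_index("param").loc["a1_pre"]
            for label, d in report.draws.items()
        }
        for la, sa in summaries.items():
            for lb, sb in summaries.items():
                assert sb["lower"] <= sa["median"] <= sb["upper"], (la, lb)

    def test_outlier_league_moves_estimate_most(self, fig_params):
        cfg = synthetic_data.SimulationConfig(
            n_leagues=4, teams_per_league=10, rounds=16, post_share=0.25,
            seed=13, true_paths=fig_params,
        )
        matches, latents = synthetic_data.simulate_matches(cfg, return_latents=True)
        pairs = match_io.to_game_pairs(matches)
        scored = ham_model.attach_true_latents(pairs, latents)
        # reverse the venue effect on performance for one league by reflecting
        # the home/away latent difference
        outlier = "L03"
        mask = scored["league_id"] == outlier
        home = mask & (scored["venue"] == "home")
        away = mask & (scored["venue"] == "away")
        perf = scored["score_performance"].copy()
        scored.loc[home, "score_performance"] = perf[home] - 2 * fig_params.a1_pre
        report = robustness.leave_one_league_out(scored, _boot_spec(seed=3))
        full_like = {
            label: abs(d.summary().set_index("param").loc["a1_pre", "median"])
            for label, d in report.draws.items()
        }
        # dropping the corrupted league restores the largest venue effect
        assert max(full_like, key=full_like.get) == f"drop_{outlier}"

    def test_single_league_raises(self, truth_scored):
        one = truth_scored[truth_scored["league_id"] == "L00"]
        with pytest.raises(ConfigurationError):
            robustness.leave_one_league_out(one, _boot_spec())

    def test_stability_table(self, truth_scored):
        three = truth_scored[truth_scored["league_id"].isin(["L00", "L01"])]
        report = robustness.leave_one_league_out(three, _boot_spec())
        assert set(report.stability["quantity"]) == set(robustness.HEADLINE_DELTAS)
        assert (report.stability["range"] >= 0).all()


class TestDifferenceSpec:
    def test_symmetric_pairs_zero_differences(self, truth_scored):
        sym = truth_scored.copy()
        for col in ("score_performance", "score_referee", "score_outcome",
                    "rating", "importance"):
            per_match = sym.groupby("match_id")[col].transform("mean")
            sym[col] = per_match
        diff = robustness.difference_frame(sym)
        for col in ("score_performance", "score_referee", "score_outcome"):
            assert np.allclose(diff[col], 0.0)

    def test_antisymmetry(self, truth_scored):
        diff = robustness.difference_frame(truth_scored)
        swapped = truth_scored.copy()
        swapped["venue"] = swapped["venue"].map({"home": "away", "away": "home"})
        diff_swapped = robustness.difference_frame(swapped)
        merged = diff.merge(diff_swapped, on="match_id", suffixes=("", "_sw"))
        assert np.allclose(
            merged["score_outcome"], -merged["score_outcome_sw"]
        )

    def test_unpaired_rows_raise(self, truth_scored):
        broken = truth_scored.drop(index=truth_scored.index[0])
        with pytest.raises(IntegrityError):
            robustness.difference_frame(broken)

    def test_effect_report_produced(self, truth_scored):
        spec = ham_model.ModelSpec(
            granularity="per_game",
            estimation=quick_estimation(seed=0, engine="bootstrap"),
        )
        report, draws = robustness.fit_difference_spec(truth_scored, spec)
        assert {"quantity", "period", "estimate"} <= set(report.columns)
        # venue effect on performance shows up through the intercept relabel
        a1_pre = report.set_index(["quantity", "period"]).loc[("a1", "pre")]
        assert a1_pre["estimate"] > 0.3

    def test_concordance_with_main_spec(self, fig_params):
        """Delta signs from the difference spec agree with the main spec."""
        agree = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = synthetic_data.SimulationConfig(
                n_leagues=3, teams_per_league=8, rounds=14, post_share=0.3,
                seed=300 + rep, true_paths=fig_params,
            )
            matches, latents = synthetic_data.simulate_matches(
                cfg, return_latents=True
            )
            pairs = match_io.to_game_pairs(matches)
            scored = ham_model.attach_true_latents(pairs, latents)
            spec = ham_model.ModelSpec(
                granularity="per_game",
                estimation=quick_estimation(seed=rep, engine="bootstrap"),
            )
            main = ham_model.fit_ham(scored, spec)
            diff_rep, _ = robustness.fit_difference_spec(scored, spec)
            main_delta = float(np.median(main.flat("a1_delta")))
            diff_delta = float(
                diff_rep.set_index(["quantity", "period"]).loc[
                    ("a1", "delta"), "estimate"
                ]
            )
            agree += int(np.sign(main_delta) == np.sign(diff_delta))
        assert agree >= 18
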