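import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from hapath import ham_model
from hapath.errors import ConfigurationError, DegenerateDataError, IntegrityError
from tests.conftest import quick_estimation


@pytest.fixture(scope="module")
def truth_scored(small_sim):
    return ham_model.attach_true_latents(small_sim["pairs"], small_sim["latents"])


@pytest.fixture(scope="module")
def truth_draws(truth_scored):
    spec = ham_model.ModelSpec(granularity="per_game",
                               estimation=quick_estimation(seed=3))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ham_model.fit_ham(truth_scored, spec)


def _synthetic_frame(n_teams=20, rows_per_team=10, noise=1.0, seed=0,
                     outcome_fn=None):
    """Hand-built scored model frame (no simulator) for estimator tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_teams):
        for i in range(rows_per_team):
            tp = rng.standard_normal()
            rd = rng.standard_normal()
            venue = "home" if i % 2 == 0 else "away"
            period = "crowd" if i < rows_per_team * 0.7 else "no_crowd"
            rows.append(
                {
                    "team_id": f"t{t:03d}",
                    "league_id": f"L{t % 4}",
                    "venue": venue,
                    "period": period,
                    "rating": rng.normal(70, 8),
                    "importance": rng.uniform(0, 100),
                    "score_performance": tp,
                    "score_referee": rd,
                }
            )
    frame = pd.DataFrame(rows)
    if outcome_fn is None:
        outcome_fn = lambda f, r: noise * r.standard_normal(len(f))
    frame["score_outcome"] = outcome_fn(frame, np.random.default_rng(seed + 1))
    return frame


class TestSettingsValidation:
    def test_too_few_draws(self):
        with pytest.raises(ConfigurationError, match="500"):
            ham_model.EstimationSettings(chains=1, draws_per_chain=100)

    def test_bad_interval(self):
        with pytest.raises(ConfigurationError, match="interval"):
            ham_model.EstimationSettings(interval_level=0.3)

    def test_bad_engine(self):
        with pytest.raises(ConfigurationError, match="engine"):
            ham_model.EstimationSettings(engine="magic")

    def test_bad_granularity(self):
        with pytest.raises(ConfigurationError, match="granularity"):
            ham_model.ModelSpec(granularity="per_planet")


class TestFitHam:
    def test_recovers_venue_path(self, truth_draws, fig_params):
        summ = truth_draws.summary().set_index("param")
        lo, hi = summ.loc["a1_pre", "lower"], summ.loc["a1_pre", "upper"]
        assert lo < fig_params.a1_pre < hi
        assert summ.loc["a1_pre", "median"] == pytest.approx(
            fig_params.a1_pre, abs=0.35
        )

    def test_diagnostics_populated(self, truth_draws):
        d = truth_draws.diagnostics
        assert d is not None
        assert {"param", "rhat", "ess"} <= set(d.columns)
        assert np.isfinite(d["rhat"]).all()

    def test_seed_reproducibility_mcmc(self, truth_scored):
        spec = ham_model.ModelSpec(granularity="team_aggregate",
                                   estimation=quick_estimation(seed=5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = ham_model.fit_ham(truth_scored, spec)
            b = ham_model.fit_ham(truth_scored, spec)
        pd.testing.assert_frame_equal(a.summary(), b.summary())

    def test_seed_reproducibility_bootstrap(self, truth_scored):
        spec = ham_model.ModelSpec(
            granularity="team_aggregate",
            estimation=quick_estimation(seed=5, engine="bootstrap"),
        )
        a = ham_model.fit_ham(truth_scored, spec)
        b = ham_model.fit_ham(truth_scored, spec)
        pd.testing.assert_frame_equal(a.summary(), b.summary())

    def test_single_league_drops_league_term(self, truth_scored):
        one = truth_scored[truth_scored["league_id"] == "L00"]
        spec = ham_model.ModelSpec(
            granularity="per_game",
            estimation=quick_estimation(seed=1, engine="bootstrap"),
        )
        with pytest.warns(UserWarning, match="league"):
            draws = ham_model.fit_ham(one, spec)
        assert draws.n_draws == 500

    def test_scale_invariance_bootstrap(self, truth_scored):
        spec = ham_model.ModelSpec(
            granularity="team_aggregate",
            estimation=quick_estimation(seed=9, engine="bootstrap"),
        )
        base = ham_model.fit_ham(truth_scored, spec)
        scaled_data = truth_scored.copy()
        for col in ("score_performance", "score_referee", "score_outcome"):
            scaled_data[col] = 2.0 * scaled_data[col]
        scaled = ham_model.fit_ham(scaled_data, spec)
        # venue -> latent paths scale with the latents
        assert np.allclose(scaled.flat("a1"), 2.0 * base.flat("a1"))
        assert np.allclose(scaled.flat("c"), 2.0 * base.flat("c"))
        # latent -> latent paths are scale free
        assert np.allclose(scaled.flat("d"), base.flat("d"))
        assert np.allclose(scaled.flat("b1"), base.flat("b1"))

    def test_partial_pooling_shrinks_small_cells(self):
        frame = _synthetic_frame(n_teams=24, rows_per_team=12, seed=4)
        # one extra team with only 2 rows and an extreme performance level
        extra = frame.head(2).copy()
        extra["team_id"] = "zzz_small"
        extra["score_performance"] = extra["score_performance"] + 3.0
        data = pd.concat([frame, extra], ignore_index=True)
        spec = ham_model.ModelSpec(granularity="per_game",
                                   estimation=quick_estimation(seed=2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = ham_model.fit_ham(data, spec)
        eq = draws.equations["performance"]
        teams = pd.Categorical(data["team_id"]).categories
        idx = list(teams).index("zzz_small")
        u_hat = eq["u_team"].reshape(-1, len(teams))[:, idx].mean()
        # raw fixed-effects deviation of the small cell from the grand mean
        raw = (
            data.loc[data["team_id"] == "zzz_small", "score_performance"].mean()
            - data["score_performance"].mean()
        )
        assert 0 < u_hat < 0.8 * raw


class TestPrepareModelFrame:
    def test_aggregate_matches_groupby(self, truth_scored):
        frame = ham_model.prepare_model_frame(truth_scored, "team_aggregate")
        brute = (
            truth_scored.groupby(["team_id", "venue", "period"])[
                "score_performance"
            ].mean()
        )
        for _, row in frame.head(25).iterrows():
            assert row["score_performance"] == pytest.approx(
                brute[(row["team_id"], row["venue"], row["period"])], abs=1e-12
            )

    def test_per_game_row_count(self, truth_scored):
        frame = ham_model.prepare_model_frame(truth_scored, "per_game")
        assert len(frame) == len(truth_scored)

    def test_flags(self, truth_scored):
        frame = ham_model.prepare_model_frame(truth_scored, "team_aggregate")
        assert set(frame["venue_flag"].unique()) <= {0.0, 1.0}
        assert set(frame["nocrowd_flag"].unique()) <= {0.0, 1.0}


class TestBayesR2:
    def test_noiseless_outcome_r2_near_one(self):
        frame = _synthetic_frame(
            seed=1,
            outcome_fn=lambda f, r: 0.9 * f["score_performance"].to_numpy()
            + 1e-4 * r.standard_normal(len(f)),
        )
        spec = ham_model.ModelSpec(granularity="per_game",
                                   estimation=quick_estimation(seed=0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = ham_model.fit_ham(frame, spec)
        r2 = ham_model.bayes_r2(draws, "outcome")
        assert r2["median"].iloc[0] > 0.99

    def test_pure_noise_outcome_r2_near_zero(self):
        frame = _synthetic_frame(n_teams=25, rows_per_team=20, seed=2)
        spec = ham_model.ModelSpec(granularity="per_game",
                                   estimation=quick_estimation(seed=0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = ham_model.fit_ham(frame, spec)
        r2 = ham_model.bayes_r2(draws, "outcome")
        assert r2["median"].iloc[0] < 0.1

    def test_matches_brute_force(self, truth_draws):
        r2 = ham_model.bayes_r2(draws=truth_draws, equation="performance")
        eq = truth_draws.equations["performance"]
        chains, ndraw, p = eq["beta"].shape
        vals = []
        for c in range(chains):
            for k in range(ndraw):
                fitted = eq["X"] @ eq["beta"][c, k]
                if eq["u_team"] is not None:
                    fitted = fitted + eq["u_team"][c, k][eq["team_idx"]]
                if eq["u_league"] is not None:
                    fitted = fitted + eq["u_league"][c, k][eq["league_idx"]]
                v = fitted.var()
                vals.append(v / (v + eq["sigma2"][c, k]))
        assert r2["median"].iloc[0] == pytest.approx(np.median(vals), abs=1e-10)

    def test_zero_variance_outcome_raises(self):
        frame = _synthetic_frame(seed=3)
        frame["score_outcome"] = 1.0
        spec = ham_model.ModelSpec(
            granularity="per_game",
            estimation=quick_estimation(seed=0, engine="bootstrap"),
        )
        draws = ham_model.fit_ham(frame, spec)
        with pytest.raises(DegenerateDataError):
            ham_model.bayes_r2(draws, "outcome")


class TestPathDraws:
    def test_from_params_periods(self):
        draws = ham_model.PathDraws.from_params(
            {"a1_pre": 0.8, "a1_post": 0.3, "d_pre": -0.1}
        )
        assert draws.flat("a1_pre")[0] == pytest.approx(0.8)
        assert draws.flat("a1_post")[0] == pytest.approx(0.3)
        assert draws.flat("a1_delta")[0] == pytest.approx(-0.5)
        assert draws.flat("d_post")[0] == pytest.approx(-0.1)
        assert draws.flat("b2_pre")[0] == 0.0

    def test_mismatched_lengths_raise(self):
        with pytest.raises(IntegrityError):
            ham_model.PathDraws(
                {"a1": np.zeros((2, 10)), "a2": np.zeros((2, 11))}
            )

    def test_csv_round_trip(self, truth_draws, tmp_path):
        path = tmp_path / "draws.csv"
        truth_draws.to_csv(path)
        clone = ham_model.PathDraws.from_csv(path)
        assert np.allclose(clone.flat("a1_pre"), truth_draws.flat("a1_pre"))
        assert clone.params["a1"].shape == truth_draws.params["a1"].shape

    def test_unknown_name_raises(self, truth_draws):
        with pytest.raises(KeyError):
            truth_draws.flat("nonexistent_pre")


def test_recovery_study_smoke(fig_params):
    from hapath import synthetic_data

    cfg = synthetic_data.SimulationConfig(
        n_leagues=3, teams_per_league=8, rounds=10, post_share=0.3,
        seed=0, true_paths=fig_params,
    )
    spec = ham_model.ModelSpec(
        granularity="per_game",
        estimation=quick_estimation(seed=0, engine="bootstrap"),
    )
    table = ham_model.recovery_study(cfg, spec, n_replicates=2, seed=5)
    assert len(table) == 18  # 6 symbols x (pre, post, delta)
    assert set(table.columns) >= {"param", "truth", "coverage", "sign_rate"}
    assert table["coverage"].between(0, 1).all()
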