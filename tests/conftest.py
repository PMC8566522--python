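import numpy as np
import pytest

from hapath import ham_model, latent_factors, match_io, synthetic_data


def scenario_params() -> synthetic_data.StructuralParams:
    """Reference structural scenario: strong venue effects on performance and
    referee decisions that shrink or reverse without a crowd; mediator and
    direct paths held constant across periods."""
    return synthetic_data.StructuralParams(
        a1_pre=0.89, a1_post=0.35,
        a2_pre=-0.30, a2_post=0.19,
        d_pre=-0.14, d_post=-0.08,
        b1_pre=0.30, b1_post=0.30,
        b2_pre=-0.10, b2_post=-0.10,
        c_pre=0.28, c_post=0.28,
        gamma_rating=0.3, gamma_importance=0.1,
    )


def quick_estimation(seed: int = 0, engine: str = "mcmc") -> ham_model.EstimationSettings:
    if engine == "bootstrap":
        return ham_model.EstimationSettings(engine="bootstrap", bootstrap_reps=500,
                                            seed=seed)
    return ham_model.EstimationSettings(
        chains=2, draws_per_chain=300, warmup=250, seed=seed
    )


@pytest.fixture(scope="session")
def fig_params():
    return scenario_params()


@pytest.fixture(scope="session")
def small_sim(fig_params):
    """One small simulated season shared across tests (read-only)."""
    cfg = synthetic_data.SimulationConfig(
        n_leagues=4, teams_per_league=10, rounds=18, post_share=0.26,
        seed=7, true_paths=fig_params,
    )
    matches, latents = synthetic_data.simulate_matches(cfg, return_latents=True)
    pairs = match_io.to_game_pairs(matches)
    return {"config": cfg, "matches": matches, "latents": latents, "pairs": pairs}


@pytest.fixture(scope="session")
def scored_small(small_sim):
    scored, models = latent_factors.attach_scores(small_sim["pairs"])
    return {"scored": scored, "models": models}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
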