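# hapath

Moderated-mediation decomposition of the home advantage in paired match
data.

The package provides a fully testable pipeline around a hierarchical
conditional-process ("path") model of how the match venue influences the
outcome of a game:

```
venue ──► team performance ──► outcome
   │            │                ▲
   │            ▼                │
   └──────► referee decisions ───┘      (plus a direct venue ──► outcome path)
```

Every path is moderated by a crowd-absence flag (games with spectators
versus games behind closed doors), so each path has a *pre* (crowd) and a
*post* (no-crowd) coefficient and a delta.  The pipeline:

1. **`synthetic_data`** — simulates league seasons (round-robin schedules,
   paired home/away rows, count indicators, team/league heterogeneity) from
   known structural parameters, so every downstream stage is testable by
   parameter recovery.
2. **`match_io`** — canonical match CSV schema, game-pairs expansion (two
   rows per match, venue as a factor) and team × venue × period
   aggregation.
3. **`latent_factors`** — scores three latent constructs (outcome from
   points/goals; team performance from corners/shots/shots-on-target;
   referee decisions from fouls/yellows/reds) by single-factor analysis
   with regression-method factor scores.
4. **`ham_model`** — fits the three linked equations jointly with team and
   league random intercepts, crowd-moderation of every path and
   rating/importance controls.  Engines: an in-house partially collapsed
   Gibbs sampler (`mcmc`, with split-chain convergence diagnostics and
   Bayesian R²) or a cluster bootstrap (`bootstrap`).
5. **`effects`** — composes draws into direct, indirect (including the
   serial channel), and total effects per period, with paired pre/post
   deltas and interval-exclusion significance.
6. **`descriptives`** — per-game home/away means with standard errors,
   percent reductions and advantage-change statistics.
7. **`robustness`** — leave-one-league-out refits and the home-minus-away
   difference specification.
8. **`cli`** — the `hapath` command wiring everything together.

## CLI

All commands accept `--config` (one YAML/JSON document with `simulation`,
`model`, `estimation` and `report` sections; flags win over the file),
`--seed`, and `--out`; fitting commands also accept
`--engine {mcmc,bootstrap}` and `--granularity {team_aggregate,per_game}`.

```bash
hapath simulate --config config.yaml --seed 1 --out out/sim
hapath describe --input out/sim/matches.csv --out out/desc
hapath fit      --input out/sim/matches.csv --config config.yaml --out out/fit
hapath effects  --draws out/fit/draws.csv --out out/eff
hapath recover  --config config.yaml --replicates 20 --out out/rec
hapath lolo     --input out/sim/matches.csv --config config.yaml --out out/lolo
```

`simulate` writes the canonical match CSV; `fit` writes coefficient draws,
convergence diagnostics and per-equation Bayesian R²; `effects` writes the
effect report as CSV/JSON plus a formatted text table; `recover` writes a
parameter-recovery coverage table; `lolo` writes one effect report per
excluded league and a stability summary.  Every run logs its config hash
and seed to stderr and records them in `meta.json`.

Minimal config example:

```yaml
simulation:
  n_leagues: 12
  teams_per_league: 18
  rounds: 20
  post_share: 0.26
  seed: 1
  true_paths: {a1_pre: 0.89, a1_post: 0.35, a2_pre: -0.30, a2_post: 0.19,
               d_pre: -0.14, d_post: -0.08, b1_pre: 0.3, b2_pre: -0.1,
               b1_post: 0.3, b2_post: -0.1, c_pre: 0.28, c_post: 0.28}
estimation:
  chains: 4
  draws_per_chain: 500
  warmup: 500
  seed: 1
model:
  granularity: team_aggregate
```

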