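"""Hierarchical moderated path model on latent construct scores.

Three linked linear equations are fitted jointly:

* performance  = f(venue, controls)
* referee      = f(venue, performance, controls)
* outcome      = f(venue, performance, referee, controls)

Every predictor is allowed to interact with the crowd-absence flag, so each
path has a base (crowd period) coefficient and a delta; the no-crowd
coefficient is base + delta.  Team and league random intercepts give partial
pooling.  The recursive structure (no feedback paths) means the joint
posterior factorizes over equations, so equations are sampled independently
with a conjugate Gibbs sampler and their draws stored jointly by index.

Priors: zero-mean normal with scale ``prior_scale`` on coefficients,
half-normal on random-intercept SDs (slice-sampled from their
block-marginalized conditionals), and a weak inverse-gamma on residual
variances.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
import scipy.linalg as sla

from hapath import latent_factors, match_io
from hapath.errors import ConfigurationError, DegenerateDataError, IntegrityError

EQUATIONS = ("performance", "referee", "outcome")

#: Structural path symbols (base coefficients; ``<s>_delta`` are the
#: crowd-absence interactions).
PATH_SYMBOLS = ("a1", "a2", "d", "b1", "b2", "c")

GRANULARITIES = ("team_aggregate", "per_game")
ENGINES = ("mcmc", "bootstrap")


@dataclass
class EstimationSettings:
    """How the path model is estimated."""

    engine: str = "mcmc"
    chains: int = 4
    draws_per_chain: int = 500
    warmup: int = 500
    bootstrap_reps: int = 1000
    seed: int = 0
    prior_scale: float = 2.5
    interval_level: float = 0.95
    tau_scale: float = 1.0
    rhat_threshold: float = 1.01

    def __post_init__(self):
        if self.engine not in ENGINES:
            raise ConfigurationError(f"engine must be one of {ENGINES}")
        total = (
            self.chains * self.draws_per_chain
            if self.engine == "mcmc"
            else self.bootstrap_reps
        )
        if total < 500:
            raise ConfigurationError("need at least 500 total draws for reporting")
        if not 0.5 < self.interval_level < 1.0:
            raise ConfigurationError("interval_level must lie in (0.5, 1)")
        if self.prior_scale <= 0:
            raise ConfigurationError("prior_scale must be > 0")


@dataclass
class ModelSpec:
    """Structural specification of the three-equation model.

    The equation structure itself is fixed (acyclic by construction: the
    performance equation excludes both mediators, the referee equation
    excludes the outcome score); the spec selects granularity, controls and
    random terms.
    """

    granularity: str = "team_aggregate"
    controls: bool = True
    random_terms: tuple[str, ...] = ("team", "league")
    estimation: EstimationSettings = field(default_factory=EstimationSettings)

    def __post_init__(self):
        if self.granularity not in GRANULARITIES:
            raise ConfigurationError(f"granularity must be one of {GRANULARITIES}")
        bad = set(self.random_terms) - {"team", "league"}
        if bad:
            raise ConfigurationError(f"unknown random terms: {sorted(bad)}")


class PathDraws:
    """Joint draws of all structural coefficients.

    Parameters are stored as ``(chains, draws)`` arrays under their base
    names (``a1``, ``a1_delta``, ...); per-period values are materialized on
    access (pre = base, post = base + delta).
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        diagnostics: pd.DataFrame | None = None,
        converged: bool = True,
        interval_level: float = 0.95,
        equations: dict | None = None,
        meta: dict | None = None,
    ):
        lengths = {v.shape for v in params.values()}
        if len(lengths) != 1:
            raise IntegrityError("parameter draw arrays have mismatched shapes")
        self.params = {k: np.atleast_2d(np.asarray(v, float)) for k, v in params.items()}
        self.diagnostics = diagnostics
        self.converged = converged
        self.interval_level = interval_level
        self.equations = equations
        self.meta = meta or {}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_draws(self) -> int:
        first = next(iter(self.params.values()))
        return first.shape[0] * first.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Flattened draws for a stored or per-period parameter name."""
        if name in self.params:
            return self.params[name].reshape(-1)
        if name.endswith("_pre"):
            return self.flat(name[: -len("_pre")])
        if name.endswith("_post"):
            base = name[: -len("_post")]
            return self.flat(base) + self.flat(base + "_delta")
        raise KeyError(name)

    def period_value(self, symbol: str, period: str) -> np.ndarray:
        return self.flat(f"{symbol}_{period}")

    def summary(self, level: float | None = None) -> pd.DataFrame:
        """Median and central interval for every stored and per-period
        parameter."""
        level = self.interval_level if level is None else level
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        names = list(self.params)
        for s in PATH_SYMBOLS:
            if s in self.params:
                names += [f"{s}_pre", f"{s}_post"]
        rows = []
        for name in names:
            x = self.flat(name)
            rows.append(
                {
                    "param": name,
                    "median": float(np.median(x)),
                    "lower": float(np.quantile(x, lo_q)),
                    "upper": float(np.quantile(x, hi_q)),
                }
            )
        return pd.DataFrame(rows)

    # -- construction helpers ---------------------------------------------
    @classmethod
    def from_params(cls, values) -> "PathDraws":
        """Single-draw PathDraws from point values.

        ``values`` may be a mapping with per-period keys (``a1_pre``,
        ``a1_post``, ...) or a
        :class:`hapath.synthetic_data.StructuralParams`.  A missing pre value
        defaults to 0; a missing post value defaults to the pre value
        (unmoderated path).
        """
        if dataclasses.is_dataclass(values):
            values = dataclasses.asdict(values)
        params = {}
        for s in PATH_SYMBOLS:
            pre = float(values.get(f"{s}_pre", 0.0))
            post = float(values.get(f"{s}_post", pre))
            params[s] = np.array([[pre]])
            params[f"{s}_delta"] = np.array([[post - pre]])
        return cls(params, converged=True)

    def to_frame(self) -> pd.DataFrame:
        """Flat draws as columns, with chain/draw index columns."""
        first = next(iter(self.params.values()))
        chains, draws = first.shape
        out = {
            "chain": np.repeat(np.arange(chains), draws),
            "draw": np.tile(np.arange(draws), chains),
        }
        for k, v in self.params.items():
            out[k] = v.reshape(-1)
        return pd.DataFrame(out)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, interval_level: float = 0.95) -> "PathDraws":
        df = pd.read_csv(path)
        chains = df["chain"].nunique()
        params = {}
        for col in df.columns:
            if col in ("chain", "draw"):
                continue
            params[col] = df[col].to_numpy().reshape(chains, -1)
        return cls(params, interval_level=interval_level)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def prepare_model_frame(scored_pairs: pd.DataFrame, granularity: str) -> pd.DataFrame:
    """Model frame from a scored game-pairs table.

    Output columns: ``team_id, league_id, venue_flag, nocrowd_flag, rating_z,
    importance_z`` and the three ``score_*`` columns.  For the
    ``team_aggregate`` granularity, scores and covariates are unweighted
    means per team x venue x period cell.
    """
    needed = [f"score_{c}" for c in EQUATIONS]
    missing = [c for c in needed if c not in scored_pairs.columns]
    if missing:
        raise ValueError(f"scored pairs are missing columns: {missing}")
    if granularity == "team_aggregate":
        keys = ["team_id", "league_id", "venue", "period"]
        cols = needed + ["rating", "importance"]
        frame = (
            scored_pairs.groupby(keys, sort=True, observed=True)[cols]
            .mean()
            .reset_index()
        )
    elif granularity == "per_game":
        frame = scored_pairs.loc[
            :,
            ["team_id", "league_id", "venue", "period", "rating", "importance"]
            + needed,
        ].copy()
    else:
        raise ConfigurationError(f"granularity must be one of {GRANULARITIES}")
    frame["venue_flag"] = (frame["venue"] == "home").astype(float)
    frame["nocrowd_flag"] = (frame["period"] == "no_crowd").astype(float)
    for cov in ("rating", "importance"):
        x = frame[cov].to_numpy(dtype=float)
        sd = x.std()
        frame[f"{cov}_z"] = 0.0 if sd == 0 else (x - x.mean()) / sd
    return frame


def _equation_design(frame: pd.DataFrame, equation: str, controls: bool):
    """Design matrix, column names and response for one equation."""
    v = frame["venue_flag"].to_numpy()
    c = frame["nocrowd_flag"].to_numpy()
    tp = frame["score_performance"].to_numpy()
    rd = frame["score_referee"].to_numpy()
    one = np.ones(len(frame))

    cols: list[tuple[str, np.ndarray]] = [
        (f"intercept_{equation}", one),
        (f"intercept_{equation}_delta", c),
    ]
    if equation == "performance":
        y = tp
        cols += [("a1", v), ("a1_delta", v * c)]
    elif equation == "referee":
        y = rd
        cols += [("a2", v), ("a2_delta", v * c), ("d", tp), ("d_delta", tp * c)]
    elif equation == "outcome":
        y = frame["score_outcome"].to_numpy()
        cols += [
            ("c", v),
            ("c_delta", v * c),
            ("b1", tp),
            ("b1_delta", tp * c),
            ("b2", rd),
            ("b2_delta", rd * c),
        ]
    else:  # pragma: no cover
        raise ValueError(equation)
    if controls:
        for cov in ("rating", "importance"):
            x = frame[f"{cov}_z"].to_numpy()
            cols += [
                (f"gamma_{cov}_{equation}", x),
                (f"gamma_{cov}_{equation}_delta", x * c),
            ]
    names = [n for n, _ in cols]
    X = np.column_stack([x for _, x in cols])
    return X, names, np.asarray(y, dtype=float)


# ---------------------------------------------------------------------------
# Gibbs sampler for one normal linear mixed equation
# ---------------------------------------------------------------------------

def _slice_sample(logpdf, x0, rng, width=0.7, max_expand=30):
    """One univariate slice-sampling update (stepping-out procedure)."""
    height = logpdf(x0) - rng.exponential()
    lo = x0 - width * rng.uniform()
    hi = lo + width
    for _ in range(max_expand):
        if logpdf(lo) <= height:
            break
        lo -= width
    for _ in range(max_expand):
        if logpdf(hi) <= height:
            break
        hi += width
    while True:
        x1 = rng.uniform(lo, hi)
        if logpdf(x1) >= height:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def _sample_equation_mcmc(y, X, team_idx, league_idx, settings, seed_seq):
    """Partially collapsed Gibbs sampler for one normal linear mixed
    equation.

    Coefficients are drawn with the random intercepts integrated out (GLS
    posterior via a Woodbury factorization of the q x q random-effect
    system); each random-intercept SD is drawn from its conditional with its
    own block marginalized, by slice sampling under a half-normal prior; the
    intercepts themselves are then refreshed jointly.  This removes the
    coefficient/random-effect and SD/block couplings that make the naive
    sweep mix slowly.
    """
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y

    blocks = []  # (idx, counts, offset)
    offset = 0
    for idx in (team_idx, league_idx):
        if idx is None:
            blocks.append(None)
        else:
            counts = np.bincount(idx)
            blocks.append((np.asarray(idx, dtype=np.int64), counts, offset))
            offset += len(counts)
    q = offset

    if q:
        ZtZ = np.zeros((q, q))
        ZtX = np.zeros((q, p))
        Zty = np.zeros(q)
        block_cols = []
        for b in blocks:
            if b is None:
                block_cols.append(None)
                continue
            idx, counts, off = b
            c = off + idx
            block_cols.append(c)
            ZtX += np.stack(
                [np.bincount(c, weights=X[:, j], minlength=q) for j in range(p)],
                axis=1,
            )
            Zty += np.bincount(c, weights=y, minlength=q)
        for b in blocks:
            if b is None:
                continue
            _, counts, off = b
            ZtZ[np.arange(off, off + len(counts)),
                np.arange(off, off + len(counts))] += counts
        if all(b is not None for b in blocks):
            # cross term between the two blocks
            np.add.at(ZtZ, (block_cols[0], block_cols[1]), 1.0)
            ZtZ[np.ix_(range(blocks[1][2], q), range(0, blocks[1][2]))] = ZtZ[
                np.ix_(range(0, blocks[1][2]), range(blocks[1][2], q))
            ].T

    prior_prec = np.eye(p) / settings.prior_scale**2

    chains_beta, chains_sigma2, chains_tau, chains_u = [], [], [], []
    for chain_seed in seed_seq.spawn(settings.chains):
        rng = np.random.default_rng(chain_seed)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid0 = y - X @ beta
        sigma2 = max(float(resid0 @ resid0) / max(n - p, 1), 1e-6)
        tau = [0.3 if b is not None else 0.0 for b in blocks]
        u = [np.zeros(len(b[1])) if b is not None else None for b in blocks]

        keep_beta = np.empty((settings.draws_per_chain, p))
        keep_sigma2 = np.empty(settings.draws_per_chain)
        keep_tau = np.empty((settings.draws_per_chain, 2))
        keep_u = [
            np.empty((settings.draws_per_chain, len(b[1]))) if b is not None else None
            for b in blocks
        ]

        for it in range(settings.warmup + settings.draws_per_chain):
            fx = X @ beta

            # random-intercept SDs: own block marginalized, then the block
            # refreshed from its conditional
            for bi, b in enumerate(blocks):
                if b is None:
                    continue
                idx, counts, _ = b
                other = np.zeros(n)
                for bj, b2 in enumerate(blocks):
                    if b2 is not None and bj != bi:
                        other += u[bj][b2[0]]
                r = y - fx - other
                s_j = np.bincount(idx, weights=r, minlength=len(counts))

                def log_marginal(log_t):
                    t2 = np.exp(2.0 * log_t)
                    denom = sigma2 + counts * t2
                    ll = -0.5 * np.sum(np.log(denom)) + 0.5 * t2 * np.sum(
                        s_j**2 / (sigma2 * denom)
                    )
                    prior = -0.5 * t2 / settings.tau_scale**2 + log_t
                    return ll + prior

                log_t = _slice_sample(log_marginal, np.log(max(tau[bi], 1e-4)), rng)
                tau[bi] = float(np.exp(log_t))

                var = 1.0 / (counts / sigma2 + 1.0 / max(tau[bi] ** 2, 1e-12))
                u[bi] = var * s_j / sigma2 + np.sqrt(var) * rng.standard_normal(
                    len(counts)
                )

            # coefficients with all random intercepts integrated out
            if q:
                dinv = np.concatenate(
                    [
                        np.full(len(b[1]), 1.0 / max(t**2, 1e-12))
                        for b, t in zip(blocks, tau)
                        if b is not None
                    ]
                )
                M = ZtZ + sigma2 * np.diag(dinv)
                cho = sla.cho_factor(M, lower=True)
                Lm = cho[0]
                MinvA = sla.cho_solve(cho, ZtX)
                Minvb = sla.cho_solve(cho, Zty)
                XtVinvX = (XtX - ZtX.T @ MinvA) / sigma2
                XtVinvy = (Xty - ZtX.T @ Minvb) / sigma2
            else:
                XtVinvX = XtX / sigma2
                XtVinvy = Xty / sigma2
            prec = XtVinvX + prior_prec
            Lp = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, XtVinvy)
            beta = mean + np.linalg.solve(Lp.T, rng.standard_normal(p))
            fx = X @ beta

            # joint refresh of all random intercepts given the new beta
            if q:
                Ztr = Zty - ZtX @ beta
                u_mean = sla.cho_solve(cho, Ztr)
                u_all = u_mean + np.sqrt(sigma2) * sla.solve_triangular(
                    Lm, rng.standard_normal(q), lower=True, trans="T"
                )
                for bi, b in enumerate(blocks):
                    if b is not None:
                        _, counts, off = b
                        u[bi] = u_all[off: off + len(counts)]

            # residual variance
            re_total = np.zeros(n)
            for b, uj in zip(blocks, u):
                if b is not None:
                    re_total += uj[b[0]]
            resid = y - fx - re_total
            shape = 1e-3 + 0.5 * n
            rate = 1e-3 + 0.5 * float(resid @ resid)
            sigma2 = rate / rng.gamma(shape)

            k = it - settings.warmup
            if k >= 0:
                keep_beta[k] = beta
                keep_sigma2[k] = sigma2
                keep_tau[k] = tau
                for bi, b in enumerate(blocks):
                    if b is not None:
                        keep_u[bi][k] = u[bi]

        chains_beta.append(keep_beta)
        chains_sigma2.append(keep_sigma2)
        chains_tau.append(keep_tau)
        chains_u.append(keep_u)

    return {
        "beta": np.stack(chains_beta),          # (chains, draws, p)
        "sigma2": np.stack(chains_sigma2),      # (chains, draws)
        "tau": np.stack(chains_tau),            # (chains, draws, 2)
        "u_team": (
            np.stack([cu[0] for cu in chains_u]) if blocks[0] is not None else None
        ),
        "u_league": (
            np.stack([cu[1] for cu in chains_u]) if blocks[1] is not None else None
        ),
    }


def _sample_equation_bootstrap(y, X, team_idx, settings, seed_seq):
    """Cluster bootstrap over teams with an OLS refit per replicate.

    A frequentist analogue of the Bayesian engine: no partial pooling, draws
    are resampled point estimates.
    """
    rng = np.random.default_rng(seed_seq)
    n, p = X.shape
    teams = np.unique(team_idx) if team_idx is not None else None
    keep_beta = np.empty((1, settings.bootstrap_reps, p))
    keep_sigma2 = np.empty((1, settings.bootstrap_reps))
    for b in range(settings.bootstrap_reps):
        if teams is None:
            take = rng.integers(0, n, size=n)
        else:
            chosen = rng.choice(teams, size=len(teams), replace=True)
            take = np.concatenate([np.flatnonzero(team_idx == t) for t in chosen])
        Xb, yb = X[take], y[take]
        beta = np.linalg.lstsq(Xb, yb, rcond=None)[0]
        resid = yb - Xb @ beta
        keep_beta[0, b] = beta
        keep_sigma2[0, b] = float(resid @ resid) / max(len(yb) - p, 1)
    return {
        "beta": keep_beta,
        "sigma2": keep_sigma2,
        "tau": np.zeros((1, settings.bootstrap_reps, 2)),
        "u_team": None,
        "u_league": None,
    }


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def fit_ham(data: pd.DataFrame, spec: ModelSpec) -> PathDraws:
    """Fit the three-equation moderated path model.

    Parameters
    ----------
    data
        A scored game-pairs table (``score_*`` columns present) or an
        already-prepared model frame (``venue_flag`` column present).
    spec
        Model specification, including estimation settings.

    Returns
    -------
    PathDraws
        Joint draws of every structural coefficient, control coefficient,
        random-intercept SD and residual SD, with split-chain convergence
        diagnostics.  A non-converged fit is flagged (``converged=False``)
        and warned about, never silently passed.
    """
    settings = spec.estimation
    if "venue_flag" in data.columns:
        frame = data
    else:
        frame = prepare_model_frame(data, spec.granularity)

    team_codes = pd.Categorical(frame["team_id"]).codes
    league_codes = pd.Categorical(frame["league_id"]).codes
    team_idx = team_codes if "team" in spec.random_terms else None
    league_idx = league_codes if "league" in spec.random_terms else None
    if league_idx is not None and len(np.unique(league_codes)) < 2:
        warnings.warn("single league in data: dropping league random term")
        league_idx = None
    if team_idx is not None and len(np.unique(team_codes)) < 2:
        warnings.warn("single team in data: dropping team random term")
        team_idx = None

    seed_root = np.random.SeedSequence(settings.seed)
    eq_seeds = seed_root.spawn(len(EQUATIONS))

    params: dict[str, np.ndarray] = {}
    equations: dict[str, dict] = {}
    for equation, eq_seed in zip(EQUATIONS, eq_seeds):
        X, names, y = _equation_design(frame, equation, spec.controls)
        if settings.engine == "mcmc":
            fit = _sample_equation_mcmc(y, X, team_idx, league_idx, settings, eq_seed)
        else:
            fit = _sample_equation_bootstrap(y, X, team_idx, settings, eq_seed)
        for j, name in enumerate(names):
            params[name] = fit["beta"][:, :, j]
        params[f"sigma_{equation}"] = np.sqrt(fit["sigma2"])
        params[f"tau_team_{equation}"] = fit["tau"][:, :, 0]
        params[f"tau_league_{equation}"] = fit["tau"][:, :, 1]
        equations[equation] = {
            "X": X,
            "names": names,
            "y": y,
            "team_idx": team_idx,
            "league_idx": league_idx,
            "beta": fit["beta"],
            "sigma2": fit["sigma2"],
            "u_team": fit["u_team"],
            "u_league": fit["u_league"],
        }

    diagnostics = None
    converged = True
    if settings.engine == "mcmc" and settings.chains >= 2:
        idata = az.from_dict({k: v for k, v in params.items()})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        diagnostics = pd.DataFrame(
            {
                "param": list(params),
                "rhat": [float(rhat[k].values) for k in params],
                "ess": [float(ess[k].values) for k in params],
            }
        )
        worst = diagnostics["rhat"].max()
        if worst > settings.rhat_threshold:
            converged = False
            warnings.warn(
                f"fit did not converge: max split-chain rhat {worst:.4f} "
                f"> {settings.rhat_threshold}"
            )

    return PathDraws(
        params,
        diagnostics=diagnostics,
        converged=converged,
        interval_level=settings.interval_level,
        equations=equations,
        meta={
            "engine": settings.engine,
            "seed": settings.seed,
            "granularity": spec.granularity,
            "n_rows": len(frame),
        },
    )


def bayes_r2(draws: PathDraws, equation: str | None = None) -> pd.DataFrame:
    """Per-equation Bayesian R² including random effects.

    Per draw: ``var(fitted) / (var(fitted) + sigma²)`` where the fitted
    values include the random intercepts; summarized by the median and the
    draws' central interval.
    """
    if draws.equations is None:
        raise ValueError("draws carry no fitted equations (loaded from CSV?)")
    eqs = [equation] if equation else list(draws.equations)
    lo_q = (1 - draws.interval_level) / 2
    rows = []
    for eq in eqs:
        info = draws.equations[eq]
        y = info["y"]
        if np.var(y) == 0:
            raise DegenerateDataError(f"{eq}: response has zero variance")
        chains, ndraw, p = info["beta"].shape
        beta = info["beta"].reshape(-1, p)
        fitted = beta @ info["X"].T  # (D, n)
        for key, idx_key in (("u_team", "team_idx"), ("u_league", "league_idx")):
            if info[key] is not None and info[idx_key] is not None:
                u = info[key].reshape(chains * ndraw, -1)
                fitted = fitted + u[:, info[idx_key]]
        var_fit = fitted.var(axis=1)
        sigma2 = info["sigma2"].reshape(-1)
        r2 = var_fit / (var_fit + sigma2)
        rows.append(
            {
                "equation": eq,
                "median": float(np.median(r2)),
                "lower": float(np.quantile(r2, lo_q)),
                "upper": float(np.quantile(r2, 1 - lo_q)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter-recovery harness
# ---------------------------------------------------------------------------

def attach_true_latents(pairs: pd.DataFrame, latents: pd.DataFrame) -> pd.DataFrame:
    """Merge simulator ground-truth latents onto a game-pairs table as the
    ``score_*`` columns (bypassing the factor-analysis stage)."""
    merged = pairs.merge(
        latents.rename(
            columns={
                "latent_performance": "score_performance",
                "latent_referee": "score_referee",
                "latent_outcome": "score_outcome",
            }
        ).drop(columns=["team_id"]),
        on=["match_id", "venue"],
        validate="one_to_one",
    )
    if len(merged) != len(pairs):
        raise IntegrityError("latent frame does not cover all pair rows")
    return merged


def recovery_study(
    sim_config,
    spec: ModelSpec,
    n_replicates: int = 20,
    seed: int = 0,
    use_true_latents: bool = True,
) -> pd.DataFrame:
    """Seeded parameter-recovery study.

    Simulates ``n_replicates`` data sets from ``sim_config``, refits the
    path model on each and reports, per structural parameter: the truth, the
    fraction of replicates whose credible interval covers it, and — for the
    pre/post deltas — the fraction of replicates whose posterior median has
    the true sign.

    ``use_true_latents`` scores rows with the generating latents themselves
    so the harness isolates the estimation stage; set it to False to run the
    factor-analysis scoring in the loop as well (path scales are then only
    recovered up to factor-score standardization).
    """
    from hapath import synthetic_data  # local import: avoids a cycle

    truth = {}
    for s in PATH_SYMBOLS:
        pre, post = sim_config.true_paths.per_period(s)
        truth[f"{s}_pre"] = pre
        truth[f"{s}_post"] = post
        truth[f"{s}_delta"] = post - pre

    records = {k: [] for k in truth}
    for rep in range(n_replicates):
        cfg = dataclasses.replace(sim_config, seed=seed + 1000 * rep)
        matches, latents = synthetic_data.simulate_matches(cfg, return_latents=True)
        pairs = match_io.to_game_pairs(matches)
        if use_true_latents:
            scored = attach_true_latents(pairs, latents)
        else:
            scored, _ = latent_factors.attach_scores(pairs)
        est = dataclasses.replace(spec.estimation, seed=seed + 1000 * rep + 7)
        rep_spec = dataclasses.replace(spec, estimation=est)
        draws = fit_ham(scored, rep_spec)
        summ = draws.summary().set_index("param")
        for name in truth:
            row = summ.loc[name]
            records[name].append(
                (
                    float(row["median"]),
                    bool(row["lower"] <= truth[name] <= row["upper"]),
                )
            )

    rows = []
    for name, recs in records.items():
        medians = np.array([m for m, _ in recs])
        covered = np.array([c for _, c in recs])
        t = truth[name]
        sign_rate = (
            float(np.mean(np.sign(medians) == np.sign(t))) if t != 0 else np.nan
        )
        rows.append(
            {
                "param": name,
                "truth": t,
                "coverage": float(covered.mean()),
                "mean_median": float(medians.mean()),
                "sign_rate": sign_rate,
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)
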