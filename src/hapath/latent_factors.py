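"""Single-factor models and regression-method factor scores.

Each latent construct is scored from its indicators with a one-factor model
fitted on z-scored data: maximum likelihood for three or more indicators,
the first principal component for the two-indicator outcome construct (an ML
one-factor model is not identified with two indicators).  Scores use the
regression (Thomson) method and are standardized to mean 0, SD 1 on the
training rows; the stored standardization is reused when scoring new rows.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from hapath.errors import DegenerateDataError

#: Default indicator sets for the three constructs, oriented so that larger
#: values mean more of the construct.
DEFAULT_CONSTRUCTS = {
    "outcome": ("points", "goals_for"),
    "performance": ("corners", "shots", "shots_on_target"),
    "referee": ("fouls", "yellows", "reds"),
}

SCORE_COLUMNS = {k: f"score_{k}" for k in DEFAULT_CONSTRUCTS}


@dataclass
class FactorModel:
    """Fitted one-factor model for a single construct."""

    construct: str
    indicators: tuple[str, ...]
    loadings: np.ndarray
    uniquenesses: np.ndarray
    variance_explained: float
    score_weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    score_shift: float  # raw-score mean on training rows
    score_scale: float  # raw-score SD on training rows

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        d["indicators"] = list(self.indicators)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FactorModel":
        d = json.loads(text)
        for k in ("loadings", "uniquenesses", "score_weights", "means", "sds"):
            d[k] = np.asarray(d[k], dtype=float)
        d["indicators"] = tuple(d["indicators"])
        return cls(**d)


def _ml_one_factor(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood one-factor decomposition of a correlation matrix.

    Profiles the loadings out: for fixed uniquenesses ``psi`` the optimal
    loading vector comes from the leading eigenpair of
    ``diag(psi)^-1/2 R diag(psi)^-1/2``; the discrepancy then depends on the
    remaining eigenvalues only.  Optimized over log-uniquenesses.
    """
    p = corr.shape[0]

    def loadings_for(psi):
        d = 1.0 / np.sqrt(psi)
        rstar = corr * np.outer(d, d)
        vals, vecs = np.linalg.eigh(rstar)
        theta, v = vals[-1], vecs[:, -1]
        lam = np.sqrt(psi) * v * np.sqrt(max(theta - 1.0, 0.0))
        return lam, vals

    def objective(log_psi):
        psi = np.exp(log_psi)
        _, vals = loadings_for(psi)
        rest = vals[:-1]
        rest = np.clip(rest, 1e-10, None)
        return float(np.sum(rest - np.log(rest) - 1.0))

    x0 = np.log(np.clip(1.0 - np.abs(corr - np.eye(p)).max(axis=1), 0.05, 0.95))
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[(np.log(5e-3), np.log(1.0))] * p,
    )
    psi = np.exp(res.x)
    lam, _ = loadings_for(psi)
    lam = np.clip(lam, -1.0, 1.0)
    return lam, psi


def fit_single_factor(
    rows: pd.DataFrame, indicators: tuple[str, ...], construct: str = ""
) -> FactorModel:
    """Fit a one-factor model on z-scored indicators.

    The sign is oriented so the mean loading is positive, and
    ``variance_explained`` is the mean squared loading (communal share of
    standardized-indicator variance).

    Raises
    ------
    ValueError
        If fewer than two indicators are requested.
    DegenerateDataError
        If any indicator is constant or fewer than three complete rows are
        available.
    """
    indicators = tuple(indicators)
    if len(indicators) < 2:
        raise ValueError("at least two indicators are required")
    missing = [c for c in indicators if c not in rows.columns]
    if missing:
        raise ValueError(f"rows are missing indicator columns: {missing}")
    x = rows.loc[:, list(indicators)].dropna().to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise DegenerateDataError("need at least 3 complete rows")
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    if (sds == 0).any():
        bad = [indicators[i] for i in np.flatnonzero(sds == 0)]
        raise DegenerateDataError(f"constant indicator(s): {bad}")
    z = (x - means) / sds
    corr = np.corrcoef(z, rowvar=False)

    if len(indicators) == 2:
        r = corr[0, 1]
        # first principal component of the z-scored pair: equal |weights|
        lam_val = np.sqrt((1.0 + abs(r)) / 2.0)
        loadings = np.array([lam_val, np.sign(r) * lam_val if r != 0 else lam_val])
        uniq = 1.0 - loadings**2
    else:
        loadings, uniq = _ml_one_factor(corr)

    if loadings.mean() < 0:
        loadings = -loadings
    variance_explained = float(np.mean(loadings**2))

    # Thomson regression weights on z-scores (pinv: the correlation matrix
    # is singular for perfectly collinear indicators)
    weights = np.linalg.pinv(corr) @ loadings
    raw = z @ weights
    shift = float(raw.mean())
    scale = float(raw.std())
    if scale == 0:
        raise DegenerateDataError("factor scores are constant")
    return FactorModel(
        construct=construct,
        indicators=indicators,
        loadings=loadings,
        uniquenesses=uniq,
        variance_explained=variance_explained,
        score_weights=weights,
        means=means,
        sds=sds,
        score_shift=shift,
        score_scale=scale,
    )


def score(model: FactorModel, rows: pd.DataFrame) -> pd.Series:
    """Score rows with a fitted factor model.

    Training rows score to mean 0, SD 1; new rows reuse the stored indicator
    standardization and score scaling.

    Raises
    ------
    ValueError
        If an indicator column is missing.
    """
    missing = [c for c in model.indicators if c not in rows.columns]
    if missing:
        raise ValueError(f"rows are missing indicator columns: {missing}")
    x = rows.loc[:, list(model.indicators)].to_numpy(dtype=float)
    z = (x - model.means) / model.sds
    raw = z @ model.score_weights
    return pd.Series((raw - model.score_shift) / model.score_scale,
                     index=rows.index, name=f"score_{model.construct}")


def fit_constructs(
    pairs: pd.DataFrame, constructs: dict[str, tuple[str, ...]] | None = None
) -> dict[str, FactorModel]:
    """Fit one factor model per construct on pooled game-pairs rows."""
    constructs = constructs or DEFAULT_CONSTRUCTS
    return {
        name: fit_single_factor(pairs, inds, construct=name)
        for name, inds in constructs.items()
    }


def attach_scores(
    pairs: pd.DataFrame, models: dict[str, FactorModel] | None = None
) -> tuple[pd.DataFrame, dict[str, FactorModel]]:
    """Return a copy of ``pairs`` with ``score_<construct>`` columns added.

    Models are fitted on the pooled rows when not supplied.
    """
    if models is None:
        models = fit_constructs(pairs)
    scored = pairs.copy()
    for name, model in models.items():
        scored[f"score_{name}"] = score(model, pairs)
    return scored, models
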