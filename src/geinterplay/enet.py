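"""Elastic-net prediction models with repeated cross-validation.

The solver minimizes, by cyclic coordinate descent on precomputed Gram moments,

    (1/2n) ||y - X b||^2 + lam * (alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2),

the sample-size-stable 1/(2n) parameterization of the usual L1+L2 penalized
residual sum of squares (alpha = 1 is the lasso, alpha = 0 the ridge limit).
Tuning selects the (alpha, lam) grid point minimizing root-mean-square error
over k-fold cross-validation repeated many times in the training set; model
performance is reported as hold-out R^2 = 1 - SSE/SST.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._kernels import enet_cd, enet_path_cd
from .errors import ConfigError

_ALPHA_FLOOR = 1e-3  # lambda_max is undefined at alpha = 0; standard floor


@dataclass
class ElasticNetConfig:
    """Tuning grids and cross-validation layout."""

    alpha_grid: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))
    lambda_grid: Sequence[float] | None = None  # None -> automatic path
    n_lambda: int = 100
    lambda_min_ratio: float = 0.001
    k_folds: int = 10
    repeats: int = 100
    seed: int = 0
    tol: float = 1e-8
    max_sweeps: int = 10_000

    def __post_init__(self) -> None:
        if len(self.alpha_grid) == 0:
            raise ConfigError("alpha grid must be non-empty")
        if any(not 0.0 <= a <= 1.0 for a in self.alpha_grid):
            raise ConfigError("alpha values must lie in [0, 1]")
        if self.lambda_grid is not None and len(self.lambda_grid) == 0:
            raise ConfigError("lambda grid must be non-empty")
        if self.k_folds < 2:
            raise ConfigError("k_folds must be at least 2")
        if self.repeats < 1:
            raise ConfigError("repeats must be at least 1")


@dataclass
class EvaluationResult:
    """Hold-out evaluation: R^2 = 1 - SSE/SST, SST around the hold-out mean."""

    r2: float
    sse: float
    sst: float
    n_holdout: int


@dataclass
class ModelFit:
    """A tuned elastic-net fit with its cross-validation trace.

    Coefficients are on the standardized-predictor scale; ``predict`` applies
    the stored training standardization to new raw panel columns.
    """

    name: str
    alpha: float
    lam: float
    beta: pd.Series
    intercept: float
    x_mean: np.ndarray = field(repr=False)
    x_sd: np.ndarray = field(repr=False)
    cv_trace: pd.DataFrame = field(repr=False)
    holdout: EvaluationResult | None = None

    @property
    def active_set(self) -> list[str]:
        return [c for c, b in self.beta.items() if b != 0.0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd
        return self.intercept + Xs @ self.beta.to_numpy()

    def to_dict(self) -> dict:
        d = {
            "name": self.name, "alpha": self.alpha, "lam": self.lam,
            "intercept": self.intercept,
            "beta": self.beta.to_dict(),
            "active_set": self.active_set,
        }
        if self.holdout is not None:
            d["holdout"] = vars(self.holdout)
        return d


def enet_fit(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Solve one elastic-net problem; expects standardized X and centered y."""
    if not 0.0 <= alpha <= 1.0:
        raise ConfigError(f"alpha must lie in [0, 1], got {alpha}")
    if lam < 0:
        raise ConfigError("lam must be non-negative")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    enet_cd(X.T @ X, X.T @ y, float(len(y)), float(alpha), float(lam), beta,
            tol, max_sweeps)
    return beta


def enet_objective(X, y, beta, alpha, lam) -> float:
    n = len(y)
    r = y - X @ beta
    return float(
        (r @ r) / (2 * n)
        + lam * (alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * beta @ beta)
    )


def kkt_violation(X, y, beta, alpha, lam) -> float:
    """Maximum violation of the stationarity (subgradient) conditions."""
    n = len(y)
    grad = -(X.T @ (y - X @ beta)) / n + lam * (1 - alpha) * beta
    active = beta != 0
    v = 0.0
    if active.any():
        v = np.max(np.abs(grad[active] + lam * alpha * np.sign(beta[active])))
    if (~active).any():
        v = max(v, float(np.max(np.maximum(np.abs(grad[~active]) - lam * alpha, 0.0))))
    return float(v)


def lambda_path(X, y, alpha, n_lambda=100, min_ratio=0.001) -> np.ndarray:
    """Decreasing log-spaced grid from lambda_max (all-zero solution) downward."""
    a = max(alpha, _ALPHA_FLOOR)
    lam_max = np.max(np.abs(X.T @ y)) / (len(y) * a)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _fold_assignments(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    order = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    folds[order] = np.arange(n) % k
    return folds


@dataclass
class CVResult:
    alpha: float
    lam: float
    cv_trace: pd.DataFrame = field(repr=False)


def repeated_cv(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: ElasticNetConfig,
) -> CVResult:
    """Grid point minimizing mean RMSE over repeats x folds.

    Each repeat draws a fresh random fold partition; standardization is refit
    inside each training fold. Ties break toward larger lam, then larger alpha
    (the sparser model). The lambda grid is shared across folds (computed on
    the full training data for the given alpha) so means are comparable.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(config.seed)
    alphas = list(config.alpha_grid)

    grids: dict[float, np.ndarray] = {}
    Xs_all = (X - X.mean(0)) / X.std(0)
    yc_all = y - y.mean()
    for a in alphas:
        if config.lambda_grid is not None:
            grids[a] = np.sort(np.asarray(config.lambda_grid, dtype=float))[::-1]
        else:
            grids[a] = lambda_path(Xs_all, yc_all, a, config.n_lambda,
                                   config.lambda_min_ratio)

    sse = {a: np.zeros(len(grids[a])) for a in alphas}
    n_pred = 0
    if n // config.k_folds < 2:
        raise ConfigError("cross-validation fold with fewer than 2 rows")
    for _rep in range(config.repeats):
        folds = _fold_assignments(n, config.k_folds, rng)
        for f in range(config.k_folds):
            val = folds == f
            Xt, yt = X[~val], y[~val]
            mu, sd = Xt.mean(0), Xt.std(0)
            sd = np.where(sd == 0, 1.0, sd)
            Xts = (Xt - mu) / sd
            ym = yt.mean()
            Xvs = (X[val] - mu) / sd
            yv = y[val]
            G = Xts.T @ Xts
            Xy = Xts.T @ (yt - ym)
            for a in alphas:
                betas = enet_path_cd(G, Xy, float(len(yt)), float(a), grids[a],
                                     config.tol, config.max_sweeps)
                pred = ym + Xvs @ betas.T
                sse[a] += ((pred - yv[:, None]) ** 2).sum(axis=0)
            n_pred += int(val.sum())

    rows = []
    for a in alphas:
        rmse = np.sqrt(sse[a] / n_pred)
        for lam, e in zip(grids[a], rmse):
            rows.append({"alpha": a, "lam": lam, "rmse": e})
    trace = pd.DataFrame(rows)
    # argmin with ties broken toward larger lam, then larger alpha
    best = trace.sort_values(["rmse", "lam", "alpha"],
                             ascending=[True, False, False]).iloc[0]
    return CVResult(alpha=float(best["alpha"]), lam=float(best["lam"]), cv_trace=trace)


def fit_model(
    name: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    columns: Sequence[str],
    config: ElasticNetConfig,
) -> ModelFit:
    """Tune by repeated CV, then refit on the full training set."""
    cv = repeated_cv(X_train, y_train, config)
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    mu, sd = X.mean(0), X.std(0)
    sd = np.where(sd == 0, 1.0, sd)
    beta = enet_fit((X - mu) / sd, y - y.mean(), cv.alpha, cv.lam,
                    config.tol, config.max_sweeps)
    return ModelFit(
        name=name, alpha=cv.alpha, lam=cv.lam,
        beta=pd.Series(beta, index=list(columns)),
        intercept=float(y.mean()), x_mean=mu, x_sd=sd, cv_trace=cv.cv_trace,
    )


def evaluate_holdout(fit: ModelFit, X_holdout: np.ndarray,
                     y_holdout: np.ndarray) -> EvaluationResult:
    y = np.asarray(y_holdout, dtype=float)
    if len(y) == 0:
        raise ConfigError("empty hold-out set")
    pred = fit.predict(X_holdout)
    sse = float(((y - pred) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    result = EvaluationResult(r2=1.0 - sse / sst, sse=sse, sst=sst, n_holdout=len(y))
    fit.holdout = result
    return result


def variable_importance(fit: ModelFit) -> pd.DataFrame:
    """Active predictors ranked by |standardized coefficient|, max rescaled to 100."""
    active = fit.beta[fit.beta != 0.0]
    if active.empty:
        return pd.DataFrame(columns=["predictor", "importance", "sign"])
    imp = active.abs() / active.abs().max() * 100.0
    out = pd.DataFrame({
        "predictor": active.index,
        "importance": imp.to_numpy(),
        "sign": np.sign(active.to_numpy()).astype(int),
    })
    return out.sort_values("importance", ascending=False).reset_index(drop=True)
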