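"""Analysis-ready variable construction.

Composite building (SES, household chaos), life-event filtering, rank-based
inverse-normal transformation of the outcome, covariate residualization,
standardization and the 80/20 train/hold-out split. The processing order
mirrors the study design: all variables (predictors and outcome alike) are
regressed on the covariates and the standardized residuals are used downstream.
Standardization moments are estimated on the training rows only and applied to
the hold-out rows, so the hold-out set never leaks into scaling decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .errors import ConfigError

_SES_COLUMNS = 5
_CHAOS_SCALE = (1, 3)


@dataclass
class PredictorPanel:
    """Residualized, standardized predictors with role labels and a split flag."""

    data: pd.DataFrame
    roles: dict[str, str]
    train_mask: np.ndarray
    outcome: pd.Series | None = None
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.roles)
        if missing:
            raise ConfigError(f"columns without a role: {sorted(missing)}")
        bad = {r for r in self.roles.values() if r not in ("gps", "environment", "covariate")}
        if bad:
            raise ConfigError(f"unknown roles: {sorted(bad)}")
        self.train_mask = np.asarray(self.train_mask, dtype=bool)
        if self.train_mask.shape[0] != len(self.data):
            raise ConfigError("split flag length differs from panel rows")

    def columns(self, role: str | tuple[str, ...]) -> list[str]:
        roles = (role,) if isinstance(role, str) else role
        return [c for c in self.data.columns if self.roles[c] in roles]

    def matrix(self, role: str | tuple[str, ...], train: bool | None = None) -> np.ndarray:
        cols = self.columns(role)
        X = self.data[cols].to_numpy(dtype=float)
        if train is None:
            return X
        return X[self.train_mask] if train else X[~self.train_mask]

    def outcome_vector(self, train: bool | None = None) -> np.ndarray:
        if self.outcome is None:
            raise ConfigError("panel has no outcome attached")
        y = self.outcome.to_numpy(dtype=float)
        if train is None:
            return y
        return y[self.train_mask] if train else y[~self.train_mask]

    @property
    def n_train(self) -> int:
        return int(self.train_mask.sum())

    @property
    def n_holdout(self) -> int:
        return int((~self.train_mask).sum())


def _check_complete(df: pd.DataFrame, what: str) -> None:
    if df.isna().to_numpy().any():
        raise ConfigError(f"{what} contains missing values; complete data required")


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean(axis=0)) / x.std(axis=0)


def build_ses_composite(measures: pd.DataFrame) -> pd.Series:
    """Socio-economic composite: row-wise mean of five standardized measures
    (parental qualifications, parental employment, maternal age at first birth)."""
    if measures.shape[1] != _SES_COLUMNS:
        raise ConfigError(
            f"SES composite needs exactly {_SES_COLUMNS} measures, got {measures.shape[1]}"
        )
    _check_complete(measures, "SES measures")
    z = _standardize(measures.to_numpy(dtype=float))
    return pd.Series(z.mean(axis=1), index=measures.index, name="ses")


def build_chaos_score(
    items: pd.DataFrame,
    reverse: tuple[int, ...] = (0, 3, 5),
    scale: tuple[int, int] = _CHAOS_SCALE,
) -> pd.Series:
    """Household-chaos score: mean of six 3-point items, with the order/calm
    items (positions 0, 3 and 5 by default) reverse-coded as max+min-x."""
    _check_complete(items, "chaos items")
    lo, hi = scale
    X = items.to_numpy(dtype=float)
    if np.any((X < lo) | (X > hi)):
        raise ConfigError(f"chaos items must lie on the {scale} scale")
    X = X.copy()
    for j in reverse:
        X[:, j] = hi + lo - X[:, j]
    return pd.Series(X.mean(axis=1), index=items.index, name="chaos")


@dataclass
class LifeEventFilterResult:
    retained: pd.DataFrame
    dropped_excluded: list[str]
    dropped_rare: list[str]

    @property
    def n_retained(self) -> int:
        return self.retained.shape[1]


def filter_life_events(
    items: pd.DataFrame,
    endorsement_min: int = 100,
    excluded_labels: tuple[str, ...] = (),
) -> LifeEventFilterResult:
    """Drop labeled exclusions, then items endorsed by fewer than
    ``endorsement_min`` respondents ("fewer than": exactly at the minimum is kept)."""
    _check_complete(items, "life-event items")
    vals = items.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ConfigError("life-event items must be binary 0/1")
    excluded = [c for c in items.columns if c in set(excluded_labels)]
    kept = items.drop(columns=excluded)
    counts = kept.sum(axis=0)
    rare = [c for c in kept.columns if counts[c] < endorsement_min]
    return LifeEventFilterResult(
        retained=kept.drop(columns=rare),
        dropped_excluded=excluded,
        dropped_rare=rare,
    )


def rank_inverse_normal(y: pd.Series | np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps averaged ranks through the standard normal quantile at
    (rank - offset) / (n + 1 - 2*offset); monotone in ``y``, ties share a value.
    """
    x = np.asarray(y, dtype=float)
    if np.any(np.isnan(x)):
        raise ConfigError("outcome contains missing values")
    if np.ptp(x) == 0:
        raise ConfigError("rank inverse-normal transform undefined for a constant vector")
    ranks = rankdata(x, method="average")
    n = len(x)
    return ndtri((ranks - offset) / (n + 1.0 - 2.0 * offset))


def residualize(
    columns: pd.DataFrame,
    covariates: pd.DataFrame,
    train_mask: np.ndarray | None = None,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Replace each column by its standardized least-squares residual on the
    covariates (plus intercept).

    The regression uses all rows; standardization moments come from the
    training rows when a split is supplied (hold-out rows are scaled with the
    training moments), otherwise from all rows.
    """
    _check_complete(columns, "predictor columns")
    _check_complete(covariates, "covariates")
    C = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ConfigError("covariate matrix is rank deficient")
    Y = columns.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(C, Y, rcond=None)
    resid = Y - C @ coef
    mask = np.ones(len(columns), dtype=bool) if train_mask is None \
        else np.asarray(train_mask, dtype=bool)
    mu = resid[mask].mean(axis=0)
    sd = resid[mask].std(axis=0)
    for j, col in enumerate(columns.columns):
        if sd[j] < tol:
            raise ConfigError(
                f"column {col!r} has zero residual variance after covariate "
                f"adjustment (collinear with covariates)"
            )
    return pd.DataFrame((resid - mu) / sd, columns=columns.columns,
                        index=columns.index)


def split_sample(n: int, fraction: float = 0.8, seed: int = 0) -> np.ndarray:
    """Random, reproducible train/hold-out row partition (True = training)."""
    if n < 10:
        raise ConfigError(f"need at least 10 rows to split, got {n}")
    if not 0.0 < fraction < 1.0:
        raise ConfigError("split fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:n_train]] = True
    return mask


def build_panel(
    predictors: pd.DataFrame,
    roles: dict[str, str],
    outcome: pd.Series,
    covariates: pd.DataFrame,
    split_fraction: float = 0.8,
    seed: int = 0,
    transform_outcome: bool = True,
) -> PredictorPanel:
    """Assemble the analysis panel: outcome transform, residualization of every
    variable on the covariates, training-moment standardization, 80/20 split."""
    mask = split_sample(len(predictors), split_fraction, seed)
    y = pd.Series(
        rank_inverse_normal(outcome) if transform_outcome else outcome.to_numpy(dtype=float),
        index=outcome.index, name=outcome.name or "outcome",
    )
    both = pd.concat([predictors, y.to_frame()], axis=1)
    res = residualize(both, covariates, train_mask=mask)
    return PredictorPanel(
        data=res[predictors.columns],
        roles={c: roles[c] for c in predictors.columns},
        train_mask=mask,
        outcome=res[y.name],
        notes={"transform": "rank-inverse-normal (Blom)" if transform_outcome else "none"},
    )
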