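"""Post-selection estimation of partial regression coefficients.

Three routes for the predictors an L1-penalized fit selects:

* ``naive_ols`` — multiple regression of the selected predictors in the
  training set, ignoring that the same data chose them (anti-conservative);
* ``holdout_ols`` — the same regression in the hold-out set (valid but less
  precise, since the hold-out is the smaller split);
* ``selective_inference`` — conditional (truncated-normal) inference in the
  training set: the lasso selection event {active set, signs} at a fixed
  penalty is a polyhedron {A y <= b} in outcome space, and conditional on it
  the OLS partial coefficient of a selected predictor follows a normal
  distribution truncated to an interval [a, b] computable from the polyhedron
  (the polyhedral lemma). The elastic net is reduced to a lasso selection
  event by absorbing its ridge component into the active-set Gram matrix.

Truncated-normal tail probabilities go through scipy's truncnorm, which
evaluates extreme tails on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import truncnorm

from .errors import ConfigError


@dataclass
class SelectiveEstimate:
    """Conditional inference for one selected predictor."""

    predictor: str
    beta_hat: float
    tau2: float
    a: float  # lower truncation bound of the selection event
    b: float  # upper truncation bound
    p_value: float
    ci: tuple[float, float]
    method: str = "conditional"
    at_boundary: bool = False


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
        raise ConfigError(f"design is rank deficient; collinear columns: {bad}")


def _ols_table(X: pd.DataFrame, y: np.ndarray, method: str) -> pd.DataFrame:
    if X.shape[1] == 0:
        raise ConfigError("empty active set")
    if len(y) == 0:
        raise ConfigError("no rows available for estimation")
    _check_full_rank(X.to_numpy(dtype=float), list(X.columns))
    design = sm.add_constant(X.to_numpy(dtype=float))
    res = sm.OLS(np.asarray(y, dtype=float), design).fit()
    ci = res.conf_int()
    return pd.DataFrame({
        "predictor": list(X.columns),
        "beta_hat": res.params[1:],
        "se": res.bse[1:],
        "p_value": res.pvalues[1:],
        "ci_low": ci[1:, 0],
        "ci_high": ci[1:, 1],
        "method": method,
    })


def naive_ols(X_train: pd.DataFrame, y_train: np.ndarray,
              active: list[str] | None = None) -> pd.DataFrame:
    """Training-set multiple regression of the selected predictors."""
    cols = list(X_train.columns) if active is None else list(active)
    return _ols_table(X_train[cols], y_train, "naive")


def holdout_ols(X_holdout: pd.DataFrame, y_holdout: np.ndarray,
                active: list[str] | None = None) -> pd.DataFrame:
    """Hold-out-set multiple regression of the selected predictors."""
    cols = list(X_holdout.columns) if active is None else list(active)
    return _ols_table(X_holdout[cols], y_holdout, "holdout")


def _selection_polyhedron(X: np.ndarray, active: np.ndarray, signs: np.ndarray,
                          lam1: float, gamma: float):
    """{A y <= b} characterizing the lasso/elastic-net active set and signs.

    ``lam1`` is the total L1 penalty (n * lam * alpha in the 1/(2n)
    convention), ``gamma`` the total ridge penalty added to the active Gram.
    """
    XA = X[:, active]
    H = XA.T @ XA + gamma * np.eye(XA.shape[1])
    K = np.linalg.inv(H)
    S = np.diag(signs.astype(float))
    A_sign = -S @ K @ XA.T
    b_sign = -lam1 * (S @ K @ signs)

    inactive = ~active
    rows = [A_sign]
    bs = [b_sign]
    if inactive.any():
        XI = X[:, inactive]
        D = XI.T - XI.T @ XA @ K @ XA.T
        c0 = lam1 * (XI.T @ XA @ K @ signs)
        rows += [D, -D]
        bs += [lam1 - c0, lam1 + c0]
    return np.vstack(rows), np.concatenate(bs)


def _truncation_interval(A: np.ndarray, b: np.ndarray, eta: np.ndarray,
                         y: np.ndarray) -> tuple[float, float]:
    """Range of the target linear functional compatible with {A y <= b}."""
    c = eta / (eta @ eta)
    obs = eta @ y
    r = y - c * obs
    Ac = A @ c
    Ar = A @ r
    with np.errstate(divide="ignore"):
        bounds = (b - Ar) / Ac
    lower = bounds[Ac < -1e-12]
    upper = bounds[Ac > 1e-12]
    v_lo = float(lower.max()) if lower.size else -np.inf
    v_hi = float(upper.min()) if upper.size else np.inf
    return v_lo, v_hi


def _tn_cdf(x: float, lo: float, hi: float, mu: float, sd: float) -> float:
    return float(truncnorm.cdf(x, (lo - mu) / sd, (hi - mu) / sd,
                               loc=mu, scale=sd))


def _tn_ci(obs: float, lo: float, hi: float, sd: float,
           level: float = 0.95) -> tuple[float, float]:
    """Invert the truncated-normal pivot in its mean parameter by bisection."""
    alpha = 1.0 - level

    def pivot(mu):
        return _tn_cdf(obs, lo, hi, mu, sd)

    span = 30.0 * sd

    def solve(target):
        a, b = obs - span, obs + span
        pa, pb = pivot(a), pivot(b)
        # pivot decreases in mu; expand until the target is bracketed
        for _ in range(60):
            if pa >= target >= pb:
                break
            a -= span
            b += span
            pa, pb = pivot(a), pivot(b)
        else:
            return np.nan
        for _ in range(200):
            mid = 0.5 * (a + b)
            if pivot(mid) > target:
                a = mid
            else:
                b = mid
        return 0.5 * (a + b)

    return (solve(1.0 - alpha / 2.0), solve(alpha / 2.0))


def selective_inference(
    X_train: pd.DataFrame | np.ndarray,
    y_train: np.ndarray,
    lam: float,
    active: list[str] | np.ndarray,
    signs: np.ndarray | None = None,
    alpha: float = 1.0,
    sigma: float | None = None,
    level: float = 0.95,
) -> list[SelectiveEstimate]:
    """Conditional p-values and intervals for the active set of an L1 fit.

    ``lam`` is on the 1/(2n) objective scale used by the elastic-net module;
    with ``alpha`` < 1 the ridge part is absorbed into the selection event's
    Gram matrix. ``sigma`` defaults to the residual standard deviation of the
    selected-model OLS on the training rows. Estimates whose observed value
    sits at a truncation boundary are flagged and given infinite intervals.
    """
    if isinstance(X_train, pd.DataFrame):
        names = list(X_train.columns)
        X = X_train.to_numpy(dtype=float)
    else:
        X = np.asarray(X_train, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y_train, dtype=float)
    n, p = X.shape

    if len(active) == 0:
        raise ConfigError("empty active set")
    if isinstance(active[0], (str, np.str_)):
        act_idx = np.array([names.index(a) for a in active])
    else:
        act_idx = np.asarray(active, dtype=int)
    active_mask = np.zeros(p, dtype=bool)
    active_mask[act_idx] = True

    XA = X[:, act_idx]
    _check_full_rank(XA, [names[j] for j in act_idx])
    GA_inv = np.linalg.inv(XA.T @ XA)
    ols = GA_inv @ XA.T @ y
    if signs is None:
        signs = np.sign(ols)
    signs = np.asarray(signs, dtype=float)

    if sigma is None:
        resid = y - XA @ ols
        dof = max(n - len(act_idx) - 1, 1)
        sigma = float(np.sqrt(resid @ resid / dof))

    lam1 = n * lam * alpha
    gamma = n * lam * (1.0 - alpha)
    A, b = _selection_polyhedron(X, active_mask, signs, lam1, gamma)
    slack = b - A @ y
    if np.min(slack) < -1e-6 * max(1.0, np.abs(b).max()):
        raise ConfigError(
            "observed outcome violates the stated selection event; check that "
            "lam, active set and signs come from the same fit"
        )

    out = []
    for k, j in enumerate(act_idx):
        eta = XA @ GA_inv[:, k]
        obs = float(eta @ y)
        tau = sigma * float(np.sqrt(GA_inv[k, k]))
        v_lo, v_hi = _truncation_interval(A, b, eta, y)
        width = v_hi - v_lo
        boundary = (
            not np.isfinite(width) and (obs <= v_lo + 1e-10 or obs >= v_hi - 1e-10)
        ) or (np.isfinite(width) and width < 1e-12)
        if boundary:
            out.append(SelectiveEstimate(
                predictor=names[j], beta_hat=obs, tau2=tau**2, a=v_lo, b=v_hi,
                p_value=1.0, ci=(-np.inf, np.inf), at_boundary=True,
            ))
            continue
        F0 = _tn_cdf(obs, v_lo, v_hi, 0.0, tau)
        p_val = float(2.0 * min(F0, 1.0 - F0))
        ci = _tn_ci(obs, v_lo, v_hi, tau, level)
        out.append(SelectiveEstimate(
            predictor=names[j], beta_hat=obs, tau2=tau**2, a=v_lo, b=v_hi,
            p_value=min(max(p_val, 0.0), 1.0), ci=ci,
        ))
    return out


def estimates_frame(estimates: list[SelectiveEstimate]) -> pd.DataFrame:
    return pd.DataFrame([
        {"predictor": e.predictor, "beta_hat": e.beta_hat,
         "tau": np.sqrt(e.tau2), "trunc_low": e.a, "trunc_high": e.b,
         "p_value": e.p_value, "ci_low": e.ci[0], "ci_high": e.ci[1],
         "method": e.method}
        for e in estimates
    ])
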