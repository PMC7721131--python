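"""Bootstrapped hold-out R^2 distributions and nested-model comparison.

Hold-out rows are resampled with replacement (B draws; the same row indices for
every model, so pairwise R^2 differences are paired); the fitted models are
*not* refit. 95% intervals are the 2.5th/97.5th percentiles, and a nested
comparison is flagged significant when the interval for the R^2 difference
excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enet import ModelFit
from .errors import ConfigError


@dataclass
class ModelR2Distribution:
    name: str
    point: float
    draws: np.ndarray = field(repr=False)
    ci: tuple[float, float] = (np.nan, np.nan)
    n_degenerate: int = 0


@dataclass
class DeltaR2Comparison:
    pair: tuple[str, str]
    median: float
    ci: tuple[float, float]
    significant: bool
    draws: np.ndarray = field(repr=False)


@dataclass
class ComparisonReport:
    models: dict[str, ModelR2Distribution]
    deltas: dict[tuple[str, str], DeltaR2Comparison]
    B: int
    seed: int

    def summary(self) -> pd.DataFrame:
        rows = [
            {"quantity": f"R2[{m.name}]", "estimate": m.point,
             "ci_low": m.ci[0], "ci_high": m.ci[1], "significant": None}
            for m in self.models.values()
        ]
        rows += [
            {"quantity": f"dR2[{a}-{b}]", "estimate": d.median,
             "ci_low": d.ci[0], "ci_high": d.ci[1], "significant": d.significant}
            for (a, b), d in self.deltas.items()
        ]
        return pd.DataFrame(rows)


def _resample_r2(y: np.ndarray, pred: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """R^2 of fixed predictions on each resample (rows of ``idx``)."""
    ys = y[idx]
    ps = pred[idx]
    sst = ((ys - ys.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sse = ((ys - ps) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - sse / sst
    r2[sst == 0] = np.nan
    return r2


def percentile_ci(draws: np.ndarray, level: float = 95.0) -> tuple[float, float]:
    lo = (100.0 - level) / 2.0
    return (float(np.percentile(draws, lo)), float(np.percentile(draws, 100.0 - lo)))


def significance_flag(delta_draws: np.ndarray, level: float = 95.0) -> bool:
    """True iff the percentile interval of the differences excludes zero."""
    d = np.asarray(delta_draws, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) == 0:
        raise ConfigError("empty delta distribution")
    lo, hi = percentile_ci(d, level)
    return bool(lo > 0.0 or hi < 0.0)


def bootstrap_r2(
    fits: dict[str, ModelFit] | list[ModelFit],
    X_holdout: dict[str, np.ndarray],
    y_holdout: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
) -> ComparisonReport:
    """Bootstrap hold-out R^2 for each fitted model and paired nested deltas.

    ``X_holdout`` maps model name to that model's hold-out design (models may
    use different predictor sets but share rows). ``pairs`` lists (larger,
    smaller) model names to compare; defaults to all ordered pairs in listing
    order. Degenerate resamples (zero outcome variance) are dropped per model
    with a count retained.
    """
    if B < 2:
        raise ConfigError("need at least 2 bootstrap draws")
    fit_map = {f.name: f for f in fits} if isinstance(fits, list) else dict(fits)
    y = np.asarray(y_holdout, dtype=float)
    n = len(y)
    preds = {}
    for name, fit in fit_map.items():
        pred = fit.predict(X_holdout[name])
        if len(pred) != n:
            raise ConfigError(f"model {name!r} hold-out rows differ from outcome")
        preds[name] = pred

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    draws = {name: _resample_r2(y, pred, idx) for name, pred in preds.items()}

    models = {}
    for name, fit in fit_map.items():
        d = draws[name]
        ok = d[~np.isnan(d)]
        point = 1.0 - ((y - preds[name]) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        models[name] = ModelR2Distribution(
            name=name, point=float(point), draws=d,
            ci=percentile_ci(ok), n_degenerate=int(np.isnan(d).sum()),
        )

    if pairs is None:
        names = list(fit_map)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    deltas = {}
    for a, b in pairs:
        dd = draws[a] - draws[b]
        ok = dd[~np.isnan(dd)]
        deltas[(a, b)] = DeltaR2Comparison(
            pair=(a, b), median=float(np.median(ok)), ci=percentile_ci(ok),
            significant=significance_flag(ok), draws=dd,
        )
    return ComparisonReport(models=models, deltas=deltas, B=B, seed=seed)
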