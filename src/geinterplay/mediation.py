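"""Gene-environment correlation (rGE) and reciprocal mediation decomposition.

The genetic and environmental model predictions on the hold-out set (the
composites G_ea and E_ea) summarize, respectively, the genetic and the
environmental information the panel carries about the outcome. Their Pearson
correlation operationalizes rGE. Mediation is the saturated linear three-
variable decomposition: with X the predictor, M the mediator and Y the outcome,

    beta_c  : Y ~ X            (total effect)
    beta_a  : M ~ X
    beta_b, beta_c_prime : Y ~ X + M   (M->Y adjusted; direct effect)

indirect = beta_a * beta_b = beta_c - beta_c_prime (an exact identity in the
linear case), and proportion mediated = (beta_c - beta_c_prime) / beta_c.
Running the decomposition in both orientations separates environmentally
mediated genetic effects from genetic confounding of environmental effects —
statistically equivalent roles, conceptually distinct readings. Confidence
intervals are percentile bootstrap with all paths refit per resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

_BETA_C_TOL = 1e-8


@dataclass
class CompositePair:
    """Hold-out predictions of the G and E models plus the hold-out outcome."""

    g_ea: np.ndarray
    e_ea: np.ndarray
    outcome: np.ndarray

    def __post_init__(self) -> None:
        self.g_ea = np.asarray(self.g_ea, dtype=float)
        self.e_ea = np.asarray(self.e_ea, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=float)
        if not len(self.g_ea) == len(self.e_ea) == len(self.outcome):
            raise ConfigError("composite vectors must have equal length")


@dataclass
class RgeResult:
    correlation: float
    ci: tuple[float, float]
    draws: np.ndarray = field(repr=False)


@dataclass
class MediationResult:
    beta_c: float
    beta_a: float
    beta_b: float
    beta_c_prime: float
    indirect: float
    proportion_mediated: float | None
    ci: dict[str, tuple[float, float]]
    orientation: str = ""
    B: int = 0


def rge_correlation(pair: CompositePair, B: int = 1000, seed: int = 0) -> RgeResult:
    """Pearson correlation of the two composites with a percentile bootstrap CI."""
    g, e = pair.g_ea, pair.e_ea
    if np.std(g) == 0 or np.std(e) == 0:
        raise ConfigError("zero-variance composite; correlation undefined")
    r = float(np.corrcoef(g, e)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(g)
    idx = rng.integers(0, n, size=(B, n))
    gs, es = g[idx], e[idx]
    gs = gs - gs.mean(axis=1, keepdims=True)
    es = es - es.mean(axis=1, keepdims=True)
    denom = np.sqrt((gs**2).sum(axis=1) * (es**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        draws = (gs * es).sum(axis=1) / denom
    ok = draws[~np.isnan(draws)]
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return RgeResult(correlation=r, ci=(float(lo), float(hi)), draws=draws)


def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """(beta_c, beta_a, beta_b, beta_c_prime) by three least-squares fits."""
    xc = x - x.mean()
    mc = m - m.mean()
    yc = y - y.mean()
    beta_c = float(xc @ yc / (xc @ xc))
    beta_a = float(xc @ mc / (xc @ xc))
    Z = np.column_stack([xc, mc])
    coef, *_ = np.linalg.lstsq(Z, yc, rcond=None)
    beta_c_prime, beta_b = float(coef[0]), float(coef[1])
    return beta_c, beta_a, beta_b, beta_c_prime


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    orientation: str = "",
) -> MediationResult:
    """Linear mediation decomposition with a path-refitting bootstrap.

    Inputs should be standardized, equal-length vectors. The proportion
    mediated is reported as None when the total effect is numerically zero.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not len(x) == len(m) == len(y):
        raise ConfigError("x, m, y must have equal length")
    beta_c, beta_a, beta_b, beta_c_prime = _paths(x, m, y)
    indirect = beta_c - beta_c_prime
    prop = indirect / beta_c if abs(beta_c) > _BETA_C_TOL else None

    rng = np.random.default_rng(seed)
    n = len(x)
    keys = ("beta_c", "beta_a", "beta_b", "beta_c_prime", "indirect", "proportion")
    draws: dict[str, list[float]] = {k: [] for k in keys}
    for _ in range(B):
        i = rng.integers(0, n, size=n)
        try:
            bc, ba, bb, bcp = _paths(x[i], m[i], y[i])
        except (ZeroDivisionError, FloatingPointError):
            continue
        draws["beta_c"].append(bc)
        draws["beta_a"].append(ba)
        draws["beta_b"].append(bb)
        draws["beta_c_prime"].append(bcp)
        draws["indirect"].append(bc - bcp)
        if abs(bc) > _BETA_C_TOL:
            draws["proportion"].append((bc - bcp) / bc)
    ci = {
        k: tuple(np.percentile(v, [2.5, 97.5])) if v else (np.nan, np.nan)
        for k, v in draws.items()
    }
    return MediationResult(
        beta_c=beta_c, beta_a=beta_a, beta_b=beta_b, beta_c_prime=beta_c_prime,
        indirect=indirect, proportion_mediated=prop, ci=ci,
        orientation=orientation, B=B,
    )


def run_both_orientations(
    pair: CompositePair, B: int = 1000, seed: int = 0
) -> dict[str, MediationResult]:
    """Both mediation readings of the composite triangle.

    "G-via-E": environmental mediation of genetic effects (E_ea mediates
    G_ea -> outcome). "E-via-G": genetic confounding of environmental effects
    (G_ea mediates E_ea -> outcome).
    """
    def z(v):
        sd = np.std(v)
        if sd == 0:
            raise ConfigError("zero-variance composite")
        return (v - np.mean(v)) / sd

    g, e, y = z(pair.g_ea), z(pair.e_ea), z(pair.outcome)
    return {
        "G-via-E": mediate(g, e, y, B=B, seed=seed, orientation="G-via-E"),
        "E-via-G": mediate(e, g, y, B=B, seed=seed + 1, orientation="E-via-G"),
    }
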