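"""Synthetic cohorts emulating a multivariable gene-environment interplay study.

Two tiers:

* **SNP tier** (:func:`simulate_snp_cohort`) — a small genotype cohort with LD
  blocks plus external-style GWAS summary statistics computed on an independent
  discovery replicate, for exercising summary-statistic polygenic scoring.
* **Score tier** (:func:`simulate_score_cohort`) — a cohort of polygenic scores
  (default 20), environmental measures (default one SES-like and one household-
  chaos-like continuous composite plus 11 binary life-event indicators),
  covariates (age, sex, 10 PCs, genotyping chip) and a continuous outcome.

The score tier is built on three standard-normal latent factors: a genetic
composite ``G``, an environmental composite ``E`` with ``cor(G, E) = rge``, and
an environment-specific factor ``Sp`` (the pooled unique parts of the
continuous environmental composites, orthogonal to both ``G`` and ``E``). The
outcome is

    y = a*G + b*E + c*Sp + (optional GxE product terms) + noise.

Observed predictors are noisy indicators loading on their composite; binary
life events are thresholded latent normals. The path coefficients ``(a, b, c)``
are solved so that the *population* R-squared of the best linear predictor from
the observed GPS set, environment set, and their union match the configured
targets exactly, with ``cor(G, E)`` pinned at ``rge``. The truth record carries
the implied predictor covariance matrix, so all population-level targets (model
R-squared, the correlation of the model-based composites, mediation
proportions) can be recomputed analytically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtri

from .errors import ConfigError, FeasibilityError
from .lassosum import LDReference, SummaryStatisticsSet

# fixed stage offsets so each generator stage has its own child stream
_STAGE_SCORE = 11
_STAGE_COVARIATES = 23
_STAGE_SNP = 37
_STAGE_DISCOVERY = 41


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    ``target_r2`` maps model names ("G", "E", "G+E") to intended population
    R-squared values. "G" and "E" are required when a map is given; the third
    degree of freedom comes from the "G+E" entry, or (if that is absent) from
    ``prop_g_mediated`` or ``prop_e_confounded``; with none of these the
    environment-specific outcome path is fixed at zero. Supplying more than one
    third constraint is an error: the system would be over-determined.
    """

    n_individuals: int = 5000
    n_snps: int = 60
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_ld_blocks: int = 6
    n_gps: int = 20
    n_env_continuous: int = 2
    n_env_binary: int = 11
    rge: float = 0.0
    prop_g_mediated: float | None = None
    prop_e_confounded: float | None = None
    gxe_effects: Sequence[tuple[int, int, float]] = ()
    target_r2: dict[str, float] | None = None
    seed: int = 0
    # indicator structure: exchangeable within-set correlations are a free
    # modeling choice, not an empirical correlation structure
    gps_loading: float = 0.85
    env_loading: float = 0.9
    binary_endorsement: Sequence[float] | None = None
    covariate_effect: float = 0.05
    # SNP tier
    snp_h2: float = 0.3
    causal_per_block: int = 1
    ld_decay: float = 0.9
    discovery_n: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_snps", "n_ld_blocks", "n_gps",
                     "n_env_continuous", "n_env_binary"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not -1.0 <= self.rge <= 1.0:
            raise ConfigError(f"rge must lie in [-1, 1], got {self.rge}")
        for name in ("prop_g_mediated", "prop_e_confounded"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.target_r2 is not None:
            for k, v in self.target_r2.items():
                if k not in ("G", "E", "G+E"):
                    raise ConfigError(f"unknown target_r2 key {k!r}")
                if not 0.0 < v < 1.0:
                    raise ConfigError(f"target_r2[{k!r}] must lie in (0, 1)")
        if not 0.0 < self.gps_loading < 1.0 or not 0.0 < self.env_loading < 1.0:
            raise ConfigError("indicator loadings must lie in (0, 1)")


def calibrated_preset(seed: int = 0, **overrides) -> GeneratorConfig:
    """The full-scale calibrated study design: n = 7,026, 20 GPS,
    13 environments, rge = 0.38 and population model R-squared targets
    G: .18, E: .30, G+E: .36."""
    base = dict(
        n_individuals=7026,
        n_gps=20,
        n_env_continuous=2,
        n_env_binary=11,
        rge=0.38,
        target_r2={"G": 0.18, "E": 0.30, "G+E": 0.36},
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def _predictor_names(cfg: GeneratorConfig) -> tuple[list[str], dict[str, str]]:
    names = [f"gps_{i + 1:02d}" for i in range(cfg.n_gps)]
    env = ["ses", "chaos"][: cfg.n_env_continuous]
    env += [f"env_c{i + 1}" for i in range(len(env), cfg.n_env_continuous)]
    env += [f"life_event_{i + 1:02d}" for i in range(cfg.n_env_binary)]
    roles = {n: "gps" for n in names}
    roles.update({n: "environment" for n in env})
    return names + env, roles


def _bvn_upper(t1: float, t2: float, r: float) -> float:
    """P(Z1 > t1, Z2 > t2) for standard bivariate normal with correlation r."""
    mvn = stats.multivariate_normal(mean=[0.0, 0.0],
                                    cov=[[1.0, r], [r, 1.0]])
    return float(mvn.cdf([-t1, -t2]))


def _moments(cfg: GeneratorConfig):
    """Population covariance of the observed predictors, and their covariances
    with the three outcome-path latents (G, E, Sp)."""
    kappa, lam, rho = cfg.gps_loading, cfg.env_loading, cfg.rge
    ng, nc, nb = cfg.n_gps, cfg.n_env_continuous, cfg.n_env_binary
    ke = nc + nb
    p = ng + ke
    if cfg.binary_endorsement is None:
        endorse = np.linspace(0.10, 0.45, nb)
    else:
        endorse = np.asarray(cfg.binary_endorsement, dtype=float)
        if endorse.shape != (nb,) or np.any((endorse <= 0) | (endorse >= 1)):
            raise ConfigError("binary_endorsement must give n_env_binary rates in (0,1)")
    thresh = ndtri(1.0 - endorse)
    phi = stats.norm.pdf(thresh)

    Sigma = np.zeros((p, p))
    M = np.zeros((p, 3))  # columns: cov with G, E, Sp
    # the environment-specific factor pools the unique parts of the *continuous*
    # environmental composites, which the panel observes without thresholding
    sp_load = np.sqrt(1.0 - lam**2) / np.sqrt(nc)

    # GPS block
    Sigma[:ng, :ng] = kappa**2
    np.fill_diagonal(Sigma[:ng, :ng], 1.0)
    M[:ng, 0] = kappa
    M[:ng, 1] = kappa * rho
    # continuous environments
    for j in range(nc):
        jj = ng + j
        Sigma[jj, jj] = 1.0
        for l in range(j):
            Sigma[jj, ng + l] = Sigma[ng + l, jj] = lam**2
        Sigma[jj, :ng] = Sigma[:ng, jj] = kappa * lam * rho
        M[jj] = (lam * rho, lam, sp_load)
    # binary environments
    for j in range(nb):
        jj = ng + nc + j
        pj = endorse[j]
        Sigma[jj, jj] = pj * (1.0 - pj)
        Sigma[jj, :ng] = Sigma[:ng, jj] = phi[j] * kappa * lam * rho
        for l in range(nc):
            Sigma[jj, ng + l] = Sigma[ng + l, jj] = phi[j] * lam**2
        for l in range(j):
            ll = ng + nc + l
            cov = _bvn_upper(thresh[j], thresh[l], lam**2) - pj * endorse[l]
            Sigma[jj, ll] = Sigma[ll, jj] = cov
        M[jj] = phi[j] * np.array([lam * rho, lam, 0.0])
    return Sigma, M, endorse, thresh


def _latent_start(tg: float, te: float, tge: float | None, rho: float):
    """Closed-form latent-level path solution, used to seed the observed-level
    root solve. Exact when indicators are noiseless."""
    u = np.sqrt(tg)
    if tge is None:
        a = (u - rho * np.sqrt(max(te, 0.0))) / max(1.0 - rho**2, 1e-9)
        b = np.sqrt(te) - rho * a
        return np.array([a, b])
    gap = tge - te
    if gap < 0 or 1.0 - rho**2 <= 0:
        return np.array([u * 0.6, np.sqrt(te) * 0.8, 0.1])
    a = np.sqrt(gap / (1.0 - rho**2))
    if abs(rho) > 1e-8:
        v0 = (u - (1.0 - rho**2) * a) / rho
    else:
        v0 = np.sqrt(te)
    c2 = te - v0**2
    if c2 < 0:
        return np.array([a, max(v0 - a * rho, 0.1), 0.1])
    return np.array([a, v0 - a * rho, np.sqrt(c2)])


def _solve_paths(cfg: GeneratorConfig, Sigma: np.ndarray, M: np.ndarray):
    """Solve outcome path coefficients (a, b, c) against the configured targets."""
    if cfg.target_r2 is None or "G" not in cfg.target_r2 or "E" not in cfg.target_r2:
        raise ConfigError('target_r2 with "G" and "E" entries is required')
    tg, te = cfg.target_r2["G"], cfg.target_r2["E"]
    tge = cfg.target_r2.get("G+E")
    rho = cfg.rge
    third = [name for name, v in (("G+E", tge),
                                  ("prop_g_mediated", cfg.prop_g_mediated),
                                  ("prop_e_confounded", cfg.prop_e_confounded))
             if v is not None]
    if len(third) > 1:
        raise ConfigError(
            f"over-determined calibration: only one of G+E target / mediation "
            f"fractions may be given, got {third}"
        )
    if tge is not None and tge < max(tg, te) - 1e-12:
        raise FeasibilityError(
            f"target_r2['G+E'] = {tge} must be at least max of the single-model "
            f"targets ({max(tg, te)})"
        )

    ng = cfg.n_gps
    idx = {"G": np.arange(ng), "E": np.arange(ng, Sigma.shape[0]),
           "G+E": np.arange(Sigma.shape[0])}

    def quad(model: str) -> np.ndarray:
        S = idx[model]
        Ms = M[S]
        return Ms.T @ np.linalg.solve(Sigma[np.ix_(S, S)], Ms)

    Q = {m: quad(m) for m in ("G", "E", "G+E")}
    # any third constraint frees the environment-specific path coefficient
    use_c = len(third) == 1

    def _embed(x):
        return np.array([x[0], x[1], x[2] if use_c else 0.0])

    def residuals(x):
        v = _embed(x)
        res = [v @ Q["G"] @ v - tg, v @ Q["E"] @ v - te]
        if tge is not None:
            res.append(v @ Q["G+E"] @ v - tge)
        elif cfg.prop_g_mediated is not None:
            res.append(v[1] * rho - cfg.prop_g_mediated * (v[0] + v[1] * rho))
        elif cfg.prop_e_confounded is not None:
            res.append(v[0] * rho - cfg.prop_e_confounded * (v[0] * rho + v[1]))
        return np.asarray(res[: len(x)])

    def jacobian(x):
        v = _embed(x)
        rows = [2.0 * Q["G"] @ v, 2.0 * Q["E"] @ v]
        if tge is not None:
            rows.append(2.0 * Q["G+E"] @ v)
        elif cfg.prop_g_mediated is not None:
            m = cfg.prop_g_mediated
            rows.append(np.array([-m, rho - m * rho, 0.0]))
        elif cfg.prop_e_confounded is not None:
            m = cfg.prop_e_confounded
            rows.append(np.array([rho - m * rho, -m, 0.0]))
        J = np.asarray(rows[: len(x)])
        return J[:, : len(x)]

    x0 = _latent_start(tg, te, tge, rho)
    if use_c and len(x0) == 2:
        x0 = np.append(x0, 0.1)
    elif not use_c and len(x0) == 3:
        x0 = x0[:2]
    starts = [x0]
    start_rng = np.random.default_rng(12345)  # fixed: solver is deterministic
    starts += [x0 * start_rng.uniform(0.5, 1.5, size=len(x0)) for _ in range(8)]
    starts += [start_rng.uniform(-1.0, 1.0, size=len(x0)) for _ in range(16)]
    sol = None
    for x_start in starts:
        cand = optimize.root(residuals, x_start, jac=jacobian, method="hybr",
                             tol=1e-14)
        if np.max(np.abs(residuals(cand.x))) < 1e-10:
            sol = cand
            break
        if sol is None or np.max(np.abs(residuals(cand.x))) < np.max(
                np.abs(residuals(sol.x))):
            sol = cand
    if sol is None or np.max(np.abs(residuals(sol.x))) > 1e-9:
        raise FeasibilityError(
            "no path coefficients satisfy the configured targets "
            f"(rge={rho}, target_r2={cfg.target_r2}, "
            f"prop_g_mediated={cfg.prop_g_mediated}, "
            f"prop_e_confounded={cfg.prop_e_confounded}); residuals="
            f"{residuals(sol.x)}"
        )
    if use_c:
        a, b, c = sol.x
    else:
        (a, b), c = sol.x, 0.0
    if a + b * rho < 0:  # orient the genetic path positively
        a, b, c = -a, -b, -c
    explained = a**2 + b**2 + c**2 + 2 * a * b * rho
    if explained > 1.0 + 1e-10:
        raise FeasibilityError(
            f"implied outcome variance decomposition exceeds 1: path variance "
            f"= {explained:.4f}"
        )
    return float(a), float(b), float(c), float(np.sqrt(max(1.0 - explained, 0.0)))


@dataclass
class ScoreTruth:
    """Generating parameters of a score-tier cohort, with analytic accessors.

    Sufficient to recompute every population-level target (model R-squared,
    composite correlation, mediation proportions) without data.
    """

    a: float
    b: float
    c: float
    rho: float
    sigma_eps: float
    names: list[str]
    roles: dict[str, str]
    gps_loading: float
    env_loading: float
    endorsement: np.ndarray
    thresholds: np.ndarray
    Sigma: np.ndarray = field(repr=False)
    M: np.ndarray = field(repr=False)
    gxe_effects: tuple = ()
    config: GeneratorConfig | None = field(default=None, repr=False)

    @property
    def sigma_xy(self) -> np.ndarray:
        """Covariance of each observed predictor with the additive outcome."""
        return self.M @ np.array([self.a, self.b, self.c])

    def _indices(self, model: str) -> np.ndarray:
        ng = sum(1 for r in self.roles.values() if r == "gps")
        p = len(self.names)
        return {"G": np.arange(ng), "E": np.arange(ng, p),
                "G+E": np.arange(p)}[model]

    def population_r2(self, model: str) -> float:
        """Population R^2 of the best linear predictor from a predictor set
        (additive outcome component; outcome variance normalized to 1)."""
        S = self._indices(model)
        s = self.sigma_xy[S]
        return float(s @ np.linalg.solve(self.Sigma[np.ix_(S, S)], s))

    def _weights(self, model: str) -> np.ndarray:
        S = self._indices(model)
        return np.linalg.solve(self.Sigma[np.ix_(S, S)], self.sigma_xy[S])

    def composite_covariance(self) -> np.ndarray:
        """Population covariance of (G-model prediction, E-model prediction, y)."""
        wg, we = self._weights("G"), self._weights("E")
        Sg, Se = self._indices("G"), self._indices("E")
        cgg = wg @ self.Sigma[np.ix_(Sg, Sg)] @ wg
        cee = we @ self.Sigma[np.ix_(Se, Se)] @ we
        cge = wg @ self.Sigma[np.ix_(Sg, Se)] @ we
        return np.array([
            [cgg, cge, self.population_r2("G")],
            [cge, cee, self.population_r2("E")],
            [self.population_r2("G"), self.population_r2("E"), 1.0],
        ])

    def population_rge(self) -> float:
        """Population correlation of the two model-based composites."""
        C = self.composite_covariance()
        return float(C[0, 1] / np.sqrt(C[0, 0] * C[1, 1]))

    def population_mediation(self, orientation: str = "G-via-E") -> dict[str, float]:
        """Analytic mediation decomposition on the standardized composites."""
        C = self.composite_covariance()
        d = np.sqrt(np.diag(C))
        R = C / np.outer(d, d)
        if orientation == "G-via-E":
            r_xy, r_my, r_xm = R[0, 2], R[1, 2], R[0, 1]
        elif orientation == "E-via-G":
            r_xy, r_my, r_xm = R[1, 2], R[0, 2], R[0, 1]
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
        beta_c = r_xy
        beta_c_prime = (r_xy - r_my * r_xm) / (1.0 - r_xm**2)
        return {
            "beta_c": beta_c,
            "beta_c_prime": beta_c_prime,
            "indirect": beta_c - beta_c_prime,
            "proportion_mediated": (beta_c - beta_c_prime) / beta_c,
        }

    @property
    def latent_prop_g_mediated(self) -> float:
        return self.b * self.rho / (self.a + self.b * self.rho)

    @property
    def latent_prop_e_confounded(self) -> float:
        return self.a * self.rho / (self.a * self.rho + self.b)

    def draw_composites(self, n: int, seed: int = 0) -> pd.DataFrame:
        """Sample (G-model prediction, E-model prediction, outcome) triples from
        their population joint distribution — handy for estimator tests."""
        rng = np.random.default_rng(seed)
        X = rng.multivariate_normal(np.zeros(3), self.composite_covariance(),
                                    size=n)
        return pd.DataFrame(X, columns=["g_ea", "e_ea", "outcome"])

    def to_json(self) -> str:
        d = {
            "a": self.a, "b": self.b, "c": self.c, "rho": self.rho,
            "sigma_eps": self.sigma_eps, "names": self.names,
            "roles": self.roles, "gps_loading": self.gps_loading,
            "env_loading": self.env_loading,
            "endorsement": self.endorsement.tolist(),
            "thresholds": self.thresholds.tolist(),
            "Sigma": self.Sigma.tolist(), "M": self.M.tolist(),
            "gxe_effects": [list(t) for t in self.gxe_effects],
        }
        return json.dumps(d, indent=1)


@dataclass
class SnpTruth:
    """Generating parameters of a SNP-tier cohort."""

    maf: np.ndarray
    beta_raw: np.ndarray
    causal_idx: np.ndarray
    blocks: list[tuple[int, int]]
    h2: float
    ld_decay: float


@dataclass
class SyntheticCohort:
    """A generated cohort: predictor panel inputs plus the generating truth."""

    outcome: pd.Series
    truth: ScoreTruth | SnpTruth
    predictors: pd.DataFrame | None = None
    covariates: pd.DataFrame | None = None
    roles: dict[str, str] | None = None
    genotypes: pd.DataFrame | None = None
    summary_stats: SummaryStatisticsSet | None = None
    ld_blocks: list[tuple[int, int]] | None = None
    latents: pd.DataFrame | None = None  # true composites (G, E, Sp) per row


def simulate_covariates(n: int, seed: int = 0) -> pd.DataFrame:
    """Covariate table: age, sex, 10 exactly orthogonal PC-like columns, chip."""
    if n <= 0:
        raise ConfigError("n must be positive")
    rng = _rng(seed, _STAGE_COVARIATES)
    age = rng.normal(16.0, 0.3, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    raw = rng.standard_normal((n, 10))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    pcs = q * np.sqrt(n)  # centered, pairwise orthogonal, unit variance
    chip = rng.integers(0, 2, size=n).astype(float)
    cols = {"age": age, "sex": sex}
    cols.update({f"pc{i + 1}": pcs[:, i] for i in range(10)})
    cols["chip"] = chip
    return pd.DataFrame(cols)


def simulate_score_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate the score-tier cohort (GPS + environments + covariates + outcome)."""
    cfg = config
    if cfg.target_r2 is None:
        # a mild default so a bare config is usable out of the box
        cfg = GeneratorConfig(**{**asdict(cfg), "target_r2": {"G": 0.15, "E": 0.25},
                                 "gxe_effects": tuple(cfg.gxe_effects)})
    names, roles = _predictor_names(cfg)
    Sigma, M, endorse, thresh = _moments(cfg)
    a, b, c, sigma_eps = _solve_paths(cfg, Sigma, M)
    truth = ScoreTruth(
        a=a, b=b, c=c, rho=cfg.rge, sigma_eps=sigma_eps, names=names,
        roles=roles, gps_loading=cfg.gps_loading, env_loading=cfg.env_loading,
        endorsement=endorse, thresholds=thresh, Sigma=Sigma, M=M,
        gxe_effects=tuple(tuple(t) for t in cfg.gxe_effects), config=cfg,
    )

    n = cfg.n_individuals
    ng, nc, nb = cfg.n_gps, cfg.n_env_continuous, cfg.n_env_binary
    ke = nc + nb
    rng = _rng(cfg.seed, _STAGE_SCORE)
    G = rng.standard_normal(n)
    E = cfg.rge * G + np.sqrt(1.0 - cfg.rge**2) * rng.standard_normal(n)
    u = rng.standard_normal((n, ng))
    s = rng.standard_normal((n, ke))
    Sp = s[:, :nc].sum(axis=1) / np.sqrt(nc)

    kappa, lam = cfg.gps_loading, cfg.env_loading
    gps = kappa * G[:, None] + np.sqrt(1 - kappa**2) * u
    z_env = lam * E[:, None] + np.sqrt(1 - lam**2) * s

    # covariates, with small loadings mixed into predictors and outcome so that
    # covariate residualization is consequential downstream
    cov = simulate_covariates(n, cfg.seed)
    C = cov.to_numpy(dtype=float)
    Cs = (C - C.mean(axis=0)) / np.where(C.std(axis=0) == 0, 1.0, C.std(axis=0))
    k_cov = Cs.shape[1]
    delta = cfg.covariate_effect
    W = rng.standard_normal((k_cov, ng + ke)) * delta / np.sqrt(k_cov)
    w_y = rng.standard_normal(k_cov) * delta / np.sqrt(k_cov)
    mix = Cs @ W

    gps_obs = gps + mix[:, :ng]
    z_env_mixed = z_env + mix[:, ng:]
    env_cont = z_env_mixed[:, :nc]
    env_bin = (z_env_mixed[:, nc:] > thresh[None, :]).astype(float)

    y = a * G + b * E + c * Sp
    for gi, ej, gamma in cfg.gxe_effects:
        if not (0 <= gi < ng and 0 <= ej < ke):
            raise ConfigError(f"gxe_effects index out of range: {(gi, ej)}")
        xg = gps[:, gi]  # core indicator values (population variance 1)
        if ej < nc:
            xe = z_env[:, ej]
            exy = Sigma[gi, ng + ej]
        else:
            pj = endorse[ej - nc]
            xe = ((z_env[:, ej] > thresh[ej - nc]) - pj) / np.sqrt(pj * (1 - pj))
            exy = Sigma[gi, ng + ej] / np.sqrt(pj * (1 - pj))
        y = y + gamma * (xg * xe - exy)
    y = y + sigma_eps * rng.standard_normal(n) + Cs @ w_y

    predictors = pd.DataFrame(
        np.column_stack([gps_obs, env_cont, env_bin]), columns=names
    )
    return SyntheticCohort(
        outcome=pd.Series(y, name="ea"),
        truth=truth,
        predictors=predictors,
        covariates=cov,
        roles=roles,
        latents=pd.DataFrame({"G": G, "E": E, "Sp": Sp}),
    )


def _ar1_chol(m: int, decay: float) -> np.ndarray:
    idx = np.arange(m)
    corr = decay ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr + 1e-12 * np.eye(m))


def _draw_genotypes(rng, n: int, mafs: np.ndarray,
                    blocks: list[tuple[int, int]], decay: float) -> np.ndarray:
    m = len(mafs)
    geno = np.zeros((n, m))
    cut = ndtri(mafs)
    for start, stop in blocks:
        L = _ar1_chol(stop - start, decay)
        for _hap in range(2):
            z = rng.standard_normal((n, stop - start)) @ L.T
            geno[:, start:stop] += (z < cut[start:stop]).astype(float)
    return geno


def simulate_snp_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate the SNP-tier cohort and its discovery-replicate summary statistics.

    Genotypes are drawn per LD block from an autoregressive latent haplotype
    model and thresholded at the per-SNP allele frequency. The phenotype is a
    linear combination of standardized genotypes at the causal SNPs plus noise,
    scaled to the configured heritability. Summary statistics (per-SNP
    phenotype-genotype correlations) come from an independently simulated
    discovery replicate of the same generative process, never from the emitted
    cohort.
    """
    cfg = config
    if cfg.n_snps % cfg.n_ld_blocks != 0:
        raise ConfigError(
            f"n_snps ({cfg.n_snps}) must divide into n_ld_blocks ({cfg.n_ld_blocks})"
        )
    if not 0.0 <= cfg.snp_h2 < 1.0:
        raise ConfigError("snp_h2 must lie in [0, 1)")
    m = cfg.n_snps
    size = m // cfg.n_ld_blocks
    blocks = [(i * size, (i + 1) * size) for i in range(cfg.n_ld_blocks)]
    rng = _rng(cfg.seed, _STAGE_SNP)
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)

    beta_raw = np.zeros(m)
    causal = []
    if cfg.causal_per_block > 0 and cfg.snp_h2 > 0:
        for start, stop in blocks:
            picks = rng.choice(np.arange(start, stop),
                               size=min(cfg.causal_per_block, stop - start),
                               replace=False)
            causal.extend(picks.tolist())
            beta_raw[picks] = rng.choice([-1.0, 1.0], size=len(picks)) \
                * rng.uniform(0.5, 1.0, size=len(picks))
    causal = np.sort(np.asarray(causal, dtype=int))

    def phenotype(geno: np.ndarray, noise_rng) -> np.ndarray:
        nloc = geno.shape[0]
        sd = geno.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (geno - geno.mean(axis=0)) / sd
        g = Xs @ beta_raw
        eps = noise_rng.standard_normal(nloc)
        if cfg.snp_h2 > 0 and g.std() > 0:
            return np.sqrt(cfg.snp_h2) * g / g.std() \
                + np.sqrt(1 - cfg.snp_h2) * eps
        return eps

    geno = _draw_genotypes(rng, cfg.n_individuals, mafs, blocks, cfg.ld_decay)
    y = phenotype(geno, rng)

    n_disc = cfg.discovery_n or cfg.n_individuals
    drng = _rng(cfg.seed, _STAGE_DISCOVERY)
    geno_d = _draw_genotypes(drng, n_disc, mafs, blocks, cfg.ld_decay)
    y_d = phenotype(geno_d, drng)
    sd = geno_d.std(axis=0)
    yd = (y_d - y_d.mean()) / y_d.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = ((geno_d - geno_d.mean(axis=0)) / np.where(sd == 0, 1.0, sd)).T @ yd / n_disc
    r[sd == 0] = 0.0

    snp_ids = np.array([f"snp{j:04d}" for j in range(m)], dtype=object)
    stats_set = SummaryStatisticsSet(
        snp_ids=snp_ids,
        effect_allele=np.array(["A"] * m, dtype=object),
        other_allele=np.array(["G"] * m, dtype=object),
        r=r,
        n_discovery=n_disc,
    )
    truth = SnpTruth(maf=mafs, beta_raw=beta_raw, causal_idx=causal,
                     blocks=blocks, h2=cfg.snp_h2, ld_decay=cfg.ld_decay)
    return SyntheticCohort(
        outcome=pd.Series(y, name="phenotype"),
        truth=truth,
        genotypes=pd.DataFrame(geno, columns=snp_ids),
        summary_stats=stats_set,
        ld_blocks=blocks,
    )


def as_ld_reference(cohort: SyntheticCohort) -> LDReference:
    """View a SNP-tier cohort's genotypes as an LD reference panel."""
    if cohort.genotypes is None or cohort.ld_blocks is None:
        raise ValueError("cohort has no genotype tier")
    return LDReference(
        genotypes=cohort.genotypes.to_numpy(),
        blocks=cohort.ld_blocks,
        snp_ids=cohort.genotypes.columns.to_numpy(dtype=object),
        effect_allele=np.array(["A"] * cohort.genotypes.shape[1], dtype=object),
        other_allele=np.array(["G"] * cohort.genotypes.shape[1], dtype=object),
    )
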