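import numpy as np
import pytest

import geinterplay as gi


@pytest.fixture(scope="session")
def score_cohort():
    """Mid-sized calibrated score-tier cohort shared across tests."""
    cfg = gi.calibrated_preset(seed=7, n_individuals=1500)
    return gi.simulate_score_cohort(cfg)


@pytest.fixture(scope="session")
def snp_cohort():
    cfg = gi.GeneratorConfig(
        n_individuals=500, n_snps=40, n_ld_blocks=4, snp_h2=0.4,
        discovery_n=8000, seed=11,
    )
    return gi.simulate_snp_cohort(cfg)


@pytest.fixture(scope="session")
def small_panel(score_cohort):
    return gi.panel_from_cohort(score_cohort, seed=3)


@pytest.fixture(scope="session")
def tiny_enet_config():
    return gi.ElasticNetConfig(alpha_grid=(0.5, 1.0), n_lambda=25, repeats=2,
                               k_folds=5, seed=0)


@pytest.fixture(scope="session")
def small_fits(small_panel, tiny_enet_config):
    return gi.fit_three_models(small_panel, tiny_enet_config)


def exact_correlation_data(R: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Columns with *sample* correlation matrix exactly R (population construction
    via orthonormalized noise, then Cholesky)."""
    rng = np.random.default_rng(seed)
    k = R.shape[0]
    Z = rng.standard_normal((n, k))
    Z -= Z.mean(axis=0)
    # orthonormalize so the empirical covariance is the identity
    q, _ = np.linalg.qr(Z)
    q -= q.mean(axis=0)
    q /= q.std(axis=0)
    # re-orthogonalize after centering drift
    c = np.linalg.cholesky(np.cov(q.T, bias=True))
    q = q @ np.linalg.inv(c).T
    L = np.linalg.cholesky(R)
    return q @ L.T
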