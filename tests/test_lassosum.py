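"""Summary-statistics penalized regression: closed forms, oracles, alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

import geinterplay as gi
from geinterplay._kernels import lassosum_cd
from geinterplay.errors import AlignmentError, ConfigError
from geinterplay.lassosum import _objective


def make_stats(r, n=10_000):
    m = len(r)
    return gi.SummaryStatisticsSet(
        snp_ids=np.array([f"s{i}" for i in range(m)], dtype=object),
        effect_allele=np.array(["A"] * m, dtype=object),
        other_allele=np.array(["G"] * m, dtype=object),
        r=np.asarray(r, dtype=float),
        n_discovery=n,
    )


def make_ref(m, n=120, rho=0.5, seed=0, blocks=None):
    rng = np.random.default_rng(seed)
    C = rho * np.ones((m, m)) + (1 - rho) * np.eye(m)
    X = rng.standard_normal((n, m)) @ np.linalg.cholesky(C).T
    return gi.LDReference(X, blocks or [(0, m)])


def brute_force_beta(R, r, lam, s, m):
    """Derivative-free minimizer of the blockwise objective via the positive/
    negative split (exact L1) and L-BFGS-B."""
    def obj(v):
        beta = v[:m] - v[m:]
        return (1 - s) * beta @ (R @ beta) - 2 * beta @ r + s * beta @ beta \
            + 2 * lam * v.sum()
    res = optimize.minimize(obj, np.zeros(2 * m), bounds=[(0, None)] * 2 * m,
                            method="L-BFGS-B",
                            options={"ftol": 1e-16, "gtol": 1e-12})
    return res.x[:m] - res.x[m:]


class TestFit:
    def test_unconstrained_case_returns_r(self):
        stats = make_stats([0.3, -0.2, 0.05])
        sol = gi.lassosum_fit(stats, make_ref(3), lam=0.0, s=1.0)
        np.testing.assert_allclose(sol.beta, stats.r)

    def test_s_one_is_soft_thresholding(self):
        stats = make_stats([0.5, 0.1])
        sol = gi.lassosum_fit(stats, make_ref(2), lam=0.2, s=1.0)
        np.testing.assert_allclose(sol.beta, [0.3, 0.0], atol=1e-12)

    @given(st.lists(st.floats(-0.9, 0.9), min_size=2, max_size=6),
           st.floats(0.0, 0.5))
    @settings(max_examples=25, deadline=None)
    def test_s_one_soft_threshold_property(self, r, lam):
        stats = make_stats(r)
        sol = gi.lassosum_fit(stats, make_ref(len(r)), lam=lam, s=1.0)
        expect = np.sign(r) * np.maximum(np.abs(r) - lam, 0.0)
        np.testing.assert_allclose(sol.beta, expect, atol=1e-10)

    @pytest.mark.parametrize("m,s,lam,seed", [
        (5, 0.5, 0.05, 0), (8, 0.2, 0.02, 1), (6, 0.8, 0.1, 2),
    ])
    def test_matches_brute_force_minimizer(self, m, s, lam, seed):
        rng = np.random.default_rng(seed)
        stats = make_stats(rng.uniform(-0.4, 0.4, m))
        ref = make_ref(m, seed=seed)
        sol = gi.lassosum_fit(stats, ref, lam=lam, s=s)
        Xs = ref.standardized()
        R = Xs.T @ Xs / Xs.shape[0]
        expect = brute_force_beta(R, stats.r, lam, s, m)
        np.testing.assert_allclose(sol.beta, expect, atol=1e-5)

    def test_blockwise_separability(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(-0.4, 0.4, 8)
        X = rng.standard_normal((100, 8))
        joint = gi.lassosum_fit(make_stats(r), gi.LDReference(X, [(0, 4), (4, 8)]),
                                lam=0.03, s=0.4)
        parts = []
        for lo, hi in ((0, 4), (4, 8)):
            sol = gi.lassosum_fit(make_stats(r[lo:hi]),
                                  gi.LDReference(X[:, lo:hi], [(0, 4)]),
                                  lam=0.03, s=0.4)
            parts.append(sol.beta)
        np.testing.assert_allclose(joint.beta, np.concatenate(parts), atol=1e-10)

    def test_objective_monotone_across_sweeps(self):
        rng = np.random.default_rng(5)
        m = 6
        r = rng.uniform(-0.4, 0.4, m)
        ref = make_ref(m, seed=5)
        Xs = ref.standardized()
        R = Xs.T @ Xs / Xs.shape[0]
        beta = np.zeros(m)
        objs = [_objective(R, r, beta, 0.02, 0.3)]
        for _ in range(20):
            lassosum_cd(R, r, 0.3, 0.02, beta, 0.0, 1)  # exactly one sweep
            objs.append(_objective(R, r, beta, 0.02, 0.3))
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    @pytest.mark.parametrize("bad", [{"s": -0.1}, {"s": 1.2}, {"lam": -1.0}])
    def test_invalid_parameters(self, bad):
        stats = make_stats([0.1, 0.2])
        with pytest.raises(ConfigError):
            gi.lassosum_fit(stats, make_ref(2), **{"lam": 0.1, "s": 0.5, **bad})

    def test_bad_block_partition_rejected(self):
        X = np.random.default_rng(0).standard_normal((50, 4))
        with pytest.raises(ConfigError):
            gi.LDReference(X, [(0, 2), (3, 4)])  # gap at index 2


class TestAlignment:
    def _ref(self):
        X = np.random.default_rng(0).standard_normal((60, 3))
        return gi.LDReference(
            X, [(0, 3)],
            snp_ids=np.array(["a", "b", "c"], dtype=object),
            effect_allele=np.array(["A", "C", "A"], dtype=object),
            other_allele=np.array(["G", "T", "C"], dtype=object),
        )

    def test_swapped_alleles_flip_sign(self):
        stats = gi.SummaryStatisticsSet(
            np.array(["a", "b"], dtype=object),
            np.array(["G", "C"], dtype=object),  # "a" swapped vs reference
            np.array(["A", "T"], dtype=object),
            np.array([0.2, 0.3]), 1000,
        )
        aligned, idx = gi.align_summary_stats(stats, self._ref())
        assert list(idx) == [0, 1]
        np.testing.assert_allclose(aligned.r, [-0.2, 0.3])

    def test_ambiguous_snp_dropped(self):
        stats = gi.SummaryStatisticsSet(
            np.array(["a", "c"], dtype=object),
            np.array(["A", "C"], dtype=object),
            np.array(["G", "G"], dtype=object),  # c is C/G ambiguous
            np.array([0.2, 0.3]), 1000,
        )
        aligned, idx = gi.align_summary_stats(stats, self._ref())
        assert list(aligned.snp_ids) == ["a"]

    def test_irreconcilable_alleles_raise(self):
        stats = gi.SummaryStatisticsSet(
            np.array(["b"], dtype=object), np.array(["A", ], dtype=object),
            np.array(["C"], dtype=object), np.array([0.2]), 1000,
        )
        with pytest.raises(AlignmentError):
            gi.align_summary_stats(stats, self._ref())


class TestScoring:
    def test_dot_product(self):
        sol = gi.LassosumSolution(beta=np.array([0.1, -0.2, 0.3]), lam=0, s=1,
                                  objective=0)
        np.testing.assert_allclose(
            gi.score_individuals(np.array([[0, 1, 2]]), sol), [0.4])

    def test_zero_beta_zero_scores(self):
        sol = gi.LassosumSolution(beta=np.zeros(3), lam=0, s=1, objective=0)
        geno = np.random.default_rng(0).integers(0, 3, (10, 3))
        assert (gi.score_individuals(geno, sol) == 0).all()

    def test_consistent_permutation_invariance(self):
        rng = np.random.default_rng(1)
        geno = rng.integers(0, 3, (15, 5)).astype(float)
        beta = rng.normal(size=5)
        sol = gi.LassosumSolution(beta=beta, lam=0, s=1, objective=0)
        perm = rng.permutation(5)
        sol_p = gi.LassosumSolution(beta=beta[perm], lam=0, s=1, objective=0)
        np.testing.assert_allclose(gi.score_individuals(geno, sol),
                                   gi.score_individuals(geno[:, perm], sol_p))

    def test_dimension_mismatch(self):
        sol = gi.LassosumSolution(beta=np.zeros(3), lam=0, s=1, objective=0)
        with pytest.raises(ValueError):
            gi.score_individuals(np.zeros((5, 4)), sol)


class TestTuning:
    def test_selected_r2_is_grid_maximum(self, snp_cohort):
        ref = gi.as_ld_reference(snp_cohort)
        res = gi.tune_gps(snp_cohort.summary_stats, ref, [0.005, 0.02, 0.08],
                          [0.5, 1.0], snp_cohort.genotypes.to_numpy(),
                          snp_cohort.outcome.to_numpy())
        assert res.best_r2 == pytest.approx(res.grid["r2"].max())

    def test_permuted_phenotype_gives_null_r2(self, snp_cohort):
        ref = gi.as_ld_reference(snp_cohort)
        r2s = []
        for seed in range(7):
            y = np.random.default_rng(seed).permutation(
                snp_cohort.outcome.to_numpy())
            res = gi.tune_gps(snp_cohort.summary_stats, ref, [0.01, 0.05],
                              [1.0], snp_cohort.genotypes.to_numpy(), y)
            r2s.append(res.best_r2)
        assert np.median(r2s) < 0.01

    def test_single_point_grid_returned(self, snp_cohort):
        ref = gi.as_ld_reference(snp_cohort)
        res = gi.tune_gps(snp_cohort.summary_stats, ref, [0.02], [0.8],
                          snp_cohort.genotypes.to_numpy(),
                          snp_cohort.outcome.to_numpy())
        assert (res.best.lam, res.best.s) == (0.02, 0.8)

    def test_all_zero_beta_grid_point_scores_zero(self, snp_cohort):
        ref = gi.as_ld_reference(snp_cohort)
        res = gi.tune_gps(snp_cohort.summary_stats, ref, [10.0], [1.0],
                          snp_cohort.genotypes.to_numpy(),
                          snp_cohort.outcome.to_numpy())
        assert res.best_r2 == 0.0

    def test_empty_grid_rejected(self, snp_cohort):
        with pytest.raises(ConfigError):
            gi.tune_gps(snp_cohort.summary_stats, gi.as_ld_reference(snp_cohort),
                        [], [1.0], snp_cohort.genotypes.to_numpy(),
                        snp_cohort.outcome.to_numpy())
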