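"""Polygenic score construction from GWAS summary statistics (lassosum).

Given per-SNP correlations ``r`` between genotype and phenotype from an external
discovery GWAS, and an LD reference panel partitioned into blocks, the method
minimizes

    y'y + (1 - s) b' X_ref' X_ref b - 2 b'r + s b'b + 2 * lam * ||b||_1

over SNP weights ``b``. ``lam`` controls the L1 (sparsity) penalty and
``s`` in [0, 1] mixes the reference LD matrix with the identity; at ``lam = 0,
s = 1`` the problem is unconstrained and ``b = r``. Because the LD matrix is
block diagonal, the problem separates over LD blocks and is solved blockwise by
coordinate descent. Tuning of ``(lam, s)`` maximizes the squared correlation of
the resulting scores with a tuning phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._kernels import lassosum_cd
from .errors import AlignmentError, ConfigError

# strand-ambiguous pairs that cannot be resolved between studies
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SummaryStatisticsSet:
    """Per-SNP discovery-GWAS correlations with the phenotype."""

    snp_ids: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    r: np.ndarray
    n_discovery: int

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.effect_allele = np.asarray(self.effect_allele, dtype=object)
        self.other_allele = np.asarray(self.other_allele, dtype=object)
        self.r = np.asarray(self.r, dtype=float)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ConfigError("duplicate SNP ids in summary statistics")
        if np.any(np.abs(self.r) > 1.0 + 1e-12):
            raise ConfigError("per-SNP correlations must satisfy |r| <= 1")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "a1": self.effect_allele,
                "a2": self.other_allele,
                "r": self.r,
                "n": self.n_discovery,
            }
        )


@dataclass
class LDReference:
    """Reference genotype panel with an ordered, non-overlapping block partition.

    ``blocks`` are half-open ``(start, stop)`` intervals over the SNP index that
    must cover every SNP exactly once.
    """

    genotypes: np.ndarray
    blocks: Sequence[tuple[int, int]]
    snp_ids: np.ndarray | None = None
    effect_allele: np.ndarray | None = None
    other_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        m = self.genotypes.shape[1]
        covered = np.zeros(m, dtype=int)
        prev_stop = 0
        for start, stop in self.blocks:
            if start != prev_stop or stop <= start:
                raise ConfigError(
                    "blocks must be ordered, non-overlapping and contiguous"
                )
            covered[start:stop] += 1
            prev_stop = stop
        if prev_stop != m or np.any(covered != 1):
            raise ConfigError("blocks must partition the SNP set exactly")

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def standardized(self) -> np.ndarray:
        """Column-standardized reference genotypes (reference panel's own moments)."""
        X = self.genotypes
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ConfigError("monomorphic SNP in reference panel (zero variance)")
        return (X - mu) / sd


@dataclass
class LassosumSolution:
    """A fitted set of SNP weights at one (lam, s) grid point."""

    beta: np.ndarray
    lam: float
    s: float
    objective: float  # objective value omitting the constant y'y term
    n_sweeps: int = 0
    snp_ids: np.ndarray | None = None


def align_summary_stats(
    stats: SummaryStatisticsSet, ref: LDReference
) -> tuple[SummaryStatisticsSet, np.ndarray]:
    """Align summary statistics to the reference panel's SNPs and alleles.

    Matching SNPs whose effect/other alleles are swapped get their correlation
    sign flipped; strand-ambiguous SNPs (A/T, C/G) are dropped. Returns the
    aligned statistics and the reference column indices retained.
    """
    if ref.snp_ids is None:
        raise AlignmentError("reference panel has no SNP metadata to align against")
    ref_index = {sid: j for j, sid in enumerate(ref.snp_ids)}
    keep_stats, keep_ref, signs = [], [], []
    for i, sid in enumerate(stats.snp_ids):
        j = ref_index.get(sid)
        if j is None:
            continue
        a1, a2 = stats.effect_allele[i], stats.other_allele[i]
        if (a1, a2) in _AMBIGUOUS:
            continue
        r1, r2 = ref.effect_allele[j], ref.other_allele[j]
        if (a1, a2) == (r1, r2):
            sign = 1.0
        elif (a1, a2) == (r2, r1):
            sign = -1.0
        elif (_COMPLEMENT.get(a1), _COMPLEMENT.get(a2)) == (r1, r2):
            sign = 1.0
        elif (_COMPLEMENT.get(a1), _COMPLEMENT.get(a2)) == (r2, r1):
            sign = -1.0
        else:
            raise AlignmentError(f"irreconcilable alleles for SNP {sid}")
        keep_stats.append(i)
        keep_ref.append(j)
        signs.append(sign)
    if not keep_stats:
        raise AlignmentError("no SNPs shared between statistics and reference")
    ks = np.asarray(keep_stats)
    aligned = SummaryStatisticsSet(
        snp_ids=stats.snp_ids[ks],
        effect_allele=stats.effect_allele[ks],
        other_allele=stats.other_allele[ks],
        r=stats.r[ks] * np.asarray(signs),
        n_discovery=stats.n_discovery,
    )
    return aligned, np.asarray(keep_ref)


def filter_snp_table(
    table: pd.DataFrame,
    maf_min: float = 0.005,
    hwe_p_min: float = 1e-5,
    info_exact: float | None = 1.0,
) -> pd.DataFrame:
    """Optional SNP-level quality filters on a metadata table.

    Drops SNPs with minor allele frequency below ``maf_min``, Hardy-Weinberg
    p-value below ``hwe_p_min`` and (if ``info_exact`` is given) imputation info
    different from that value. Columns absent from the table are ignored.
    """
    keep = pd.Series(True, index=table.index)
    if "maf" in table:
        maf = np.minimum(table["maf"], 1.0 - table["maf"])
        keep &= maf >= maf_min
    if "hwe_p" in table:
        keep &= table["hwe_p"] >= hwe_p_min
    if info_exact is not None and "info" in table:
        keep &= table["info"] == info_exact
    return table.loc[keep]


def _objective(R: np.ndarray, r: np.ndarray, beta: np.ndarray, lam: float, s: float) -> float:
    return float(
        (1.0 - s) * beta @ (R @ beta)
        - 2.0 * beta @ r
        + s * beta @ beta
        + 2.0 * lam * np.abs(beta).sum()
    )


def lassosum_fit(
    stats: SummaryStatisticsSet,
    ld: LDReference,
    lam: float,
    s: float,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
) -> LassosumSolution:
    """Fit SNP weights at one (lam, s) point, blockwise over the LD partition.

    Requires ``stats`` already aligned to the reference (same SNPs, same order);
    use :func:`align_summary_stats` first when working from raw tables.
    """
    if not 0.0 <= s <= 1.0:
        raise ConfigError(f"s must lie in [0, 1], got {s}")
    if lam < 0:
        raise ConfigError(f"lam must be non-negative, got {lam}")
    if len(stats) != ld.n_snps:
        raise AlignmentError(
            f"{len(stats)} summary SNPs vs {ld.n_snps} reference SNPs; align first"
        )
    r = stats.r
    beta = np.zeros(ld.n_snps)
    objective = 0.0
    sweeps = 0
    if s == 1.0:
        # LD term vanishes: coordinatewise soft-thresholding of r
        beta = np.sign(r) * np.maximum(np.abs(r) - lam, 0.0)
        for start, stop in ld.blocks:
            objective += _objective(np.eye(stop - start), r[start:stop],
                                    beta[start:stop], lam, s)
    else:
        X = ld.standardized()
        n_ref = X.shape[0]
        for start, stop in ld.blocks:
            Xb = X[:, start:stop]
            R = (Xb.T @ Xb) / n_ref
            b = np.zeros(stop - start)
            sweeps = max(sweeps, lassosum_cd(R, r[start:stop], s, lam, b, tol, max_sweeps))
            beta[start:stop] = b
            objective += _objective(R, r[start:stop], b, lam, s)
    return LassosumSolution(
        beta=beta, lam=lam, s=s, objective=objective, n_sweeps=sweeps,
        snp_ids=stats.snp_ids,
    )


def score_individuals(genotypes: np.ndarray, solution: LassosumSolution) -> np.ndarray:
    """Weighted allele-count sum per individual: score_i = sum_j g_ij * beta_j."""
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[1] != solution.beta.shape[0]:
        raise ValueError(
            f"genotype matrix has {G.shape[1] if G.ndim == 2 else '?'} SNPs, "
            f"weights have {solution.beta.shape[0]}"
        )
    return G @ solution.beta


@dataclass
class TuningResult:
    best: LassosumSolution
    best_r2: float
    grid: pd.DataFrame = field(repr=False)


def tune_gps(
    stats: SummaryStatisticsSet,
    ld: LDReference,
    lambda_grid: Sequence[float],
    s_grid: Sequence[float],
    tuning_genotypes: np.ndarray,
    tuning_phenotype: np.ndarray,
) -> TuningResult:
    """Choose (lam, s) maximizing squared correlation of scores with a phenotype.

    Grid points whose weights are all zero (constant scores) get R^2 = 0 rather
    than raising. The full R^2 grid is retained for reporting.
    """
    if len(lambda_grid) == 0 or len(s_grid) == 0:
        raise ConfigError("tuning grids must be non-empty")
    y = np.asarray(tuning_phenotype, dtype=float)
    rows = []
    best: LassosumSolution | None = None
    best_r2 = -1.0
    for s in s_grid:
        for lam in lambda_grid:
            sol = lassosum_fit(stats, ld, lam, s)
            scores = score_individuals(tuning_genotypes, sol)
            if np.std(scores) == 0 or np.std(y) == 0:
                r2 = 0.0
            else:
                r2 = float(np.corrcoef(scores, y)[0, 1] ** 2)
            rows.append({"lam": lam, "s": s, "r2": r2,
                         "n_nonzero": int(np.count_nonzero(sol.beta))})
            if r2 > best_r2:
                best, best_r2 = sol, r2
    assert best is not None
    return TuningResult(best=best, best_r2=best_r2, grid=pd.DataFrame(rows))


def default_lambda_grid() -> np.ndarray:
    """Log-spaced default L1 grid (the original grids are a free tuning choice)."""
    return np.geomspace(0.001, 0.1, 20)


def default_s_grid() -> np.ndarray:
    return np.array([0.2, 0.5, 0.9, 1.0])
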