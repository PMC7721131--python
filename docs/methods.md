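# Methods

`geinterplay` implements a multivariable gene–environment interplay analysis
for a continuous outcome (the motivating application is tested educational
achievement at 16): polygenic scores and measured environments are modeled
jointly in penalized regressions with hold-out evaluation, their overlap is
quantified as a gene–environment correlation (rGE) and a reciprocal mediation
decomposition, and two-way interactions are searched under strong hierarchy.
Because individual-level cohort data of this kind is access-restricted, the
package ships a calibrated synthetic-cohort generator; everything below is
testable end to end without any download.

## Polygenic scoring from summary statistics

`lassosum.lassosum_fit` minimizes, over SNP weights β,

    y'y + (1−s)·β' X_ref' X_ref β − 2 β'r + s·β'β + 2λ‖β‖₁,

where r holds the per-SNP phenotype–genotype correlations from an external
discovery GWAS and X_ref is a column-standardized reference panel whose
correlation matrix is block-diagonal over LD blocks. The problem separates by
block and is solved by cyclic coordinate descent (update
β_j ← soft(r_j − (1−s)(Rβ)_j + (1−s)R_jjβ_j, λ) / ((1−s)R_jj + s));
convergence is declared when the largest coefficient change in a sweep falls
below 1e-7 (max 10,000 sweeps), comfortably tighter than the 1e-5 oracle
tolerance used in the tests. At s = 1 the LD term vanishes and the solution is
the elementwise soft-threshold of r; at λ = 0, s = 1 it is r itself. Both
identities are exercised as tests, along with a derivative-free minimizer on
small blocks and blockwise-separability checks. The stored objective value
omits the constant y'y term, which is not recoverable from summary statistics.

Allele alignment between summary statistics and the reference flips the sign
of r when effect/other alleles are swapped (directly or via strand
complement) and drops strand-ambiguous A/T and C/G SNPs; this is the standard
convention. Scoring is the raw weighted allele-count sum. Tuning maximizes the
squared correlation of scores with a tuning phenotype over a (λ, s) grid; the
original study does not report its grids, so the defaults
(λ ∈ geomspace(0.001, 0.1, 20), s ∈ {0.2, 0.5, 0.9, 1.0}) are this package's
choice. Grid points with all-zero weights score R² = 0 rather than erroring.
Optional SNP metadata filters (MAF < 0.5%, HWE p < 1e-5, info ≠ 1) mirror the
usual pre-scoring hygiene and act only on supplied metadata tables.

## Variable preparation

* **SES composite** — row mean of five standardized parental
  education/employment/maternal-age measures.
* **Chaos score** — mean of six 3-point household-confusion items with items
  1, 4 and 6 reverse-coded as max+min−x.
* **Life events** — binary items; labeled, educationally contaminated items
  are removed first, then items endorsed by fewer than `endorsement_min`
  (default 100) respondents; "fewer than" is strict, so an item at exactly the
  minimum is kept.
* **Outcome transform** — rank-based inverse normal with the Blom offset:
  Φ⁻¹((rank − 3/8)/(n + 1/4)), average ranks for ties. The offset is this
  package's choice (the transform's name alone does not fix it); Blom is the
  common default.
* **Residualization** — every analysis variable (predictors and outcome) is
  regressed on age, sex, 10 genetic PCs and genotyping chip on the full
  sample; standardized residuals are used downstream. Standardization moments
  come from the training rows only and are applied to the hold-out rows — the
  leakage-safe choice for a step whose moment source is otherwise a free
  design decision. A column collinear with the covariates (zero residual
  variance) is a named error. Inputs with missing cells are rejected: the synthetic data are
  complete and real-data missingness policies are out of scope.
* **Split** — a seeded random 80/20 row partition.

## Penalized prediction models

`enet.enet_fit` minimizes (1/(2n))‖y − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²) by
cyclic coordinate descent on precomputed Gram moments, so a fit's cost is
independent of n after one X'X. The 1/(2n) scaling (rather than the unscaled
residual sum of squares) keeps λ comparable across sample sizes; it is a
monotone reparameterization of the same penalized problem. KKT subgradient
violations at convergence are checked to 1e-6 in the tests, alongside the
OLS limit at λ = 0, the orthonormal-design soft-threshold closed form, and a
numerical minimizer.

Tuning follows the study procedure: k-fold cross-validation (k = 10) repeated
(100 times at full scale) in the 80% training split, choosing the (α, λ) grid
point with the smallest mean RMSE; ties break toward larger λ, then larger α
(the sparser model). Fold standardization is refit inside each training fold.
The α grid default is {0.1, …, 1.0} and the λ path 100 log-spaced values from
λ_max down to 0.001·λ_max per α (grids are unstated in the study and are this
package's defaults). Note the RMSE-*minimum* rule is deliberately kept even
though it is known to over-select under a global null (the tests assert median
sparsity there, not emptiness). Hold-out performance is R² = 1 − SSE/SST with
SST around the hold-out mean. Variable importance is |standardized
coefficient| rescaled so the largest is 100, sign kept separately.

## Bootstrap model comparison

Hold-out rows are resampled with replacement (B = 1000), with the same row
indices applied to every model so that nested ΔR² distributions are paired;
fitted models are *not* refit — the resampling quantifies evaluation
uncertainty of fixed models on the hold-out set (an interpretive choice:
refitting per draw would answer a different question and would no longer be a
hold-out evaluation).
95% intervals are the 2.5th/97.5th percentiles, and a ΔR² is called
significant when its interval excludes zero. Resamples with zero outcome
variance are dropped with a count retained.

## Post-selection inference

For the active set of an L1 fit at fixed λ, three estimates of each partial
regression coefficient are provided: naive training-set OLS, hold-out OLS,
and conditional inference. The conditional route uses the polyhedral
characterization of the lasso selection event: conditioning on the active set
and coefficient signs, {y : Ay ≤ b} with rows from the sign and inactive-
subgradient KKT conditions. For the j-th selected predictor the target is the
OLS functional η'y on the active design; conditional on the selection event,
η'y follows a normal distribution truncated to an interval [a, b] obtained by
intersecting the polyhedron with the line through y along η. The elastic net
(α < 1) is reduced to this framework by absorbing its ridge term into the
active-set Gram matrix (the usual augmented-design identity) — an
approximation to however the original analysis handled α < 1, which is not
stated. σ² is estimated from the selected-model OLS residuals on the training
rows (also unstated in the source; this is the common default). Truncated-
normal tail probabilities are computed by scipy's truncnorm, which works on
the log scale for extreme bounds; confidence intervals invert the
truncated-normal pivot in its mean by bisection. An observed value sitting on
a truncation boundary yields a flagged estimate with an infinite interval
rather than a failure. Calibration is verified two ways: a rejection-sampling
Monte Carlo oracle on a one-predictor problem, and approximate uniformity of
conditional p-values across a global-null simulation where naive p-values are
demonstrably anti-conservative.

## rGE and mediation

The hold-out predictions of the G-only and E-only models (G_ea, E_ea) act as
genetic and environmental composites; their Pearson correlation is the rGE
estimate, with a paired percentile bootstrap interval. Mediation is the
saturated linear three-variable decomposition fitted as two/three OLS
regressions (exactly equivalent to a SEM in this saturated linear case):
total βC from y~x, βa from m~x, direct βC′ and βb from y~x+m, indirect
= βa·βb = βC − βC′ (an algebraic identity, asserted to 1e-10), proportion
mediated = (βC − βC′)/βC, undefined (None) when βC is numerically zero.
Bootstrap CIs refit all paths per resample — unlike the model-comparison
bootstrap, because here the paths themselves are the estimands. Both
orientations are reported: E_ea mediating G_ea→y (environmental mediation)
and G_ea mediating E_ea→y (genetic confounding); the two are statistically
equivalent decompositions with distinct readings.

## Interaction discovery under strong hierarchy

All p(p−1)/2 unordered pairs are candidates, labeled GxE/GxG/ExE from the
predictor roles. The search solves an overlapped group lasso in the
Lim–Hastie parameterization: singleton groups for pure main effects (weight
1) plus, for every candidate pair, a three-coefficient group holding both
mains and the product term (weight √3, the square-root-of-group-size
scaling). A product can only enter inside a group that carries its mains, so
strong hierarchy holds by construction; the reported "selected mains" are the
union of active singletons and members of active pair groups, making the
invariant directly assertable on every output. The objective is minimized by
monotone FISTA (a proximal-gradient step is accepted only if it does not
increase the objective; on rejection the momentum restarts), with the
Lipschitz constant bounded by p·λ_max(F'F/n). Because the overlapped latent
decomposition is not unique, convergence is judged on the objective alone.
Products are built from standardized mains and re-standardized before both
the group-lasso fit and the elastic-net refit, keeping coefficients
comparable.

λ is chosen by 10-fold CV (one repeat) along a 30-point descending path, with
the one-standard-error rule by default: once a pair group is open its product
weight is nonzero whenever the product's gradient exceeds λ, so the plain CV
minimum accumulates near-zero false-positive pairs on additive data; the 1-SE
rule is the standard sparsity-favoring remedy and keeps the additive null
mostly clean (the occasional surviving false positive has product weight
≲0.01 and is documented test behavior, matching the nonzero interaction
false-positive rates reported for this family of methods). Discovered GxE
pairs can be re-introduced into the elastic net (`refit_with_gxe`) and the
augmented model compared to G+E by the paired bootstrap.

## The synthetic cohort generator

Two tiers. The **SNP tier** draws genotypes per LD block from an AR(1) latent
haplotype model (two haplotypes thresholded at the per-SNP allele frequency,
MAF uniform in `maf_range`), assigns one causal SNP per block (configurable),
scales the genetic value to the target heritability, and computes summary
statistics on an *independent discovery replicate* of the same process —
mirroring the real two-sample design so that scoring tests cannot overfit by
construction.

The **score tier** rests on three standard-normal latents: a genetic
composite G, an environmental composite E with cor(G, E) = `rge`, and an
environment-specific factor Sp (the pooled unique parts of the continuous
environmental composites, orthogonal to G and E). The outcome is
y = aG + bE + cSp (+ optional GxE product terms) + ε with var(y) normalized
to 1. Observed predictors are indicators: 20 GPS loading κ = 0.85 on G, two
continuous environments loading λ = 0.9 on E, and 11 binary life events
thresholded from latent normals loading λ on E (endorsement rates default to
linspace(0.10, 0.45)). Within-set indicator correlations are exchangeable
(κ², λ²) — the source reports no correlation matrices, so this structure is a
documented free choice. The loadings are set high enough that the observed
models can attain the calibration targets below; with weaker indicators
(especially the thresholded binaries, which lose the most information) those
targets become infeasible and the generator says so.

**Calibration.** The generator computes the exact population covariance of
all observed predictors and the outcome — thresholded-indicator covariances
use φ(t) factors and bivariate-normal orthant probabilities — and solves
(a, b, c) so that the *population R² of the best linear predictor* from the
GPS set, the environment set, and their union equal `target_r2` exactly, with
cor(G, E) pinned at `rge`. Three R² targets plus rge need three path degrees
of freedom; the environment-specific path supplies the third (a two-path
model is overdetermined: the calibration targets G .18 / E .30 / G+E .36
would force cor(G,E) ≈ 0.36 ≠ 0.38). When the "G+E" target is absent, either
`prop_g_mediated` (= bρ/(a+bρ)) or `prop_e_confounded` (= aρ/(aρ+b)) may
serve as the third constraint instead; supplying more than one is an
over-determination error, and configurations whose implied variance
decomposition exceeds 1 (or whose targets are unattainable at the given
loadings) raise a feasibility error naming the violation. The solve is a
seeded multi-start Newton iteration with analytic Jacobian, accepted only at
residuals < 1e-10, so the truth record reproduces the targets to far better
than 1e-6. GxE product terms are added on top of the additive calibration
(they are uncorrelated with the linear terms up to thresholding third
moments); the recorded R² refer to the additive component.

The truth record carries the paths, loadings, thresholds and covariance
blocks, and can analytically produce: per-model population R², the population
correlation and covariance of the model-based composites (used as ground
truth for rGE and mediation recovery tests, and to draw composite triples
directly at any n), and the latent mediation fractions. Covariates (age, sex,
10 exactly orthogonalized PC-like columns, chip) are mixed into predictors
and outcome with small weights (scale 0.05) so residualization is
consequential; for continuous columns residualization removes this exactly in
population, for thresholded binaries the distortion is O(effect²) and the
Monte-Carlo calibration checks therefore run with the mixing disabled.
Determinism: every output is a pure function of (config, seed); stage streams
are derived from the master seed through fixed offsets (score tier 11,
covariates 23, SNP tier 37, discovery replicate 41).

**What the generator does not emulate** — and hence what passing tests do not
show about real data: realistic human LD and allele-frequency spectra,
ancestry structure, family/twin relatedness, missing data, non-Gaussian
outcome tails (the pipeline rank-normalizes anyway), non-exchangeable
indicator correlation structure, and any causal distinction between the two
mediation orientations. Parameter-recovery results on this generator say the
estimators are consistent and calibrated under the assumed structure, not
that the substantive conclusions transfer to any cohort.

## Problem sizes and defaults used in checks

The full-scale configuration (n = 7,026, 20 GPS + 13 environments,
rge = 0.38, targets G .18 / E .30 / G+E .36, 10×100 repeated CV, B = 1000) is
what `scripts/acceptance.py` runs once end to end. The repeated simulation
studies in the test suite use reduced designs chosen to keep the whole suite
in the tens of minutes on one core: 5 CV repeats and a 2-point α grid for the
100-run R²-ordering study, B = 200 bootstrap draws and n = 1,405 composite
draws for the recovery studies, 500 replicates at n = 200, p = 10 for the
selective-inference calibration, and n = 2,000 for planted-interaction
recovery. These sizes are the package's own test design; the statistical
thresholds they feed are stated in each test.

## Known limitations

* The lassosum reference panel is used as given; cross-chromosome LD and
  pseudovalidation (tuning without a phenotype) are not implemented.
* Selective inference conditions on the active set and signs at one fixed λ;
  data carving, multi-λ conditioning and FDR-controlling selective procedures
  are out of scope.
* The hierarchical search handles continuous/standardized-binary predictors
  only; categorical-variable machinery (one-hot group structures) is not
  implemented because the pipeline's panel is fully residualized/continuous.
* Mediation here is a variance decomposition on predicted composites;
  nothing in the package identifies causal effects, and the genetic-
  confounding orientation in particular is a statistical abstraction.
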