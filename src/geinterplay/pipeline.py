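"""End-to-end orchestration of the gene-environment interplay analysis.

Typical flow: simulate (or load) a cohort, build the analysis panel, fit the
E / G / G+E elastic-net models, compare their hold-out accuracy by paired
bootstrap, estimate post-selection coefficients, quantify rGE and reciprocal
mediation from the model-based composites, and search for two-way interactions
under strong hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bootstrap import ComparisonReport, bootstrap_r2
from .enet import ElasticNetConfig, ModelFit, evaluate_holdout, fit_model
from .interactions import HierarchicalSelection, fit_hierarchical, refit_with_gxe
from .mediation import CompositePair, MediationResult, RgeResult, \
    rge_correlation, run_both_orientations
from .preprocess import PredictorPanel, build_panel
from .synthetic import SyntheticCohort

MODEL_ROLES = {"G": ("gps",), "E": ("environment",), "G+E": ("gps", "environment")}


def panel_from_cohort(
    cohort: SyntheticCohort,
    split_fraction: float = 0.8,
    seed: int = 0,
    transform_outcome: bool = True,
) -> PredictorPanel:
    """Residualize, standardize and split a score-tier cohort."""
    if cohort.predictors is None or cohort.covariates is None:
        raise ValueError("cohort has no score tier")
    return build_panel(
        predictors=cohort.predictors,
        roles=cohort.roles,
        outcome=cohort.outcome,
        covariates=cohort.covariates,
        split_fraction=split_fraction,
        seed=seed,
        transform_outcome=transform_outcome,
    )


def fit_three_models(
    panel: PredictorPanel, config: ElasticNetConfig
) -> dict[str, ModelFit]:
    """Fit and hold-out-evaluate the E, G and joint G+E models."""
    y_tr = panel.outcome_vector(train=True)
    y_ho = panel.outcome_vector(train=False)
    fits = {}
    for name, roles in MODEL_ROLES.items():
        cols = panel.columns(roles)
        fit = fit_model(name, panel.matrix(roles, train=True), y_tr, cols, config)
        evaluate_holdout(fit, panel.matrix(roles, train=False), y_ho)
        fits[name] = fit
    return fits


def compare_models(
    fits: dict[str, ModelFit],
    panel: PredictorPanel,
    B: int = 1000,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
) -> ComparisonReport:
    X_ho = {name: panel.matrix(MODEL_ROLES[name], train=False) for name in fits
            if name in MODEL_ROLES}
    for name in fits:
        if name not in X_ho:  # augmented models carry their own design
            raise ValueError(f"no hold-out design known for model {name!r}")
    if pairs is None:
        pairs = [("G+E", "E"), ("G+E", "G")]
    return bootstrap_r2(fits, X_ho, panel.outcome_vector(train=False),
                        B=B, seed=seed, pairs=pairs)


def composites_from_fits(fits: dict[str, ModelFit],
                         panel: PredictorPanel) -> CompositePair:
    """Hold-out G-model and E-model predictions plus the hold-out outcome."""
    return CompositePair(
        g_ea=fits["G"].predict(panel.matrix(("gps",), train=False)),
        e_ea=fits["E"].predict(panel.matrix(("environment",), train=False)),
        outcome=panel.outcome_vector(train=False),
    )


@dataclass
class InterplayResult:
    """Everything the full pipeline computes on one cohort."""

    panel: PredictorPanel
    fits: dict[str, ModelFit]
    comparison: ComparisonReport
    rge: RgeResult
    mediation: dict[str, MediationResult]
    selection: HierarchicalSelection | None = None
    gxe_fit: ModelFit | None = None
    gxe_delta: object = None
    notes: dict = field(default_factory=dict)


def run_full_analysis(
    cohort: SyntheticCohort,
    enet_config: ElasticNetConfig | None = None,
    B: int = 1000,
    seed: int = 0,
    split_fraction: float = 0.8,
    discover_interactions: bool = True,
    interaction_lambdas: int = 30,
) -> InterplayResult:
    """Run the whole analysis on a score-tier cohort."""
    config = enet_config or ElasticNetConfig(seed=seed)
    panel = panel_from_cohort(cohort, split_fraction=split_fraction, seed=seed)
    fits = fit_three_models(panel, config)
    comparison = compare_models(fits, panel, B=B, seed=seed)
    pair = composites_from_fits(fits, panel)
    rge = rge_correlation(pair, B=B, seed=seed)
    mediation = run_both_orientations(pair, B=B, seed=seed)

    selection = None
    gxe_fit = None
    gxe_delta = None
    if discover_interactions:
        cols = panel.columns(("gps", "environment"))
        roles = [panel.roles[c] for c in cols]
        selection = fit_hierarchical(
            panel.matrix(("gps", "environment"), train=True),
            panel.outcome_vector(train=True),
            roles=roles, n_lambda=interaction_lambdas, seed=seed,
        )
        gxe_names = [(cols[i], cols[j]) for i, j in selection.gxe_pairs()]
        if gxe_names:
            gxe_fit = refit_with_gxe(panel, gxe_names, config)
            # paired bootstrap of the augmented model against G+E
            from .bootstrap import _resample_r2, percentile_ci, significance_flag
            y_ho = panel.outcome_vector(train=False)
            rng = np.random.default_rng(seed)
            idx = rng.integers(0, len(y_ho), size=(B, len(y_ho)))
            base_pred = fits["G+E"].predict(
                panel.matrix(("gps", "environment"), train=False))
            cols_aug = list(gxe_fit.beta.index)
            X_aug = _augmented_holdout(panel, gxe_names)
            aug_pred = gxe_fit.predict(X_aug)
            d = _resample_r2(y_ho, aug_pred, idx) - _resample_r2(y_ho, base_pred, idx)
            ok = d[~np.isnan(d)]
            gxe_delta = {
                "median": float(np.median(ok)),
                "ci": percentile_ci(ok),
                "significant": significance_flag(ok),
            }
    return InterplayResult(
        panel=panel, fits=fits, comparison=comparison, rge=rge,
        mediation=mediation, selection=selection, gxe_fit=gxe_fit,
        gxe_delta=gxe_delta,
    )


def _augmented_holdout(panel: PredictorPanel,
                       gxe_names: list[tuple[str, str]]) -> np.ndarray:
    cols = panel.columns(("gps", "environment"))
    base = panel.data[cols]
    parts = [base.to_numpy(dtype=float)[~panel.train_mask]]
    for a, b in gxe_names:
        prod = base[a].to_numpy() * base[b].to_numpy()
        mu = prod[panel.train_mask].mean()
        sd = prod[panel.train_mask].std()
        parts.append(((prod - mu) / (sd if sd else 1.0))[~panel.train_mask, None])
    return np.column_stack(parts)
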