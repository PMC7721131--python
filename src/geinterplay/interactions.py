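"""Two-way interaction discovery under strong hierarchy.

All p(p-1)/2 unordered predictor pairs are candidates. A hierarchical group
lasso in the Lim-Hastie parameterization searches them jointly: each candidate
pair contributes a three-coefficient group holding both member main effects
and the product term, alongside singleton groups for pure main effects, so a
product can enter the model only inside a group that also carries its two main
effects — strong hierarchy by construction. The overlapped group-lasso
objective

    (1/2n) ||y - sum_g Z_g theta_g||^2 + lam * sum_g w_g ||theta_g||_2

is minimized by monotone proximal-gradient descent (FISTA with a
non-increase safeguard) along a decreasing lambda path, with lambda chosen by
k-fold cross-validation. Pair groups are penalized with weight sqrt(3) (the
square root of the group size) so mains-only and pair groups are comparably
penalized. Discovered gene-environment pairs can then be re-introduced into
the elastic net to test whether hold-out prediction improves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._kernels import group_fista
from .enet import ElasticNetConfig, ModelFit, evaluate_holdout, fit_model
from .errors import ConfigError
from .preprocess import PredictorPanel

_PAIR_WEIGHT = np.sqrt(3.0)


@dataclass
class InteractionCandidateSet:
    """All unordered predictor pairs with role-derived class labels."""

    roles: list[str]
    pairs: list[tuple[int, int]]
    classes: list[str]

    @property
    def n_candidates(self) -> int:
        return len(self.pairs)


def _pair_class(role_i: str, role_j: str) -> str:
    kinds = {role_i, role_j}
    if kinds == {"gps", "environment"}:
        return "GxE"
    if kinds == {"gps"}:
        return "GxG"
    return "ExE"


def build_candidates(roles: Sequence[str]) -> InteractionCandidateSet:
    """Enumerate the p(p-1)/2 candidate pairs for p role-labeled predictors."""
    roles = list(roles)
    p = len(roles)
    if p < 2:
        raise ConfigError("need at least 2 predictors to form pairs")
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    classes = [_pair_class(roles[i], roles[j]) for i, j in pairs]
    return InteractionCandidateSet(roles=roles, pairs=pairs, classes=classes)


@dataclass
class SelectedPair:
    i: int
    j: int
    weight: float  # product-term coefficient at the chosen lambda
    klass: str


@dataclass
class HierarchicalSelection:
    """Output of the hierarchical group-lasso search."""

    main_effects: dict[int, float]
    pairs: list[SelectedPair]
    lam: float
    lambda_path: np.ndarray = field(repr=False)
    cv_mse: pd.DataFrame = field(repr=False)
    roles: list[str] = field(default_factory=list)

    @property
    def selected_mains(self) -> set[int]:
        return set(self.main_effects)

    def satisfies_strong_hierarchy(self) -> bool:
        mains = self.selected_mains
        return all(p.i in mains and p.j in mains for p in self.pairs)

    def gxe_pairs(self) -> list[tuple[int, int]]:
        return [(p.i, p.j) for p in self.pairs if p.klass == "GxE"]


def _latent_layout(p: int, pairs: list[tuple[int, int]]):
    """Latent-to-feature map for the overlapped parameterization.

    Features: [p mains, q products]. Latent coordinates: p singleton mains,
    then (main_i, main_j, product) triplets per pair.
    """
    q = len(pairs)
    feat = np.empty(p + 3 * q, dtype=np.int64)
    feat[:p] = np.arange(p)
    group_start = np.empty(p + q, dtype=np.int64)
    group_len = np.empty(p + q, dtype=np.int64)
    weights = np.empty(p + q)
    group_start[:p] = np.arange(p)
    group_len[:p] = 1
    weights[:p] = 1.0
    for k, (i, j) in enumerate(pairs):
        s = p + 3 * k
        feat[s:s + 3] = (i, j, p + k)
        group_start[p + k] = s
        group_len[p + k] = 3
        weights[p + k] = _PAIR_WEIGHT
    return feat, group_start, group_len, weights


def _feature_matrix(X: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    Xs = (X - X.mean(0)) / X.std(0)
    prods = np.empty((X.shape[0], len(pairs)))
    for k, (i, j) in enumerate(pairs):
        prods[:, k] = Xs[:, i] * Xs[:, j]
    mu = prods.mean(0)
    sd = prods.std(0)
    sd[sd == 0] = 1.0
    return np.column_stack([Xs, (prods - mu) / sd])


def _power_lambda_max(Gf: np.ndarray, iters: int = 60) -> float:
    v = np.ones(Gf.shape[0]) / np.sqrt(Gf.shape[0])
    for _ in range(iters):
        w = Gf @ v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return 1.0
        v = w / nrm
    return float(v @ Gf @ v)


def _group_norms(vec: np.ndarray, group_start, group_len) -> np.ndarray:
    return np.array([
        np.linalg.norm(vec[s:s + l]) for s, l in zip(group_start, group_len)
    ])


def _fit_path(Gf, fty, lams, feat, group_start, group_len, weights, L,
              tol, max_iter):
    D = feat.shape[0]
    coefs = np.zeros((len(lams), D))
    coef = np.zeros(D)
    for k, lam in enumerate(lams):
        group_fista(Gf, fty, float(lam), feat, group_start, group_len,
                    weights, L, coef, tol, max_iter)
        coefs[k] = coef
    return coefs


def _to_features(coef: np.ndarray, feat: np.ndarray, n_feat: int) -> np.ndarray:
    f = np.zeros(n_feat)
    np.add.at(f, feat, coef)
    return f


def fit_hierarchical(
    X: np.ndarray,
    y: np.ndarray,
    roles: Sequence[str] | None = None,
    lambda_path_values: np.ndarray | None = None,
    n_lambda: int = 30,
    lambda_min_ratio: float = 0.01,
    cv_folds: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
    lambda_rule: str = "1se",
) -> HierarchicalSelection:
    """Hierarchical group-lasso search over all pairs, lambda by k-fold CV.

    ``lambda_rule`` "1se" (default) picks the largest lambda whose CV error is
    within one standard error of the minimum — the standard sparsity-favoring
    choice, which keeps the null case (no true interactions) clean; "min"
    picks the CV-error minimum. Returns the selection at the chosen lambda; an
    empty selection (the path never picks anything) is a valid result, not an
    error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ConfigError("non-finite values in the design or outcome")
    n, p = X.shape
    roles = list(roles) if roles is not None else ["gps"] * p
    cand = build_candidates(roles)
    feat, group_start, group_len, weights = _latent_layout(p, cand.pairs)

    F = _feature_matrix(X, cand.pairs)
    yc = y - y.mean()
    n_feat = F.shape[1]
    Gf_all = F.T @ F / n
    fty_all = F.T @ yc / n

    grad0 = _group_norms(-fty_all[feat], group_start, group_len) / weights
    lam_max = float(grad0.max())
    if lambda_path_values is None:
        lams = np.geomspace(lam_max * 1.0001, lam_max * lambda_min_ratio, n_lambda)
    else:
        lams = np.sort(np.asarray(lambda_path_values, dtype=float))[::-1]

    if lambda_rule not in ("min", "1se"):
        raise ConfigError(f"unknown lambda_rule {lambda_rule!r}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % cv_folds
    fold_mse = np.zeros((cv_folds, len(lams)))
    for f in range(cv_folds):
        val = folds == f
        Ft, yt = F[~val], yc[~val]
        Gf = Ft.T @ Ft / len(yt)
        fty = Ft.T @ (yt - yt.mean()) / len(yt)
        L = _power_lambda_max(Gf) * p * 1.05 + 1e-12
        coefs = _fit_path(Gf, fty, lams, feat, group_start, group_len,
                          weights, L, tol, max_iter)
        fc = np.zeros((len(lams), n_feat))
        for k in range(len(lams)):
            fc[k] = _to_features(coefs[k], feat, n_feat)
        pred = yt.mean() + F[val] @ fc.T
        fold_mse[f] = ((pred - yc[val][:, None]) ** 2).mean(axis=0)
    mse = fold_mse.mean(axis=0)
    k_min = int(np.argmin(mse))
    if lambda_rule == "min":
        best_k = k_min
    else:
        se = fold_mse.std(axis=0, ddof=1) / np.sqrt(cv_folds)
        within = np.flatnonzero(mse <= mse[k_min] + se[k_min])
        best_k = int(within[0])  # path is descending: first index = largest lam

    L = _power_lambda_max(Gf_all) * p * 1.05 + 1e-12
    coefs = _fit_path(Gf_all, fty_all, lams[: best_k + 1], feat, group_start,
                      group_len, weights, L, tol, max_iter)
    coef = coefs[-1]
    fcoef = _to_features(coef, feat, n_feat)

    sel_pairs = []
    pair_members = set()
    norms = _group_norms(coef, group_start, group_len)
    for k, (i, j) in enumerate(cand.pairs):
        if norms[p + k] > 0:
            sel_pairs.append(SelectedPair(
                i=i, j=j, weight=float(fcoef[p + k]), klass=cand.classes[k]))
            pair_members.update((i, j))
    mains = {
        j: float(fcoef[j])
        for j in range(p)
        if norms[j] > 0 or j in pair_members
    }
    return HierarchicalSelection(
        main_effects=mains, pairs=sel_pairs, lam=float(lams[best_k]),
        lambda_path=lams,
        cv_mse=pd.DataFrame({"lam": lams, "mse": mse}),
        roles=roles,
    )


def selection_to_dot(selection: HierarchicalSelection,
                     names: Sequence[str]) -> str:
    """Render the selected interaction network as a Graphviz DOT string.

    Nodes are the selected main effects; edges the selected pairs, labeled by
    class with the product weight as edge weight.
    """
    lines = ["graph interactions {"]
    for j in sorted(selection.selected_mains):
        shape = "box" if selection.roles and selection.roles[j] == "gps" else "ellipse"
        lines.append(f'  "{names[j]}" [shape={shape}];')
    for q in selection.pairs:
        lines.append(
            f'  "{names[q.i]}" -- "{names[q.j]}" '
            f'[label="{q.klass}", weight="{q.weight:.3f}"];'
        )
    lines.append("}")
    return "\n".join(lines)


def refit_with_gxe(
    panel: PredictorPanel,
    gxe_pairs: list[tuple[str, str]],
    config: ElasticNetConfig,
    name: str = "G+E+GxE",
) -> ModelFit:
    """Augment the panel with product terms for the given GPS-environment
    pairs, refit the elastic net and evaluate hold-out R^2.

    Products are built from the (already standardized) member columns and
    re-standardized on the training rows so coefficients stay comparable.
    """
    cols = panel.columns(("gps", "environment"))
    for a, b in gxe_pairs:
        if a not in cols or b not in cols:
            raise ConfigError(f"pair ({a}, {b}) references predictors not in the panel")
        kinds = {panel.roles[a], panel.roles[b]}
        if kinds != {"gps", "environment"}:
            raise ConfigError(f"pair ({a}, {b}) is not a GPS x environment pair")
    base = panel.data[cols]
    frames = [base]
    names = list(cols)
    for a, b in gxe_pairs:
        prod = base[a].to_numpy() * base[b].to_numpy()
        mu = prod[panel.train_mask].mean()
        sd = prod[panel.train_mask].std()
        frames.append(pd.DataFrame({f"{a}*{b}": (prod - mu) / (sd if sd else 1.0)}))
        names.append(f"{a}*{b}")
    Xfull = pd.concat(frames, axis=1).to_numpy(dtype=float)
    y = panel.outcome_vector()
    fit = fit_model(name, Xfull[panel.train_mask], y[panel.train_mask], names, config)
    evaluate_holdout(fit, Xfull[~panel.train_mask], y[~panel.train_mask])
    return fit
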