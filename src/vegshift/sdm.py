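"""Maximum-entropy-style species distribution model (presence/background).

The habitat-suitability model is an L1-penalized log-linear discriminator of
presence cells against randomly sampled background cells — the standard
logistic-regression formulation of the maximum-entropy (Maxent) SDM family.
The workflow mirrors common SDM practice:

1. predictor pre-selection by a pairwise Pearson correlation filter
   (:func:`select_variables`, default threshold |r| < 0.8);
2. replicated fitting with random presence train/test splits and ROC AUC
   evaluation on the held-out presences (:func:`fit`);
3. per-variable percent contributions from coefficient magnitude scaled by
   feature spread (:func:`contributions`), normalized to sum to 100;
4. projection of a fitted model onto another co-registered scenario stack —
   e.g. a model trained under Last Glacial Maximum climate projected to
   current climate (:func:`project`).  Features are always rebuilt with the
   *training* standardization so the projection is an extrapolation of the
   fitted response, not a refit.

Feature classes are linear and quadratic terms of the z-scored predictors by
default, with optional hinge features (10 knots per variable at training-data
deciles).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .grid_io import Grid, GridStack, OccurrenceSet

__all__ = [
    "SdmConfig",
    "SuitabilityResult",
    "select_variables",
    "fit",
    "auc",
    "contributions",
    "project",
]

logger = logging.getLogger(__name__)

VALID_FEATURE_CLASSES = ("linear", "quadratic", "hinge")
N_HINGE_KNOTS = 10


@dataclass(frozen=True)
class SdmConfig:
    """Configuration of the presence/background model.

    Defaults follow the study protocol: predictors kept at pairwise
    |r| < 0.8, 10 replicates with 10% of presences held out as test data,
    optimizer capped at 10,000 iterations, models gated at AUC >= 0.75,
    10,000 background cells.
    """

    correlation_threshold: float = 0.8
    n_background: int = 10_000
    n_replicates: int = 10
    test_fraction: float = 0.10
    max_iterations: int = 10_000
    auc_gate: float = 0.75
    feature_classes: tuple[str, ...] = ("linear", "quadratic")
    l1_penalty: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.l1_penalty < 0:
            raise ValueError("l1_penalty must be >= 0")
        unknown = set(self.feature_classes) - set(VALID_FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes {sorted(unknown)}")


@dataclass
class FeatureMap:
    """Frozen training-time featurization: per-variable z-scoring statistics
    and hinge knots.  Reused verbatim when projecting to another scenario."""

    variables: tuple[str, ...]
    means: dict[str, float]
    sds: dict[str, float]
    feature_classes: tuple[str, ...]
    knots: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        for v in self.variables:
            if "linear" in self.feature_classes:
                names.append(f"{v}:linear")
            if "quadratic" in self.feature_classes:
                names.append(f"{v}:quadratic")
            if "hinge" in self.feature_classes:
                names.extend(f"{v}:hinge{k}" for k in range(len(self.knots[v])))
        return names

    def build(self, layer_values: Mapping[str, np.ndarray]) -> np.ndarray:
        """Design matrix (n, p) from per-variable raw value vectors."""
        cols: list[np.ndarray] = []
        for v in self.variables:
            z = (np.asarray(layer_values[v], dtype=float) - self.means[v]) / self.sds[v]
            if "linear" in self.feature_classes:
                cols.append(z)
            if "quadratic" in self.feature_classes:
                cols.append(z**2)
            if "hinge" in self.feature_classes:
                for knot in self.knots[v]:
                    cols.append(np.maximum(0.0, z - knot))
        return np.column_stack(cols)

    def variable_of(self, feature_name: str) -> str:
        return feature_name.rsplit(":", 1)[0]


@dataclass
class SuitabilityResult:
    """A fitted SDM: coefficients, replicate AUCs, contributions and the
    suitability surface of the best replicate."""

    coefficients: dict[str, float]
    intercept: float
    replicate_aucs: list[float]
    mean_auc: float
    best_replicate: int
    contributions: dict[str, float]
    suitability: Grid
    selected_variables: list[str]
    feature_map: FeatureMap
    feature_sds: dict[str, float]
    config: SdmConfig
    converged: bool = True

    @property
    def passes_gate(self) -> bool:
        return self.mean_auc >= self.config.auc_gate


# ---------------------------------------------------------------------------
# predictor pre-selection


def select_variables(stack: GridStack, cfg: SdmConfig | None = None) -> list[str]:
    """Greedy collinearity filter on pairwise Pearson correlation.

    Correlations are computed over the cells valid in every layer.  While any
    pair violates |r| < threshold, the variable with the most violating
    partners is dropped (ties broken by larger mean |r| with the remaining
    variables, then by lexicographically smallest name).  The returned list
    preserves the stack's layer order.
    """
    cfg = cfg or SdmConfig()
    names = stack.names
    if len(names) < 2:
        raise ValueError("need at least 2 layers for variable selection")
    mask = stack.common_mask()
    if mask.sum() < 3:
        raise ValueError("fewer than 3 cells valid across all layers")
    data = np.column_stack([stack.layers[n].values[mask] for n in names])
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(data, rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)  # constant layers correlate with nothing
    np.fill_diagonal(corr, 0.0)

    keep = list(range(len(names)))
    while True:
        sub = corr[np.ix_(keep, keep)]
        viol = sub >= cfg.correlation_threshold
        counts = viol.sum(axis=1)
        if counts.max() == 0:
            break
        worst = counts.max()
        tied = [i for i, c in enumerate(counts) if c == worst]
        if len(tied) > 1:
            mean_r = sub.mean(axis=1)
            best_mean = max(mean_r[i] for i in tied)
            tied = [i for i in tied if mean_r[i] == best_mean]
        drop_local = min(tied, key=lambda i: names[keep[i]])
        keep.pop(drop_local)
        if len(keep) == 1:
            break
    return [names[i] for i in keep]


# ---------------------------------------------------------------------------
# ROC AUC


def auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """ROC AUC as the Mann–Whitney probability P(pos > neg) + 0.5 P(pos = neg)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# fitting


def _fit_one(
    X: np.ndarray, y: np.ndarray, cfg: SdmConfig
) -> tuple[LogisticRegression, bool]:
    C = 1.0 / cfg.l1_penalty if cfg.l1_penalty > 0 else 1e6
    model = LogisticRegression(
        penalty="l1",
        C=C,
        solver="liblinear",
        max_iter=cfg.max_iterations,
        random_state=0,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            logger.warning(
                "optimizer hit the %d-iteration cap without converging", cfg.max_iterations
            )
    return model, converged


def fit(
    occ: OccurrenceSet,
    stack: GridStack,
    cfg: SdmConfig,
    variables: Sequence[str] | None = None,
) -> SuitabilityResult:
    """Fit the presence/background model with replicated test-split evaluation.

    Background cells are sampled uniformly at random (seeded) from the
    non-nodata cells of the stack, excluding presence cells.  Each replicate
    holds out ``test_fraction`` of the presences, fits on the rest plus the
    background, and records the ROC AUC of held-out presences against the
    background sample.  The reported suitability surface comes from the
    replicate with the highest test AUC (ties to the lowest index), via the
    logistic link.
    """
    if len(occ) == 0:
        raise ValueError("occurrence set is empty")
    variables = list(variables) if variables is not None else select_variables(stack, cfg)
    missing = [v for v in variables if v not in stack.layers]
    if missing:
        raise ValueError(f"stack lacks selected variables {missing}")

    mask = stack.common_mask(variables)
    occ = occ.clip_to(stack.layers[variables[0]].like(np.where(mask, 1.0, np.nan), nodata=np.nan))
    n_pres = len(occ)
    if n_pres < 2 * cfg.n_replicates:
        raise ValueError(
            f"insufficient data: {n_pres} presences for {cfg.n_replicates} replicates"
        )

    rng = np.random.default_rng(cfg.seed)
    x, y = occ.xy
    prow, pcol = stack.transform.point_to_cell(x, y, stack.shape)[:2]
    pres_flat = np.unique(prow * stack.shape[1] + pcol)

    valid_flat = np.flatnonzero(mask.ravel())
    bg_pool = np.setdiff1d(valid_flat, pres_flat, assume_unique=False)
    if bg_pool.size == 0:
        raise ValueError("no background cells available")
    n_bg = min(cfg.n_background, bg_pool.size)
    bg_flat = rng.choice(bg_pool, size=n_bg, replace=False)

    def cell_values(flat_idx: np.ndarray) -> dict[str, np.ndarray]:
        r, c = np.unravel_index(flat_idx, stack.shape)
        return {v: stack.layers[v].values[r, c] for v in variables}

    # presence rows follow the occurrence table (one row per point, duplicates
    # on a shared cell retained: each record carries weight)
    pres_vals = {v: stack.layers[v].values_at(x, y) for v in variables}
    bg_vals = cell_values(bg_flat)

    train_cells = {v: np.concatenate([pres_vals[v], bg_vals[v]]) for v in variables}
    means = {v: float(np.mean(train_cells[v])) for v in variables}
    sds = {v: float(np.std(train_cells[v])) or 1.0 for v in variables}
    fmap = FeatureMap(
        variables=tuple(variables),
        means=means,
        sds=sds,
        feature_classes=tuple(cfg.feature_classes),
    )
    if "hinge" in cfg.feature_classes:
        for v in variables:
            z = (train_cells[v] - means[v]) / sds[v]
            qs = np.linspace(0, 100, N_HINGE_KNOTS + 2)[1:-1]
            fmap.knots[v] = np.percentile(z, qs)

    X_pres = fmap.build(pres_vals)
    X_bg = fmap.build(bg_vals)

    replicate_aucs: list[float] = []
    models: list[LogisticRegression] = []
    all_converged = True
    n_test = max(1, int(round(cfg.test_fraction * n_pres)))
    for rep in range(cfg.n_replicates):
        rep_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, rep)))
        perm = rep_rng.permutation(n_pres)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        X = np.vstack([X_pres[train_idx], X_bg])
        yv = np.concatenate([np.ones(len(train_idx)), np.zeros(n_bg)])
        model, conv = _fit_one(X, yv, cfg)
        all_converged &= conv
        test_scores = model.decision_function(X_pres[test_idx])
        bg_scores = model.decision_function(X_bg)
        replicate_aucs.append(auc(test_scores, bg_scores))
        models.append(model)

    best = int(np.argmax(replicate_aucs))  # argmax takes the lowest index on ties
    best_model = models[best]
    feat_names = fmap.feature_names
    coefs = dict(zip(feat_names, best_model.coef_.ravel().astype(float)))

    # suitability over every cell valid in all selected layers
    r, c = np.unravel_index(valid_flat, stack.shape)
    X_all = fmap.build({v: stack.layers[v].values[r, c] for v in variables})
    scores = best_model.decision_function(X_all)
    surf = np.full(stack.shape, np.nan)
    surf[r, c] = 1.0 / (1.0 + np.exp(-scores))
    ref = stack.layers[variables[0]]
    suit_grid = Grid(
        values=surf, transform=stack.transform, crs_label=ref.crs_label, nodata=np.nan,
        units="suitability",
    )

    X_train_all = np.vstack([X_pres, X_bg])
    feature_sds = {n: float(np.std(X_train_all[:, j])) for j, n in enumerate(feat_names)}
    contrib = _contributions_from(coefs, feature_sds, fmap)

    result = SuitabilityResult(
        coefficients=coefs,
        intercept=float(best_model.intercept_[0]),
        replicate_aucs=[float(a) for a in replicate_aucs],
        mean_auc=float(np.mean(replicate_aucs)),
        best_replicate=best,
        contributions=contrib,
        suitability=suit_grid,
        selected_variables=list(variables),
        feature_map=fmap,
        feature_sds=feature_sds,
        config=cfg,
        converged=all_converged,
    )
    return result


# ---------------------------------------------------------------------------
# contributions and projection


def _contributions_from(
    coefs: Mapping[str, float], feature_sds: Mapping[str, float], fmap: FeatureMap
) -> dict[str, float]:
    raw = {v: 0.0 for v in fmap.variables}
    for name, beta in coefs.items():
        raw[fmap.variable_of(name)] += abs(beta) * feature_sds[name]
    total = sum(raw.values())
    if total == 0:
        warnings.warn("all coefficients are zero; contributions set uniform", stacklevel=2)
        return {v: 100.0 / len(raw) for v in raw}
    return {v: 100.0 * r / total for v, r in raw.items()}


def contributions(result: SuitabilityResult, stack: GridStack | None = None) -> dict[str, float]:
    """Percent contribution per variable: sum over the variable's features of
    |coefficient| x feature standard deviation over training cells, normalized
    to sum to 100.  An analogue of Maxent's percent contribution, not a
    replica of its path-tracked accounting."""
    return _contributions_from(result.coefficients, result.feature_sds, result.feature_map)


def project(result: SuitabilityResult, target_stack: GridStack) -> Grid:
    """Project a fitted model onto another co-registered predictor stack.

    Features are rebuilt with the *training* means/sds and knots, so the
    surface reflects how the fitted response extrapolates to the target
    scenario (e.g. a paleo-trained model under current climate).
    """
    missing = [v for v in result.selected_variables if v not in target_stack.layers]
    if missing:
        raise ValueError(f"target stack lacks variables {missing}")
    variables = result.selected_variables
    mask = target_stack.common_mask(variables)
    flat = np.flatnonzero(mask.ravel())
    r, c = np.unravel_index(flat, target_stack.shape)
    X = result.feature_map.build({v: target_stack.layers[v].values[r, c] for v in variables})
    beta = np.array([result.coefficients[n] for n in result.feature_map.feature_names])
    scores = X @ beta + result.intercept
    surf = np.full(target_stack.shape, np.nan)
    surf[r, c] = 1.0 / (1.0 + np.exp(-scores))
    return Grid(
        values=surf,
        transform=target_stack.transform,
        crs_label=next(iter(target_stack.layers.values())).crs_label,
        nodata=np.nan,
        units="suitability",
    )
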