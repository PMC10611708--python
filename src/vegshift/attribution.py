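"""Driver attribution: hexagonal zonal statistics and random-forest regression.

The study region is tessellated with flat-top regular hexagons (default side
5 km, area (3√3/2)·s² = 64.95 km²).  Mean degradation level, human footprint
(hfp) and five climate predictors — precipitation seasonality (pss), annual
precipitation (pre), temperature seasonality (tss), max temperature (tma),
min temperature (tmi) — are extracted per hexagon, and a tuned
random-forest regression predicts mean degradation level from the six
predictors.  Model diagnostics (R², RMSE, MAE) come from out-of-fold
predictions of 10-fold cross-validation; variable importances are held-out
permutation importances averaged over folds and rescaled so the largest
equals 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold

from .grid_io import AlignmentError, Grid

__all__ = [
    "PREDICTORS",
    "HexGrid",
    "AttributionReport",
    "hex_area",
    "tessellate",
    "zonal_means",
    "fit_rf",
]

PREDICTORS = ("hfp", "pss", "pre", "tss", "tma", "tmi")
DEFAULT_TUNE_GRID = (2, 3, 4, 5, 6)
N_TREES = 500
N_FOLDS = 10
N_PERMUTATION_REPEATS = 5


def hex_area(side_km: float) -> float:
    """Area of a regular hexagon of the given side: (3√3/2)·s²."""
    if side_km <= 0:
        raise ValueError("hexagon side must be positive")
    return 1.5 * np.sqrt(3.0) * side_km**2


@dataclass
class HexGrid:
    """Flat-top regular hexagons on an axial lattice.

    Centers form the lattice (columns spaced 1.5·s, rows √3·s, odd columns
    offset by √3·s/2); the hexagons are the Voronoi cells of the centers, so
    they tile the plane without overlap and every point belongs to the
    hexagon whose center is nearest.
    """

    side_km: float
    centers: np.ndarray  # (n, 2) center coordinates in map units (km)
    orientation: str = "flat-top"

    def __len__(self) -> int:
        return len(self.centers)

    def polygon(self, i: int) -> Polygon:
        s, (cx, cy) = self.side_km, self.centers[i]
        ang = np.deg2rad(np.arange(0, 360, 60))
        return Polygon(np.column_stack([cx + s * np.cos(ang), cy + s * np.sin(ang)]))

    @property
    def polygons(self) -> list[Polygon]:
        return [self.polygon(i) for i in range(len(self))]

    def assign(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Hexagon index of each point (nearest center; lattice Voronoi)."""
        tree = cKDTree(self.centers)
        return tree.query(np.column_stack([np.asarray(x), np.asarray(y)]))[1]


def tessellate(
    extent: tuple[float, float, float, float],
    side_km: float,
    mask: Grid | None = None,
) -> HexGrid:
    """Hexagonal lattice covering a bounding box (xmin, ymin, xmax, ymax).

    Hexagons whose centers fall outside the optional mask (nodata or outside
    its extent) are dropped.  A side exceeding the extent yields a single
    hexagon with a warning.
    """
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate extent")
    s = side_km
    if s <= 0:
        raise ValueError("hexagon side must be positive")
    if s > (xmax - xmin) and s > (ymax - ymin):
        warnings.warn("hexagon side exceeds the extent; returning one hexagon", stacklevel=2)
        centers = np.array([[(xmin + xmax) / 2.0, (ymin + ymax) / 2.0]])
        return HexGrid(side_km=s, centers=centers)

    dx, dy = 1.5 * s, np.sqrt(3.0) * s
    # centers within the extent dilated by one circumradius cover every point
    i0 = int(np.floor((xmin - s - xmin) / dx))
    i1 = int(np.ceil((xmax + s - xmin) / dx))
    centers = []
    for i in range(i0, i1 + 1):
        cx = xmin + i * dx
        off = (dy / 2.0) if (i % 2) else 0.0
        j0 = int(np.floor((ymin - s - off - ymin) / dy))
        j1 = int(np.ceil((ymax + s - off - ymin) / dy))
        for j in range(j0, j1 + 1):
            centers.append((cx, ymin + off + j * dy))
    centers = np.asarray(centers)
    if mask is not None:
        vals = mask.values_at(centers[:, 0], centers[:, 1])
        keep = vals != mask.nodata
        if np.isnan(mask.nodata):
            keep = ~np.isnan(vals)
        centers = centers[keep]
    return HexGrid(side_km=side_km, centers=centers)


def zonal_means(hexes: HexGrid, grids: Mapping[str, Grid]) -> pd.DataFrame:
    """Mean of each grid per hexagon; a cell belongs to the hexagon containing
    its center.

    Means are computed over cells valid (non-nodata) in *every* grid so all
    columns of a retained row are populated; ``n_valid_cells`` counts those
    cells, and hexagons with none are dropped.  Returns a DataFrame indexed
    by ``hex_id`` with one column per grid plus ``n_valid_cells``.
    """
    if not grids:
        raise ValueError("need at least one grid")
    items = list(grids.items())
    ref = items[0][1]
    for name, g in items[1:]:
        if not g.same_grid(ref):
            raise AlignmentError(f"grid {name!r} is misaligned with {items[0][0]!r}")

    valid = np.ones(ref.shape, dtype=bool)
    for _, g in items:
        valid &= g.mask
    rows, cols = np.nonzero(valid)
    x, y = ref.transform.cell_center(rows, cols)
    hex_id = hexes.assign(x, y)

    n = len(hexes)
    counts = np.bincount(hex_id, minlength=n)
    data = {"hex_id": np.arange(n)}
    for name, g in items:
        sums = np.bincount(hex_id, weights=g.values[rows, cols].astype(float), minlength=n)
        with np.errstate(invalid="ignore"):
            data[name] = sums / counts
    data["n_valid_cells"] = counts
    df = pd.DataFrame(data)
    return df[df["n_valid_cells"] > 0].reset_index(drop=True)


@dataclass
class AttributionReport:
    """Tuned random-forest diagnostics and 0-100 scaled importances."""

    r2: float
    rmse: float
    mae: float
    importances: dict[str, float]
    best_params: dict[str, int]
    n_trees: int
    seed: int
    cv_rmse_by_candidate: dict[int, float] = field(default_factory=dict)
    resampling: str = f"{N_FOLDS}-fold CV"
    importance_mode: str = "held-out permutation, mean over folds, max scaled to 100"


def fit_rf(
    table: pd.DataFrame,
    seed: int,
    tune_grid: Sequence[int] = DEFAULT_TUNE_GRID,
    response: str = "degradation_mean",
    predictors: Sequence[str] = PREDICTORS,
    n_trees: int = N_TREES,
) -> AttributionReport:
    """Tuned random-forest regression of mean degradation level on the
    predictor set.

    Each candidate value of ``max_features`` (predictors tried per split) is
    scored by 10-fold cross-validated RMSE on shared folds; the best
    candidate's out-of-fold predictions give R², RMSE and MAE.  Importances
    are permutation importances computed on each held-out fold, averaged,
    floored at zero and linearly rescaled so the maximum is exactly 100.
    """
    predictors = list(predictors)
    missing = [c for c in [response, *predictors] if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    if len(table) < 50:
        raise ValueError(f"need >= 50 hexagons, got {len(table)}")
    X = table[predictors].to_numpy(float)
    y = table[response].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("constant response: degradation level does not vary")

    tune_grid = [m for m in tune_grid if m <= len(predictors)]
    folds = list(KFold(n_splits=N_FOLDS, shuffle=True, random_state=seed).split(X))

    def oof_predictions(m: int, keep_models: bool = False):
        preds = np.empty_like(y)
        models = []
        for tr, te in folds:
            rf = RandomForestRegressor(
                n_estimators=n_trees, max_features=m, random_state=seed, n_jobs=1
            )
            rf.fit(X[tr], y[tr])
            preds[te] = rf.predict(X[te])
            if keep_models:
                models.append(rf)
        return preds, models

    cv_rmse: dict[int, float] = {}
    for m in tune_grid:
        preds, _ = oof_predictions(m)
        cv_rmse[m] = float(np.sqrt(np.mean((preds - y) ** 2)))
    best_m = min(cv_rmse, key=lambda m: (cv_rmse[m], m))

    preds, models = oof_predictions(best_m, keep_models=True)
    ss_res = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    mae = float(np.mean(np.abs(preds - y)))

    raw = np.zeros(len(predictors))
    for rf, (tr, te) in zip(models, folds):
        pi = permutation_importance(
            rf, X[te], y[te], n_repeats=N_PERMUTATION_REPEATS, random_state=seed, n_jobs=1
        )
        raw += pi.importances_mean
    raw = np.maximum(raw / len(folds), 0.0)
    if raw.max() <= 0:
        raise ValueError("degenerate model: no predictor has positive importance")
    # divide before scaling so the top importance is exactly 100.0
    importances = {p: float(100.0 * (v / raw.max())) for p, v in zip(predictors, raw)}

    return AttributionReport(
        r2=r2,
        rmse=rmse,
        mae=mae,
        importances=importances,
        best_params={"max_features": best_m},
        n_trees=n_trees,
        seed=seed,
        cv_rmse_by_candidate=cv_rmse,
    )
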