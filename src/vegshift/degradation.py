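"""Degradation classification of potential vegetation against current land cover.

Each analyzed cell is assigned a degradation level by crossing the binary
potential-vegetation map (FOREST / SHRUB) with the observed land-cover class:

===========  ====================  ======
potential    observed              level
===========  ====================  ======
FOREST       ForestFormation       0 (no change)
SHRUB        SavannaFormation      0 (no change)
SHRUB        ForestFormation       0 (forest where shrub was predicted is
                                      not degradation; counted separately)
FOREST       SavannaFormation      1 (forest to shrub)
either       Pasture/Agriculture   2 (forest/shrub to farming)
either       NonVegetated          3 (forest/shrub to non-vegetation)
either       Other                 excluded from the analyzed region
===========  ====================  ======

The area ledger converts cell counts into km² per category, and
:func:`summary_stats` derives the headline percentages.  Printed-report
conventions are deliberately mixed: natural cover, forest-remaining and the
potential fractions are *truncated* (2 and 1 decimals respectively), while
shrub expansion and farming are rounded to integers — each noted per field.
Shrub expansion is the ratio of current total shrubland (undisturbed plus
forest-to-shrub) to potential shrubland, x100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .grid_io import AlignmentError, Grid
from .potential_vegetation import FOREST, SHRUB

__all__ = [
    "LANDCOVER_CLASSES",
    "DEFAULT_CODE_TABLE",
    "LandCoverMap",
    "AreaLedger",
    "DegradationMap",
    "classify",
    "area_ledger",
    "summary_stats",
]

LANDCOVER_CLASSES = (
    "ForestFormation",
    "SavannaFormation",
    "Pasture",
    "Agriculture",
    "NonVegetated",
    "Other",
)

DEFAULT_CODE_TABLE: dict[int, str] = {
    1: "ForestFormation",
    2: "SavannaFormation",
    3: "Pasture",
    4: "Agriculture",
    5: "NonVegetated",
    6: "Other",
}

EXCLUDED = -1  # degradation-map sentinel for nodata / Other / outside mask


@dataclass
class LandCoverMap:
    """Categorical land-cover raster with its code table."""

    grid: Grid
    code_table: dict[int, str]

    def __post_init__(self) -> None:
        bad = set(self.code_table.values()) - set(LANDCOVER_CLASSES)
        if bad:
            raise ValueError(f"unknown land-cover class names {sorted(bad)}")
        codes = np.unique(self.grid.values[self.grid.mask]).astype(int)
        unknown = [int(c) for c in codes if int(c) not in self.code_table]
        if unknown:
            raise ValueError(f"land-cover codes without a code-table entry: {unknown}")


@dataclass
class AreaLedger:
    """Areas (km²) of the potential and observed categories."""

    potential_forest_km2: float = 0.0
    potential_shrub_km2: float = 0.0
    current_forest_km2: float = 0.0
    current_shrub_km2: float = 0.0
    forest_to_shrub_km2: float = 0.0
    farming_km2: float = 0.0
    nonveg_km2: float = 0.0
    region_km2: float = 0.0
    forest_over_predicted_shrub_km2: float = 0.0

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DegradationMap:
    """Degradation-level raster (codes 0-3, excluded cells as nodata) plus
    the per-category area ledger."""

    grid: Grid
    cell_area_km2: float
    ledger: AreaLedger


def classify(potential: Grid, landcover: LandCoverMap) -> DegradationMap:
    """Cross the binary potential map with observed land cover into levels 0-3.

    Cells that are nodata in either input, or whose observed class is Other,
    are excluded from the analyzed region.  Raises on misaligned inputs or
    land-cover codes missing from the code table.
    """
    lc = landcover.grid
    if not potential.same_grid(lc):
        raise AlignmentError("potential and land-cover grids are misaligned")

    name_of = landcover.code_table
    valid = potential.mask & lc.mask
    codes = lc.values.astype(int)
    unknown = set(np.unique(codes[valid])) - set(name_of)
    if unknown:
        raise ValueError(f"unknown land-cover codes {sorted(unknown)}")

    is_class = {
        cls: valid & np.isin(codes, [k for k, v in name_of.items() if v == cls])
        for cls in LANDCOVER_CLASSES
    }
    pot = potential.values
    forest_pred = valid & (pot == FOREST)
    shrub_pred = valid & (pot == SHRUB)

    out = np.full(potential.shape, EXCLUDED, dtype=np.int16)
    out[forest_pred & is_class["ForestFormation"]] = 0
    out[shrub_pred & is_class["SavannaFormation"]] = 0
    out[shrub_pred & is_class["ForestFormation"]] = 0
    out[forest_pred & is_class["SavannaFormation"]] = 1
    out[(forest_pred | shrub_pred) & (is_class["Pasture"] | is_class["Agriculture"])] = 2
    out[(forest_pred | shrub_pred) & is_class["NonVegetated"]] = 3

    cell_area = potential.cell_area
    grid = Grid(
        values=out, transform=potential.transform, crs_label=potential.crs_label,
        nodata=EXCLUDED, units="degradation level",
        code_table={0: "no change", 1: "forest to shrub", 2: "farming", 3: "non-vegetation"},
    )
    dmap = DegradationMap(grid=grid, cell_area_km2=cell_area, ledger=AreaLedger())
    dmap.ledger = area_ledger(dmap, potential, landcover)
    return dmap


def area_ledger(
    dmap: DegradationMap, potential: Grid, landcover: LandCoverMap | None = None
) -> AreaLedger:
    """Cell counts x cell area per category.

    ``current_forest`` counts level-0 cells where forest was predicted,
    ``current_shrub`` level-0 cells where shrub was predicted; the region is
    every non-excluded cell.  Forest observed where shrub was predicted is
    level 0 but additionally tallied in ``forest_over_predicted_shrub_km2``.
    """
    lvl = dmap.grid.values
    analyzed = lvl != EXCLUDED
    pot = potential.values
    a = dmap.cell_area_km2

    forest_pred = analyzed & (pot == FOREST)
    shrub_pred = analyzed & (pot == SHRUB)
    over = 0.0
    if landcover is not None:
        ff_codes = [k for k, v in landcover.code_table.items() if v == "ForestFormation"]
        over = float(
            np.sum(shrub_pred & (lvl == 0) & np.isin(landcover.grid.values.astype(int), ff_codes))
        ) * a

    return AreaLedger(
        potential_forest_km2=float(forest_pred.sum()) * a,
        potential_shrub_km2=float(shrub_pred.sum()) * a,
        current_forest_km2=float((forest_pred & (lvl == 0)).sum()) * a,
        current_shrub_km2=float((shrub_pred & (lvl == 0)).sum()) * a,
        forest_to_shrub_km2=float((lvl == 1).sum()) * a,
        farming_km2=float((lvl == 2).sum()) * a,
        nonveg_km2=float((lvl == 3).sum()) * a,
        region_km2=float(analyzed.sum()) * a,
        forest_over_predicted_shrub_km2=over,
    )


def _truncate(x: float, decimals: int) -> float:
    factor = 10.0**decimals
    return math.floor(x * factor) / factor


def summary_stats(ledger: AreaLedger) -> dict[str, float | None]:
    """Headline percentages from the area ledger.

    Report conventions (documented per field):
      - natural_percent, forest_remaining_percent: truncated to 2 decimals
      - potential_forest_percent, potential_shrub_percent: truncated to 1 decimal
      - nonveg_percent: 1 decimal
      - shrub_expansion_percent, farming_percent: rounded to integer
    A zero denominator yields None for the affected field rather than raising.
    """
    out: dict[str, float | None] = {}
    region = ledger.region_km2
    pf, ps = ledger.potential_forest_km2, ledger.potential_shrub_km2

    if region > 0:
        out["natural_percent"] = _truncate(
            100.0 * (ledger.current_forest_km2 + ledger.current_shrub_km2) / region, 2
        )
        out["farming_percent"] = float(round(100.0 * ledger.farming_km2 / region))
        out["potential_forest_percent"] = _truncate(100.0 * pf / region, 1)
        out["potential_shrub_percent"] = _truncate(100.0 * ps / region, 1)
        out["nonveg_percent"] = round(100.0 * ledger.nonveg_km2 / region, 1)
    else:
        out.update(
            natural_percent=None, farming_percent=None, potential_forest_percent=None,
            potential_shrub_percent=None, nonveg_percent=None,
        )
    out["forest_remaining_percent"] = (
        _truncate(100.0 * ledger.current_forest_km2 / pf, 2) if pf > 0 else None
    )
    out["shrub_expansion_percent"] = (
        float(round(100.0 * (ledger.current_shrub_km2 + ledger.forest_to_shrub_km2) / ps))
        if ps > 0
        else None
    )
    return out
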