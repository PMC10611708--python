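"""End-to-end orchestration on a synthetic landscape.

Chains every stage: generate fields and occurrences, fit the forest SDM under
current climate and soil, fit the shrub SDM under paleo climate and project
it to current climate, combine and binarize the suitabilities into the
potential-vegetation map, classify degradation against the generated
land-cover snapshot, and attribute degradation to human footprint vs climate
with the hexagon + random-forest stage.  Because the landscape's ground truth
is known, the result also reports recovery diagnostics (cellwise agreement of
the potential map with the truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import attribution, degradation, potential_vegetation, sdm
from .grid_io import Grid, GridStack, OccurrenceSet
from .synthetic_landscape import (
    LandscapeSpec,
    gen_fields,
    gen_landcover,
    gen_occurrences,
    true_potential_map,
)

__all__ = ["PipelineResult", "run_pipeline", "ATTRIBUTION_CLIMATE"]

# which synthetic climate layers stand in for the five attribution predictors
ATTRIBUTION_CLIMATE = {
    "pss": "clim02",
    "pre": "clim03",
    "tss": "clim04",
    "tma": "clim05",
    "tmi": "clim06",
}


@dataclass
class PipelineResult:
    forest_model: sdm.SuitabilityResult
    shrub_model: sdm.SuitabilityResult
    shrub_projected: Grid
    veg_map: potential_vegetation.SignedVegMap
    landcover: degradation.LandCoverMap
    degradation_map: degradation.DegradationMap
    summary: dict
    feature_table: "object"
    attribution_report: attribution.AttributionReport
    truth_agreement_percent: float
    occurrences: tuple[OccurrenceSet, OccurrenceSet]


def run_pipeline(
    spec: LandscapeSpec,
    sdm_cfg: sdm.SdmConfig | None = None,
    hex_side_km: float = 5.0,
    threshold_percentile: float = 10.0,
) -> PipelineResult:
    """Run the full reconstruction-classification-attribution chain."""
    current, paleo, hfp, soil = gen_fields(spec)
    occ_forest, occ_shrub = gen_occurrences(current, paleo, spec)
    cfg = sdm_cfg or sdm.SdmConfig(seed=spec.seed)

    # forest model: current climate plus soil (soil enters only this model)
    forest_stack = GridStack({**current.layers, **soil}, scenario="current")
    forest_vars = sdm.select_variables(forest_stack, cfg)
    forest_model = sdm.fit(occ_forest, forest_stack, cfg, variables=forest_vars)

    # shrub model: paleo climate, projected onto current climate
    shrub_vars = sdm.select_variables(paleo, cfg)
    shrub_model = sdm.fit(occ_shrub, paleo, cfg, variables=shrub_vars)
    shrub_projected = sdm.project(shrub_model, current)

    veg_map = potential_vegetation.build_potential_map(
        forest_model.suitability, shrub_projected, occ_forest, threshold_percentile
    )

    truth = true_potential_map(current, spec)
    landcover = gen_landcover(truth, hfp, spec)
    dmap = degradation.classify(veg_map.binary, landcover)
    summary = degradation.summary_stats(dmap.ledger)

    both = veg_map.binary.mask & truth.mask
    agreement = 100.0 * float(
        np.mean(veg_map.binary.values[both] == truth.values[both])
    )

    t = spec.transform
    nrows, ncols = spec.shape
    extent = (t.x0, t.y0 - nrows * t.dy, t.x0 + ncols * t.dx, t.y0)
    hexes = attribution.tessellate(extent, hex_side_km)
    level = dmap.grid
    response = Grid(
        values=level.values.astype(float), transform=level.transform,
        crs_label=level.crs_label, nodata=float(level.nodata), units="degradation level",
    )
    zonal_grids = {"degradation_mean": response, "hfp": hfp}
    zonal_grids.update({k: current.layers[v] for k, v in ATTRIBUTION_CLIMATE.items()})
    table = attribution.zonal_means(hexes, zonal_grids)
    report = attribution.fit_rf(table, seed=spec.seed)

    return PipelineResult(
        forest_model=forest_model,
        shrub_model=shrub_model,
        shrub_projected=shrub_projected,
        veg_map=veg_map,
        landcover=landcover,
        degradation_map=dmap,
        summary=summary,
        feature_table=table,
        attribution_report=report,
        truth_agreement_percent=agreement,
        occurrences=(occ_forest, occ_shrub),
    )
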