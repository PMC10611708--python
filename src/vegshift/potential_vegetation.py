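"""Combine forest and shrub suitability surfaces into a potential-vegetation map.

The forest suitability (trained on current climate and soil) and the shrub
suitability (trained on paleoclimate, projected to current climate) are
combined by signing the shrub surface negative and summing:

    combined = forest_suitability - shrub_suitability        (range [-1, 1])

The signed surface is binarized with a threshold calibrated on the forest
occurrence points: the default rule takes the 10th percentile of combined
values at forest occurrences, so at least 90% of the calibration presences
classify as forest.  Cells with combined >= threshold are FOREST, below are
SHRUB (ties break toward FOREST).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid_io import AlignmentError, Grid, OccurrenceSet

__all__ = [
    "FOREST",
    "SHRUB",
    "SignedVegMap",
    "combine",
    "calibrate_threshold",
    "binarize",
    "build_potential_map",
]

FOREST = 1
SHRUB = 0
BINARY_NODATA = -1
BINARY_CODES = {FOREST: "FOREST", SHRUB: "SHRUB"}


@dataclass
class SignedVegMap:
    """The signed suitability surface with its calibrated binary partition."""

    combined: Grid
    threshold: float
    binary: Grid


def combine(forest: Grid, shrub: Grid) -> Grid:
    """Cellwise forest minus shrub suitability; nodata where either is nodata."""
    if not forest.same_grid(shrub):
        raise AlignmentError("forest and shrub suitability grids are misaligned")
    valid = forest.mask & shrub.mask
    fv = forest.values.astype(float)
    sv = shrub.values.astype(float)
    if np.any((fv[valid] < 0) | (fv[valid] > 1) | (sv[valid] < 0) | (sv[valid] > 1)):
        raise ValueError("suitability inputs must lie in [0, 1]")
    out = np.where(valid, fv - sv, np.nan)
    return Grid(
        values=out, transform=forest.transform, crs_label=forest.crs_label,
        nodata=np.nan, units="signed suitability",
    )


def calibrate_threshold(
    combined: Grid, forest_occ: OccurrenceSet, percentile: float = 10.0
) -> float:
    """Threshold = the given percentile (linear interpolation) of the combined
    surface sampled at forest occurrence cells, so (100 - percentile)% of the
    calibration presences classify as FOREST.  Percentile 0 is the
    minimum-training-presence rule."""
    if not 0 <= percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    x, y = forest_occ.xy
    vals = combined.values_at(x, y)
    if np.isnan(combined.nodata):
        vals = vals[~np.isnan(vals)]
    else:
        vals = vals[vals != combined.nodata]
    if vals.size == 0:
        raise ValueError("all occurrences fall on nodata cells")
    if vals.size < 10:
        warnings.warn(
            f"calibrating on only {vals.size} occurrences; threshold may be unstable",
            stacklevel=2,
        )
    return float(np.percentile(vals, percentile))


def binarize(combined: Grid, threshold: float) -> Grid:
    """FOREST where combined >= threshold, SHRUB below; nodata preserved."""
    valid = combined.mask
    out = np.full(combined.shape, BINARY_NODATA, dtype=np.int16)
    out[valid & (combined.values >= threshold)] = FOREST
    out[valid & (combined.values < threshold)] = SHRUB
    return Grid(
        values=out, transform=combined.transform, crs_label=combined.crs_label,
        nodata=BINARY_NODATA, units="class", code_table=dict(BINARY_CODES),
    )


def build_potential_map(
    forest: Grid, shrub: Grid, forest_occ: OccurrenceSet, percentile: float = 10.0
) -> SignedVegMap:
    """Full combine -> calibrate -> binarize chain."""
    comb = combine(forest, shrub)
    thr = calibrate_threshold(comb, forest_occ, percentile)
    return SignedVegMap(combined=comb, threshold=thr, binary=binarize(comb, thr))
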