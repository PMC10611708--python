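"""Synthetic landscapes with known ground truth for every pipeline stage.

The generator emulates the statistical structure of the real inputs without
any geography: spatially autocorrelated environmental fields (Gaussian random
fields), presence points importance-sampled from a known suitability surface,
and a land-cover snapshot produced from the true potential-vegetation map by
a human-pressure-driven degradation process.  Because the truth (suitability
coefficients, potential map, transition probabilities) is known exactly,
model recovery can be asserted rather than assumed.

Default conditions: a 200x200 grid of 1 km cells, 19 climate layers with a
length scale of 15 cells (two of them near-duplicates at rho = 0.95 so the
collinearity filter always has work to do), 196 forest and 197 shrub
occurrences, suitability = logistic(4 z) on one driver layer, and a
degradation process whose multinomial logits are linear in the human
footprint with slope 2 (climate plays no generative role, giving driver
attribution an unambiguous ground truth; a climate term can be switched on
to study confounding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .degradation import DEFAULT_CODE_TABLE, LandCoverMap
from .grid_io import Grid, GridStack, OccurrenceSet, Transform
from .potential_vegetation import BINARY_CODES, BINARY_NODATA, FOREST, SHRUB

__all__ = [
    "DegradationLink",
    "LandscapeSpec",
    "gen_fields",
    "true_suitability",
    "true_potential_map",
    "gen_occurrences",
    "gen_landcover",
    "transition_probabilities",
]

CLIMATE_NAMES = tuple(f"clim{i:02d}" for i in range(1, 20))
SOIL_NAMES = ("clay", "sand")

# outcome order within each multinomial (baseline "stay" first)
FOREST_OUTCOMES = ("ForestFormation", "SavannaFormation", "Farming", "NonVegetated")
SHRUB_OUTCOMES = ("SavannaFormation", "Farming", "NonVegetated")


@dataclass(frozen=True)
class DegradationLink:
    """Multinomial logit link of the degradation process.

    For each cell the outcome logits are ``intercept + slope_hfp * hfp``
    (+ ``slope_climate * climate`` if enabled) against a baseline "stay
    natural" logit of 0.  Forest cells can stay, become shrubland, farming or
    bare; shrub cells can stay, become farming or bare.
    """

    forest_intercepts: tuple[float, float, float] = (0.0, -0.5, -3.0)
    shrub_intercepts: tuple[float, float] = (-0.5, -3.0)
    slope_hfp: float = 2.0
    slope_climate: float = 0.0
    climate_layer: str = "clim04"


@dataclass(frozen=True)
class LandscapeSpec:
    """Generator conditions; all outputs are reproducible from (spec, seed)."""

    shape: tuple[int, int] = (200, 200)
    cell_km: float = 1.0
    n_climate_layers: int = 19
    field_length_scale: float = 15.0
    forest_coeffs: Mapping[str, float] = field(default_factory=lambda: {"clim01": 4.0})
    shrub_coeffs: Mapping[str, float] = field(default_factory=lambda: {"clim01": -4.0})
    n_forest_occ: int = 196
    n_shrub_occ: int = 197
    duplicate_pair: tuple[str, str] = ("clim18", "clim19")
    duplicate_rho: float = 0.95
    paleo_anomaly_scale: float = 0.6
    paleo_anomaly_length: float = 25.0
    degradation_link: DegradationLink = field(default_factory=DegradationLink)
    farm_pasture_fraction: float = 0.5  # farming outcome split between Pasture/Agriculture
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 1 or self.cell_km <= 0:
            raise ValueError("shape must be positive and cell_km > 0")

    @property
    def transform(self) -> Transform:
        return Transform(x0=0.0, y0=self.shape[0] * self.cell_km, dx=self.cell_km, dy=self.cell_km)

    def _grid(self, values: np.ndarray, units: str = "") -> Grid:
        return Grid(
            values=values, transform=self.transform, crs_label="synthetic-km",
            nodata=np.nan, units=units,
        )


def _grf(rng: np.random.Generator, shape: tuple[int, int], length_scale: float) -> np.ndarray:
    """Standardized Gaussian random field: smoothed white noise."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=length_scale, mode="reflect")
    return (z - z.mean()) / z.std()


def gen_fields(
    spec: LandscapeSpec,
) -> tuple[GridStack, GridStack, Grid, dict[str, Grid]]:
    """Generate (current stack, paleo stack, hfp grid, soil grids).

    Every climate layer is an independent standardized Gaussian random field
    except the designated duplicate pair, whose second member is a rho-mixed
    copy of the first.  Paleo layers are the current layers plus a smooth
    seeded anomaly; hfp and the two soil layers are further independent
    fields.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    names = CLIMATE_NAMES[: spec.n_climate_layers]
    fields: dict[str, np.ndarray] = {
        n: _grf(rng, spec.shape, spec.field_length_scale) for n in names
    }
    a, b = spec.duplicate_pair
    if a in fields and b in fields:
        rho = spec.duplicate_rho
        mixed = rho * fields[a] + np.sqrt(1 - rho**2) * fields[b]
        fields[b] = (mixed - mixed.mean()) / mixed.std()

    current = GridStack({n: spec._grid(v) for n, v in fields.items()}, scenario="current")
    paleo_layers = {}
    for n in names:
        anomaly = spec.paleo_anomaly_scale * _grf(rng, spec.shape, spec.paleo_anomaly_length)
        paleo_layers[n] = spec._grid(fields[n] + anomaly)
    paleo = GridStack(paleo_layers, scenario="paleo")

    hfp = spec._grid(_grf(rng, spec.shape, spec.field_length_scale), units="human footprint")
    soil = {n: spec._grid(_grf(rng, spec.shape, spec.field_length_scale), units="g/kg (z)") for n in SOIL_NAMES}
    return current, paleo, hfp, soil


def true_suitability(stack: GridStack, coeffs: Mapping[str, float], spec: LandscapeSpec) -> Grid:
    """logistic(sum of coeff x z-scored layer) on the given stack."""
    eta = np.zeros(spec.shape)
    for name, c in coeffs.items():
        v = stack.layers[name].values
        eta = eta + c * (v - np.nanmean(v)) / np.nanstd(v)
    return spec._grid(1.0 / (1.0 + np.exp(-eta)), units="suitability")


def true_potential_map(current: GridStack, spec: LandscapeSpec) -> Grid:
    """Ground-truth binary potential vegetation: FOREST where the forest
    truth meets or exceeds the shrub truth evaluated under current climate."""
    f = true_suitability(current, spec.forest_coeffs, spec).values
    s = true_suitability(current, spec.shrub_coeffs, spec).values
    out = np.where(f >= s, FOREST, SHRUB).astype(np.int16)
    return Grid(
        values=out, transform=spec.transform, crs_label="synthetic-km",
        nodata=BINARY_NODATA, units="class", code_table=dict(BINARY_CODES),
    )


def _sample_occ(
    truth: Grid, n: int, taxa: list[str], role: str, scenario: str, rng: np.random.Generator
) -> OccurrenceSet:
    p = truth.values.ravel().astype(float)
    valid = ~np.isnan(p)
    if n > valid.sum():
        raise ValueError(f"requested {n} occurrences but only {valid.sum()} valid cells")
    p = np.where(valid, p, 0.0)
    p /= p.sum()
    flat = rng.choice(p.size, size=n, replace=False, p=p)
    r, c = np.unravel_index(flat, truth.shape)
    x, y = truth.transform.cell_center(r, c)
    points = pd.DataFrame(
        {"x": x, "y": y, "taxon": [taxa[i % len(taxa)] for i in range(n)]}
    )
    return OccurrenceSet(points=points, role=role, scenario=scenario)


def gen_occurrences(
    current: GridStack, paleo: GridStack, spec: LandscapeSpec
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Presence points importance-sampled from the true suitability surfaces.

    Forest points come from the current-climate forest truth; shrub points
    from the paleo-climate shrub truth (the shrub indicators are a paleo
    assemblage).  Cells are drawn without replacement with probability
    proportional to the truth; synthetic taxon labels cycle through 6 forest
    and 8 shrub taxa, mirroring the indicator species counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 2)))
    forest_truth = true_suitability(current, spec.forest_coeffs, spec)
    shrub_truth = true_suitability(paleo, spec.shrub_coeffs, spec)
    forest_taxa = [f"forest_taxon_{i:02d}" for i in range(1, 7)]
    shrub_taxa = [f"shrub_taxon_{i:02d}" for i in range(1, 9)]
    occ_f = _sample_occ(forest_truth, spec.n_forest_occ, forest_taxa, "forest", "current", rng)
    occ_s = _sample_occ(shrub_truth, spec.n_shrub_occ, shrub_taxa, "shrub", "paleo", rng)
    return occ_f, occ_s


def transition_probabilities(
    true_binary: Grid, hfp: Grid, spec: LandscapeSpec, climate: Grid | None = None
) -> dict[str, np.ndarray]:
    """Per-cell multinomial outcome probabilities of the degradation process.

    Returns ``{"forest": (4, rows, cols), "shrub": (3, rows, cols)}`` arrays
    in the outcome orders ``FOREST_OUTCOMES`` / ``SHRUB_OUTCOMES``.  Exposed
    so tests can hold sampled class frequencies to their exact expectations.
    """
    link = spec.degradation_link
    h = hfp.values
    extra = 0.0
    if link.slope_climate != 0.0:
        if climate is None:
            raise ValueError("climate grid required when slope_climate != 0")
        extra = link.slope_climate * climate.values

    def softmax_against_baseline(intercepts: tuple[float, ...]) -> np.ndarray:
        logits = np.stack([np.zeros_like(h)] + [a + link.slope_hfp * h + extra for a in intercepts])
        logits -= logits.max(axis=0, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=0, keepdims=True)

    return {
        "forest": softmax_against_baseline(link.forest_intercepts),
        "shrub": softmax_against_baseline(link.shrub_intercepts),
    }


def gen_landcover(
    true_binary: Grid, hfp: Grid, spec: LandscapeSpec, climate: Grid | None = None
) -> LandCoverMap:
    """Draw a land-cover snapshot from the degradation process.

    Each cell's outcome is a multinomial draw whose logits are linear in the
    human footprint: natural cells either persist (ForestFormation /
    SavannaFormation), convert to farming (split between Pasture and
    Agriculture), or to NonVegetated; forest cells can additionally collapse
    to shrubland (SavannaFormation).
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 3)))
    probs = transition_probabilities(true_binary, hfp, spec, climate)
    code_of = {v: k for k, v in DEFAULT_CODE_TABLE.items()}

    out = np.full(spec.shape, code_of["Other"], dtype=np.int16)
    u = rng.random(spec.shape)
    farm_split = rng.random(spec.shape) < spec.farm_pasture_fraction

    def draw(mask: np.ndarray, p: np.ndarray, outcomes: tuple[str, ...]) -> None:
        cum = np.cumsum(p, axis=0)
        idx = (u[None, ...] > cum).sum(axis=0)
        for k, name in enumerate(outcomes):
            sel = mask & (idx == k)
            if name == "Farming":
                out[sel & farm_split] = code_of["Pasture"]
                out[sel & ~farm_split] = code_of["Agriculture"]
            else:
                out[sel] = code_of[name]

    pot = true_binary.values
    draw(pot == FOREST, probs["forest"], FOREST_OUTCOMES)
    draw(pot == SHRUB, probs["shrub"], SHRUB_OUTCOMES)

    grid = Grid(
        values=out, transform=spec.transform, crs_label="synthetic-km",
        nodata=-1, units="class", code_table=dict(DEFAULT_CODE_TABLE),
    )
    return LandCoverMap(grid=grid, code_table=dict(DEFAULT_CODE_TABLE))
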