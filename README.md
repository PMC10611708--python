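# vegshift

Reconstruct the potential natural vegetation of a dry-forest region, measure
how far the present-day land cover has departed from it, and attribute that
departure to human pressure versus climate.

`vegshift` is aimed at landscape ecologists and biogeographers working on
seasonally dry tropical forests (SDTFs), where centuries of land use have
converted forest into shrubland, farmland and bare soil, and where naive
remote-sensing baselines mistake degradation-derived shrubland for natural
vegetation. The package implements the full inference chain as a tested
library, exercised end-to-end on synthetic landscapes with known ground
truth.

## The method

1. **Habitat suitability (SDM).** Two presence/background distribution
   models are fitted as L1-penalized log-linear discriminators — the
   standard logistic formulation of the maximum-entropy (Maxent) SDM family.
   Occurrences of forest-indicator taxa are modelled against current climate
   (19 bioclimatic layers) and soil (clay, sand); occurrences of
   open-vegetation indicator taxa are modelled against Last Glacial Maximum
   climate and the fitted model is projected onto current climate.
   Predictors are pre-filtered to pairwise Pearson |r| < 0.8; each model is
   evaluated by ROC AUC over 10 replicates with 10% of presences held out,
   against an AUC ≥ 0.75 gate; per-variable percent contributions
   (|coefficient| × feature spread, normalized to 100) summarize which
   variables drive each model.
2. **Potential vegetation.** The two suitability surfaces (each in [0, 1])
   are combined as `forest − shrub ∈ [−1, 1]` and binarized with a threshold
   calibrated on the forest occurrences (default: their 10th-percentile
   combined value, so ≥ 90% of presences classify as forest).
3. **Degradation levels.** The binary potential map is crossed with a
   categorical land-cover snapshot into levels 0–3: 0 no change, 1 forest →
   shrub, 2 forest/shrub → farming, 3 forest/shrub → non-vegetation. An area
   ledger (km² per category) feeds `summary_stats`, which reproduces
   report-style percentages (natural cover remaining, forest remaining
   relative to potential, shrubland expansion ratio, farming share).
4. **Driver attribution.** The region is tessellated with flat-top regular
   hexagons (side *s*, area (3√3/2)·s²; 64.95 km² at s = 5 km). Mean
   degradation level, human footprint (hfp) and five climate predictors
   (pss, pre, tss, tma, tmi) are extracted per hexagon, and a tuned random
   forest regresses degradation on the six predictors. Diagnostics (R²,
   RMSE, MAE) come from 10-fold out-of-fold predictions; importances are
   held-out permutation importances rescaled so the top variable is exactly
   100.

A synthetic-landscape generator produces all four input kinds with known
truth: Gaussian-random-field predictors (two deliberately collinear),
presences importance-sampled from a known logistic suitability, and a land
cover drawn from a degradation process whose multinomial logits are linear
in the human footprint. Because the truth is known, recovery is asserted,
not assumed.

## Worked example

```python
from vegshift import LandscapeSpec, run_pipeline

res = run_pipeline(LandscapeSpec(seed=1))
print("forest model AUC", round(res.forest_model.mean_auc, 3))
print("potential-map agreement %", round(res.truth_agreement_percent, 2))
print("hfp importance", res.attribution_report.importances["hfp"])
print("attribution R2", round(res.attribution_report.r2, 3))
```

prints

```
forest model AUC 0.714
potential-map agreement % 91.97
hfp importance 100.0
attribution R2 0.889
```

i.e. on a landscape whose degradation is driven purely by human pressure,
the pipeline recovers the true potential-vegetation map on 92% of cells,
identifies the human footprint as the dominant driver (importance 100, every
climate variable ≤ 2.2), and explains 89% of the hexagon-level variation in
degradation. The same stages are available as a CLI (`vegshift synth`,
`vegshift sdm fit`, `vegshift combine`, `vegshift classify`,
`vegshift attribute`) exchanging GeoTIFF/CSV/JSON/YAML files.

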