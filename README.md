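# avishift

Presence-only range-shift modelling and spatial conservation prioritization
for multi-species occurrence datasets on gridded climate scenarios.

`avishift` is built for the workflow a national-scale climate-impact
assessment of a species group (its design case is birds recorded by citizen
scientists) runs end to end: clean and thin biased presence-only records,
fit a climatic niche model per species, project it onto one or more future
climate scenarios, binarize the projections into range maps, measure how
ranges grow, shrink and move, and turn the result into a weighted
conservation priority ranking with protected-area gap statistics. Every
stage is also exercisable on seeded synthetic worlds with known ground
truth, so the whole chain is testable without any external data download.

## The models

**Niche model.** For each species, presences are contrasted with background
cells in an L2-penalized logistic log-linear model on standardized linear
and quadratic climate features — the presence-background formulation
equivalent to maximum-entropy (MaxEnt-style) modelling, restricted to
feature classes that capture Gaussian niches exactly and keep the fit
convex. Suitability is reported through the cloglog link

    p = 1 − exp(−exp(η)),   η = β₀ + Σᵥ (β₁ᵥ zᵥ + β₂ᵥ zᵥ²)

Models are cross-validated by five replicates (80/20 presence splits
against a shared background) with AUC scoring; the species suitability map
is the mean of the replicate predictions. Sampling bias is handled by
presence thinning (no conspecific pair closer than one arc-minute) and by
restricting the background to the regions ("provinces") where the species
has presences. Collinear climate variables are screened beforehand:
whichever variable has the most pairwise |r| > 0.9 partners at presence
sites is dropped, iteratively.

**Range dynamics.** Suitability is binarized at the threshold maximizing
test sensitivity plus specificity (MTSS) into distribution range maps
(DRMs). Per species and scenario the package reports the percentage area
change, the displacement vector between the geometric-median range centres
(great-circle km, bearing, compass quadrant), stacked species richness and
its change, and per-elevation-band diversity with a turning-point
elevation.

**Prioritization.** Cells are ranked by core-area zonation (CAZ): greedy
removal of the cell minimizing `max_j w_j p_ij / Q_j`, where `Q_j` is
species *j*'s remaining suitability, in batches of `warp_factor` cells.
Weights encode climate impact, `w = clamp(1 − Δ%/100, 0.1, 2.0) + 0.5 ·
endemic`, so range losers rank high. A masked scenario removes all
reserve cells first, yielding priorities strictly outside the existing
reserve network, and coverage statistics quantify the protected-area gap.

## Worked example

Fit one virtual species in a synthetic world and measure its response to a
+2-degree warming of the temperature-gradient band:

```python
import numpy as np
from avishift import (WorldConfig, SpeciesTruth, make_world, sample_occurrences,
                      fit_niche_model, mtss_threshold, binarize, range_change_record)
from avishift.niche import land_cell_mask, predict_suitability, sample_background_anywhere

cfg = WorldConfig(seed=0)                       # 60x80 grid, 0.1 deg cells
world = make_world(cfg)
current = world["climate_current"]
future = current.with_values(current.values + np.array([2.0, 0, 0, 0])[:, None, None],
                             band_names=current.band_names)

truth = SpeciesTruth("demo", {"bio1": 5.0}, {"bio1": 2.0})   # Gaussian niche on bio1
occ = sample_occurrences(truth, current, 400, seed=1)
bg = sample_background_anywhere(land_cell_mask(current), 2000, seed=2)
model = fit_niche_model(occ, bg, current, variables=["bio1"], seed=3)
print(f"recovered optimum: {model.fitted_optimum('bio1'):.2f} (true 5.0)")
print(f"mean held-out AUC: {model.mean_test_auc():.3f}")

t = mtss_threshold(model.cv_presence_scores_, model.cv_background_scores_)
drm_now = binarize(predict_suitability(model, current), t, "demo", "current")
drm_fut = binarize(predict_suitability(model, future), t, "demo", "warmed")
rec = range_change_record(drm_now, drm_fut)
print(f"MTSS threshold: {t:.3f}")
print(f"area change: {rec['pct_change']:+.1f}%  "
      f"shift: {rec['shift_km']:.1f} km toward {rec['bearing_deg']:.0f} deg")
```

Output:

```
recovered optimum: 4.88 (true 5.0)
mean held-out AUC: 0.910
MTSS threshold: 0.248
area change: +2.8%  shift: 28.4 km toward 10 deg
```

The fitted optimum lands within a tenth of a niche breadth of the truth,
and the +2-degree offset on a band whose gradient is −5 degrees per degree
of latitude should displace the range 0.4° ≈ 44 km poleward; the measured
vector points 10° east of due north at the right order of magnitude, the
residual reflecting the spatial noise in the climate surface.

The same chain runs from a shell: `avishift simulate | prep | fit |
project | analyze | prioritize`, or in one command

```sh
avishift run-all --out runs/demo --seed 1
```

which writes the world rasters, cleaned occurrences, model JSONs,
suitability and range-map GeoTIFFs, range-change and summary tables,
priority rankings with top-30%/top-50% maps, coverage statistics, and a
manifest with per-stage seeds and output checksums (two runs with the same
config and seed are byte-identical).

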