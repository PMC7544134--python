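# Methods

This note documents the models implemented in `avishift`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Niche model

The per-species model is a presence-background binomial fit: presences
(y = 1) against background cells (y = 0), L2-penalized logistic regression
on standardized linear and quadratic features of the selected climate and
elevation variables. This is the log-linear formulation commonly used as a
reproducible equivalent of maximum-entropy presence-only modelling. We
restrict features to linear + quadratic terms deliberately: they represent
unimodal (Gaussian) responses exactly, keep every fit convex and fast, and
make the fitted optimum of each variable available in closed form
(`x* = mean − scale · β₁ / (2 β₂)` when β₂ < 0). Hinge, product and
threshold features are out of scope; multimodal or skewed responses are
therefore approximated at best.

Suitability is reported through the cloglog link `p = 1 − exp(−exp(η))`,
which maps the linear predictor to an approximate probability of presence
(η = 0 gives p ≈ 0.632). The link is monotone, so ranking-based statistics
(AUC, MTSS) are unaffected by the choice.

Standardization constants (mean, standard deviation per variable) are
computed once from the pooled presences + background of the full fit and
shared by the replicate fits. A variable with zero variance in that pool
raises an error naming the variable.

**Cross-validation.** Presences are shuffled under the stage seed and dealt
into k = 5 folds; each replicate trains on the other four folds plus the
entire shared background and is scored by AUC (rank-based, midrank ties —
algebraically the all-pairs concordance count) on the held-out fold. The
species suitability map used downstream is the mean of the five replicate
predictions; the all-data fit is stored alongside and used for
coefficient-based decisions (pruning, optima).

**Parameters.** `regularization` (penalty strength on standardized
features, default 1.0; sklearn C = 1/regularization); `k_folds` (5);
`n_background` (cells per species; 10,000 is the conventional ceiling, the
synthetic-world default is 2,000 which already exceeds a quarter of the
default grid).

## Variable screening and the two-round procedure

Pairwise Pearson correlations are computed at all presence sites pooled
over species. While any pair exceeds |r| > 0.9, the variable in the most
high-correlation pairs is removed. Ties are broken by the largest mean |r|
against all other variables, then lexicographically — the iteration order
and tie rules are our own fixed convention, chosen for determinism.
Constant variables are removed first with a warning since their
correlations are undefined.

Round 1 fits every species on all screened climate variables plus
elevation with an unrestricted background. Two filters follow:

* **Locality density.** The predicted range is tiled with 3° × 3° blocks
  (anchored at 0°); species whose locality count divided by the number of
  blocks intersecting the range is *strictly* below 1 are excluded. A
  density of exactly 1.0 is retained.
* **Zero contribution.** Variables whose |linear| + |quadratic|
  standardized coefficient mass is ≤ 1e−8 in the round-1 fit are dropped
  for that species. Coefficient mass is our operationalization of "no
  contribution"; it is not identical to MaxEnt-style percent contribution,
  but a variable with (numerically) zero coefficients provably contributes
  nothing to the fitted surface.

Round 2 refits the survivors on their per-species variable sets with the
background restricted to land cells of the regions (province analogues)
containing at least one presence of the species — the standard
target-group-style correction for geographically biased recording effort.
Per-species failures at any stage are logged with a reason and skipped;
they never abort the batch.

## Thresholding and range dynamics

**MTSS.** Candidate thresholds are the midpoints between adjacent distinct
pooled scores plus one candidate below and one above all scores;
sensitivity is the share of presences ≥ t and specificity the share of
background < t; the smallest maximizer is returned. Scores are the pooled
held-out presence suitabilities (each presence scored by the replicate
that held it out) against the replicate-mean background suitabilities.
Binarization uses ≥, so a cell exactly at the threshold is presence; the
midpoint candidates make this choice rarely binding, but it must be fixed.

**Areas** are reported both as cell counts and km² (spherical
cosine-latitude cell areas, R = 6371 km); percentage change uses cell
counts. A species with an empty current range has undefined percentage
change and is logged and excluded from summaries and weights.

**Median centre.** The range centre is the geometric median of the
presence-cell centres: Weiszfeld iterative reweighting in a local
equirectangular frame about the centroid (x scaled by cos of the centroid
latitude), tolerance 1e−8 degrees, with the Vardi–Zhang adjustment when an
iterate coincides with a data point. Displacement distances between
centres use the haversine formula; quadrants follow the strict sign rule
(north requires Δlat > 0, east requires Δlon > 0), with Δlat = 0 or
Δlon = 0 flagged as boundary cases and a zero vector given no quadrant.

**Elevation profile.** Bands are half-open [lo, hi) intervals with the
conventional edges 0, 500, …, 4000, 5000 m and an open top band; per-band
diversity is the number of species occupying at least one cell in the
band. The turning point is the lowest band edge below which every band's
diversity change is ≤ 0 and at/above which every change is ≥ 0 — `None`
when no such edge exists or nothing changes. Note the edge can be the
bottom edge (0 m) when diversity increases in every band; real elevation
responses need not have a single sign change, in which case no turning
point is reported.

## Prioritization

Core-area zonation removes cells greedily, worst first: the marginal loss
of cell i is `max_j w_j p_ij / Q_j` with `Q_j` the species' suitability
summed over not-yet-removed cells. Each iteration removes the
`warp_factor` cells with the smallest loss without intra-batch
recomputation (warp semantics); losses are recomputed from scratch between
iterations, so warp 1 reproduces the exact greedy algorithm — this is what
the brute-force oracle tests check, to bitwise equality including the
tie-breaks (smallest loss, then row-major cell index). Species whose total
suitability is zero are dropped with a warning. Rank = removal position /
land-cell count, so ranks form a permutation of {1/N … 1}.

Weights: `w = clamp(1 − Δ%/100, 0.1, 2.0) + 0.5 · endemic`. The transform
is monotone decreasing in the range change (losers high, expanders low),
strictly positive, bounded, and adds exactly 0.5 for endemics. The masked
("outside reserves") scenario removes every reserve cell first in its own
CAZ-ordered phase — with Q still summed over all remaining cells — so the
top of the ranking and all top-fraction selections lie strictly outside
the reserve network. Whether to exclude reserve cells entirely or rank
them first is an open design point; removal-first is the default because
it keeps one consistent ranking surface.

Default `warp_factor` is 1,000 in run configurations (the batch size a
full-scale prioritization would use) and 1 wherever oracle comparability
matters.

## Synthetic worlds

`make_world` generates, from one seed: multi-band climate (a linear
north–south gradient per band plus moving-average-smoothed white noise —
the cheapest spatially autocorrelated field with controllable structure),
a future scenario equal to the current one plus a per-band additive offset
(exact by construction, up to one float addition), a non-negative
elevation surface spanning several of the standard bands, a partition into
axis-aligned contiguous region blocks, and a binary reserve mask covering
a configured fraction (default 0.15) of cells. Per-band noise amplitude is
scaled to the band's own gradient signal so that bands share the
latitudinal trend without being collinear (between-band |r| ≈ 0.5 at the
default noise level, comfortably under the 0.9 screening threshold).

Virtual species have Gaussian climatic niches; occurrences are multinomial
draws over cells proportional to true suitability, optionally multiplied
by an effort-bias surface (`exp(strength · smoothed noise)`), jittered
uniformly within the cell. The default study conditions are a 60 × 80 grid
of 0.1° cells, 4 climate bands, 20 species with breadths of 15% of each
band's central range, 250 records per species, effort bias strength 1 —
chosen so that niches are strong but not trivial and a full pipeline run
takes seconds on one core. Recovery experiments use 500 presences per
species and 12–20 species; oracle checks use 50–200 random instances.

What the generator does *not* emulate: realistic climate fields (no
seasonality structure, no cross-variable physics), dispersal limits or
demography, temporal record accumulation, coastline/land-sea masks, or
taxonomic error. Passing tests therefore demonstrate the correctness of
the algorithms and the recoverability of signal under the stated
generative model — not predictive skill on real species data.

## Numerical and degenerate-input conventions

* Cell membership of a point is the half-open cell [x, x + Δ) in each
  axis; points jittered within a cell always map back to it.
* Thinning distance is Euclidean in degree space (matching the arc-minute
  criterion); thinning visits points in seeded random order and keeps a
  point iff no kept conspecific lies within the separation, which is
  idempotent and monotone in the separation distance.
* Exact duplicates are removed deterministically before the
  minimum-locality count, so the rule counts distinct localities.
* All stochastic stages derive their seed from the master seed plus a
  CRC32 hash of the stage path; manifests contain no timestamps, making
  identical (config, seed) runs byte-identical.
* GeoTIFF I/O supports geographic (lon/lat) rasters only; a projected
  model type raises an error. Missing data is NaN in float grids and
  round-trips losslessly.

## Known limitations

* Linear + quadratic features cannot represent multimodal niches.
* The MTSS threshold is estimated from cross-validation scores of the same
  data used for the final map; with few presences it is noisy, and an
  all-absence binarized map (threshold above every suitability) is only
  warned about.
* Region-restricted background assumes the region partition is meaningful
  for recording effort; with one giant region it reduces to the
  unrestricted case.
* CAZ recomputes marginal losses between warp batches only; very large
  warp factors coarsen the ranking within batches by design.
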