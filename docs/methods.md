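# Methods

## The ecoclimatic-index model

The engine follows the classic growth-minus-stress formulation of
semi-mechanistic climatic niche models.  For each grid cell and week
*w* ∈ {1..52}:

- **Temperature Index** `TI_w = trap(tavg_w; DV0, DV1, DV2, DV3)`, the
  trapezoid that is 0 at or below DV0 and at or above DV3, 1 on
  [DV1, DV2], with linear ramps between.
- **Moisture Index** `MI_w = trap(sm_w; SM0, SM1, SM2, SM3)` on soil
  moisture expressed as a fraction of bucket capacity.
- **Weekly Growth Index** `GI_w = TI_w × MI_w`; annually
  `GI_A = 100 × mean_w GI_w` so that the final index lands on the
  conventional 0–100 scale.
- **Stresses.**  Cold stress is driven by weekly minimum temperature below
  TTCS, heat stress by weekly maximum above TTHS, dry and wet stress by
  soil moisture below SMDS / above SMWS.  Each accumulates linearly,
  `S = min(100, 100 × |rate| × 7 × Σ_w exceed_w)`, and the Stress Index is
  the product of survival factors `SI = Π (1 − S/100)`.
- **Degree-days** above DV0 accumulate as `Σ_w 7 × max(0, tavg_w − DV0)`.
- **Ecoclimatic Index** `EI = clamp(GI_A × SI, 0, 100)`.  With the
  generation gate enabled, any cell whose annual degree-day total is below
  PDD is forced to EI = 0.  Suitability categories: EI = 0 unsuitable,
  (0, 10) marginal, [10, 30) suitable, [30, 100] optimal; the boundary
  values 10 and 30 belong to the higher category so the partition is
  total and deterministic.

The commercial implementation of this model family does not publish its
internal weekly stepping, hydrology or stress compounding.  This package
therefore fixes an open, documented variant and treats it as the model:

- **Monthly → weekly interpolation** is piecewise linear between month
  midpoints with December–January wrap-around (months taken as 365/12
  days).  Point-sampled variables (temperatures, humidity) are
  interpolated directly; monthly totals (precipitation) are interpolated
  and rescaled by 12/52 so a constant 31 mm/month becomes 7.15 mm/week
  and the annual total is conserved.
- **Hydrology** is a single bucket: capacity 100 mm (the soil-moisture
  unit), weekly evaporation `1.5 mm · °C⁻¹ × max(0, tavg)`, overflow
  ceiling 2.5 capacities so that transient waterlogging can trip the
  wet-stress threshold (SMWS = 1.4).  The state starts at 0.5 and runs
  two annual cycles, reporting the second; with periodic forcing a third
  cycle reproduces the second to < 10⁻⁶ (tested), so the spin-up removes
  initial-condition sensitivity.
- **Stress accumulation is linear** (non-compounding) and capped at 100.
  All bound, gate and monotonicity properties asserted in the test suite
  are independent of these internals.
- **Degree-days** use the weekly mean times 7 days; no within-day
  sinusoid.
- Relative humidity is ingested and carried for completeness but no index
  term consumes it, since no published formula for it exists in this
  model family's public descriptions.

The seed-bug parameter values (`WCSB_PARAMS`) are taken as given:
DV0 = 13.4 °C, DV1 = 21, DV2 = 28, DV3 = 31, PDD = 500 degree-days,
SM0 = 0.05, SM1 = 0.1, SM2 = 0.8, SM3 = 1.4, TTCS = −10 °C with rate
−0.0005, TTHS = 31 °C with rate 0.0015, SMDS = 0.05 with rate −0.005,
SMWS = 1.4 with rate 0.001.  Both the gated (with-PDD) and ungated runs
are first-class: the gate expresses whether one generation can complete,
and comparing the two maps is itself informative about range limits.

## Occurrence processing

- Distances are great-circle (haversine, R = 6371.0088 km) on WGS84
  degrees; at the 10 km thinning scale projection error is negligible.
- **Thinning** is a deterministic greedy scan in record order: keep a
  point iff no already-kept point lies within the radius.  The result is
  maximal and idempotent and is verified against a brute-force oracle.
  Other orders give different (equally valid) subsets, which is why
  thinned counts are scenario properties, not universal constants.
- **Pseudo-absences** are sampled uniformly without replacement from grid
  cells containing no presence record (no buffer beyond the cell), placed
  at cell centers, defaulting to a 1:1 match of the presence count.
- **Stratified split** takes `ceil(f × class size)` per class for
  training — the only rounding rule that turns 1939 + 1939 points at 7:3
  into the 2716/1162 partition the workflow is built around.

## Random-forest pipeline

The forest itself is scikit-learn's `RandomForestClassifier`
(bootstrap, out-of-bag scoring); everything around it is implemented
here.  Tuning evaluates every combination of ntree ∈ {50, 100, …, 400}
and mtry ∈ {1, 2, 3, 4} (32 fits) and minimises OOB error, breaking ties
toward smaller ntree then smaller mtry for parsimony.  Classification
uses the majority vote (probability ≥ 0.5); no threshold tuning.
AUC is the rank-based Mann–Whitney statistic with averaged ties, checked
against a pairwise-comparison oracle and an independent library
implementation.  MDA permutes one feature column at a time (default 10
permutations; 0 disables MDA but keeps MDG) and reports the mean accuracy
drop; MDG averages each tree's total Gini impurity decrease per feature.
Row class errors follow the published report layout in which the
predicted-negative row holds (TP, FP) and the predicted-positive row
(FN, TN); only the training-side cells of that report are arithmetically
self-consistent, and only those are used as a worked example.

The collinearity filter retains layers greedily in a priority order
(default: the canonical layer list tx3, tx5, tn8, tn12, rr4, rr5, rr8,
rr9, rr10, qq5, qq12, hu4, hu12, DEM, Di), dropping a candidate when
|Pearson r| with any retained layer exceeds 0.8.  Distance to conifer is
an exact nearest-neighbour search (k-d tree on unit-sphere coordinates;
chord distance is monotone in arc distance), center-to-center on the
raster grid.

## Synthetic study systems

`SyntheticScenario` defines the default desk-scale conditions: a
200 × 200 grid of 1 km cells from 44° N, annual-mean temperature 16 °C at
the southern edge falling 0.8 °C per degree of latitude and 6.5 °C per km
of elevation, a July-peaking seasonal cycle of ±9 °C, 0.5 °C cell-month
noise, fixed oceanic monthly profiles (plus noise) for precipitation,
humidity and radiation, 25 conifer disks of 6 km radius (~6% cover), a
smoothed random DEM on 0–1200 m, and 5000 raw presence records drawn from
`logistic(−6 − 0.6·Di + 0.9·tx3 − 0.006·DEM)` (units: km, °C, m) with
within-cell jitter.  These defaults were chosen so that the full workflow
reproduces the discrimination regime typical of real continental
occurrence modelling for this species — OOB error ≈ 0.20, accuracy
≈ 0.75, AUC ≈ 0.8, TSS ≈ 0.5 — rather than a trivially separable toy.
An 18 km `coarse_scenario()` mirrors the resolution at which the EI map
is usually computed.

Two named variants support calibration-style checks:

- `strong_recovery_scenario()`: 300 × 300 grid, 40 patches of 10 km,
  occurrences from `logistic(−25.3 − 2·Di + 2·tx3)` with 30 000 raw
  records.  The steep distance term confines presences to conifer
  neighbourhoods, the dense records mean most suitable cells hold a
  record (so pseudo-absences rarely land on suitable habitat), and the
  temperature term suppresses the cold-edge patches.  Replicated runs
  recover AUC > 0.9 and rank Di and tx3 as the top two MDA variables.
  Because small held-out sets make 10-permutation MDA ranks noisy, the
  recovery check evaluates importance on the full labelled table with 20
  permutations; replicate runs also use a reduced tuning grid
  (ntree ∈ {100, 200}, mtry ∈ {2, 3}) since grid cardinality is checked
  separately.
- `null_scenario()`: all slopes zero; presences are uniform and the
  fitted classifier sits at chance (AUC ≈ 0.5), a guard against leakage
  anywhere in the pipeline.

What the generator does *not* emulate: coastlines and real geography,
spatially correlated climate noise, polygon land cover (cover is
raster-native), observation effort gradients (an optional urban-bias
multiplier exists but is off by default), and taxonomic/georeferencing
error in records.  Passing tests therefore demonstrate the correctness
and calibration of the machinery, not the ecological accuracy of any
real-world map.

## Numerical and design notes

- Rasters are text ASCII grids with an ESRI-style header extended by
  `dx`/`dy` (geographic cells are not square in degrees); values are
  written with 9 significant digits, which round-trips float32
  bit-exactly.  No-data is −9999 on disk and NaN in memory.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit arguments; generator components use fixed sub-streams so each
  layer is reproducible independently.
- `tune_rf` report rows are ordered by (ntree, mtry), so the first
  minimum implements the documented tie-break.
- Workflow problem sizes (grid side 200–300, 5000–30 000 raw records,
  replicate counts 5–10) are desk-scale choices that keep a full
  replicate set to roughly a minute while leaving enough test points for
  stable rank statistics.
- Degenerate inputs fail loudly with typed errors: no conifer cells, an
  exhausted pseudo-absence domain (the shortfall is named), single-class
  training data, mismatched grid geometries or feature sets.

## Known limitations

- The EI variant is qualitative-faithful, not bit-compatible with the
  commercial implementation; absolute EI values should be compared
  between runs of this engine only.
- Greedy thinning depends on record order; shuffle first for a
  randomised variant.
- The bucket hydrology has no snow, runoff or soil classes; arid and
  alpine moisture regimes are caricatures.
- Permutation importance on strongly correlated predictors splits credit;
  the collinearity filter mitigates but does not remove this.
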