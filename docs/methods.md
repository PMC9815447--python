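# Methods

## Model

The quantity of interest is the distance cost of access to one facility for
the patients of a region: the total `D = Σ_ij d_ij` over patients at
locations *ij*, or equivalently the case-weighted average distance. The
estimator replaces the (private) patient locations with public aggregates:

* each basic statistical area *c* contributes `n′_c = round(pop_c × p)`
  expected cases, where `p` is the regional prevalence of the disease;
* all of an area's cases are placed at the area's **center** — the point
  geometry itself, or the area centroid of a polygon. Aggregating areas
  (e.g. to a community) uses the population-weighted mean of member
  centers;
* `D′_c` is the shortest-path road distance from that center to the
  facility, and the estimate is `D̂ = Σ_c n′_c · D′_c`.

The estimator is exact when every patient lives at their area center and
per-area counts equal `n′_c` — the identity `Σ d_ij = Σ n′_c D′_c` — and
the validation question is how fast agreement degrades as real residences
scatter around the centers and observed cohorts subsample true cases.

Assumptions worth stating: prevalence is uniform within the region (a
per-area prevalence column overrides this when available); all patients
attend the one facility (reasonable for chronic disease in a single-
medical-center catchment, not for conditions with provider shopping);
distance, not travel time, is the cost (no congestion or mode model);
the resident population is an acceptable proxy for the insured population
whenever insured/resident ≥ 0.95, which `coverage_check` verifies.

## Road network and distances

Roads are an undirected graph: polyline vertices become nodes (endpoints
within 0.5 m merge; node ids derive from coordinates quantized to that
tolerance, so graphs are invariant to input order), segments become edges
weighted by Euclidean length, and parallel edges keep the shorter length.
Shortest paths are nonnegative-weight Dijkstra (networkx); the tests hold
them to an independent Bellman–Ford oracle.

Area centers, patient residences and the facility are snapped to their
nearest node (KD-tree; exact ties break to the lexicographically smallest
node id). The snap gap is added to the path as a straight-line connector
by default — centers rarely sit exactly on a road — and a gap beyond
1,000 m logs a warning; `include_connectors=False` disables both
additions. Disconnected origin–destination pairs are an explicit error
(units) or a counted, logged exclusion (patients), never a silent zero.
All coordinates must be planar projected meters; inputs whose coordinates
all fit lon/lat ranges are rejected at load time rather than measured in
degrees, and reprojection is the caller's responsibility.

A Euclidean straight-line engine is available (`engine: euclidean`) for
testing and for effectively one-road corridors; it is never the default.

## Counting and aggregation

`round(pop × p)` uses half-away-from-zero rounding. With a prevalence
printed to two decimals this reproduces published worked counts to ±1
(the residual comes from the rounding of the prevalence itself, not the
rule). The region-level count is computed from the region population —
not by summing per-area roundings — and the discrepancy between the two
is reported (`AllocationResult.rounding_discrepancy`), typically a
handful of cases out of thousands.

Cost aggregation conserves by construction: the region total equals the
sum of community totals equals the sum of unit contributions
`n′_c · D′_c`. When a validation cohort inhabits only a subset of areas,
the estimation arm is masked to those areas (`unit_mask`) so both arms
average over the same geography; the per-group tables report both the
total and the used area counts.

## Agreement statistics

**ICC.** Per-area pairs (actual mean distance, estimated mean distance)
enter a two-way ANOVA; the default form is the two-way random-effects,
**absolute agreement**, single-measures ICC,

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)),  k = 2,

chosen because interchangeability is the claim being made — a systematic
offset between the arms should (and does) lower it. The consistency form
is available behind `form="consistency"`. The 95% CI uses the standard
F-based construction (Satterthwaite df for the agreement form) and the
p-value tests ICC = 0 via F = MSR/MSE on (n−1, (n−1)(k−1)) df. The
implementation is from-scratch ANOVA mean squares; tests pin it to
pingouin's `ICC(A,1)`/`ICC(C,1)` rows to 1e-9. When the two columns are
identical and constant the ICC is defined as 1 with a degenerate-CI flag.

**Adjusted regression.** Unit of analysis is the validation patient:
outcome = the estimated distance `D′_c` of the patient's area, predictors
= the patient's actual distance, gender (male = 1), age, plus intercept
(OLS via statsmodels, checked against the normal equations). Standardized
betas are `b_j · sd(x_j)/sd(y)`; adjusted R² is
`1 − (1 − R²)(n − 1)/(n − p − 1)`. Constant or collinear predictor
columns (e.g. a single-gender cohort) raise an error naming the column.
Diseases and years are analyzed independently, with no pooling and no
multiplicity correction; the significance level is 0.05 throughout.

## Synthetic scenario generator

`ScenarioConfig` defaults define the emulated setting: 512 areas of
150–450 residents in 15 communities, prevalence 9.65% (diabetes-like;
18.77% for a hypertension-like run), facility offset 80 km, address
jitter SD 300 m, 7% of true cases observed as validation patients, ages
~N(65, 13²) truncated to [18, 100], genders Bernoulli(0.5).

Geography is a linear corridor — communities at evenly spaced anchors
between 0.88 and 1.05 of the facility offset (realized road distances
roughly 67–92 km), unit centers Gaussian-scattered (SD 1.5 km) around
their anchor. The road network is a spine with nodes every 2 km from the
facility plus one straight branch per unit center, so the graph is
connected by construction and every center is a node; a 2-D `blob` layout
(units routed through their community anchor) is available via config.

True cases per area are Binomial(pop, p) by default, so the two arms
disagree with realistic sampling noise even at zero jitter of totals;
`case_model="expected"` switches to deterministic `round(pop × p)` counts,
which is what the exact-identity tests use (jitter 0 + full sampling +
expected counts ⇒ both arms equal to machine precision). Patient addresses
are the unit center plus isotropic Gaussian jitter truncated at 3 SD per
coordinate. Everything derives from one `numpy` generator seeded by
`config.seed`; identical configs are byte-identical on disk.

What the generator does **not** emulate: real road topology or terrain,
within-area population gradients (addresses scatter symmetrically around
the center, so the estimator's center-placement assumption is correct by
construction up to jitter), spatially varying prevalence, multi-facility
choice, and visit-frequency weighting. Passing tests therefore show the
pipeline's internal consistency and its robustness to address scatter and
cohort subsampling — not that any particular real region satisfies the
assumptions.

## Problem sizes and numerical notes

The test suite and the acceptance script run the full 512-area scenario;
a single replicate (generation + both arms) takes well under a second, the
10-replicate headline check a few seconds, and the 5-level × 20-seed
jitter sweep about ten seconds. Distances are reported in meters and
written to CSV with 2 decimals; internal computation is double precision
throughout. Exact-identity assertions use relative tolerance 1e-12
(float summation order differs between `Σ d_ij` and `Σ n′·D′c`). The
jitter sweep (1000 → 600 → 300 → 100 → 0 m) uses common seeds across
levels, under which the mean unit-level ICC increases monotonically toward
1 (≈0.980 at 1 km jitter, ≈0.996 at the 300 m default).

## Known limitations

* No travel-time, congestion or transport-mode modelling.
* One facility per run; multi-destination OD matrices are out of scope.
* No raster/dasymetric population surfaces: an area's center is its
  centroid, with population weighting only across areas.
* Visit multiplicity is accepted as a per-record weight but no behavioral
  model of visit frequency is implemented.
* Geographic (lon/lat) inputs must be reprojected by the caller.
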