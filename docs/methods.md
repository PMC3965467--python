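# Methods

## Model structure and assumptions

The pipeline estimates habitat suitability for ground-dwelling farmland
birds from resource provision rather than land-cover identity. It assumes:

- **Resources are the proximate driver of occurrence.** A cover type
  matters only through the diet items it supplies and the sward heights it
  offers for foraging and nesting. No other constraint (hunting pressure,
  microclimate, interspecific interactions, distance to unsuitable edges)
  is modelled; where such constraints bind, the model over-predicts
  occupancy.
- **Practices depress food linearly in count and intensity.** Expected
  relative abundance of a food resource is `a = 1/(n·f + 1)`: each
  additional impacting practice (agro-chemical inputs, irrigation,
  ploughing) and each unit of production intensity `f` lowers it; `n = 0`
  gives exactly 1. The `+1` keeps the value finite and in (0, 1]. `f`
  defaults to field yield (t/ha) with fallows fixed at 1; alternatives
  (`unit`: f = 1 everywhere; `coarse`: 1 for low-intensive, 2 for
  high-intensive systems) are first-class modes used by the sensitivity
  analysis. Exemptions (a crop that is itself consumable plant material,
  e.g. alfalfa) are rows in the input data, not code, so new crops can
  declare analogous rules.
- **Sward height is an adequate structural proxy** for foraging access and
  nest-site quality in herbaceous covers. Height distributions are
  qualitative scores per cover × month over four fixed categories (0–25,
  25–50, 50–100, >100 cm), normalised to frequencies. Months are integers
  4–9 (April–September); spring is {4,5,6}, summer {7,8,9}, and food
  quantities are constant within each period while structure varies
  monthly.
- **Substitutable diet, obligate activities.** The diet scalar product is
  truncated at 1 *before* entering the foraging product: food types
  substitute until the diet is satisfied, but surplus food cannot
  compensate for inaccessible structure (multiplicative foraging
  suitability), and neither foraging nor nesting suitability can compensate
  for the other (geometric-mean total, 0 if either is 0).
- **Absent is not zero.** Nesting suitability outside a species' nesting
  window — or for male Little Bustard, which takes no part in nesting — is
  excluded from averages rather than counted as 0. Temporal integration of
  nesting intersects the window with the nesting months and returns an
  absent value if the intersection is empty, in which case the total falls
  back to the foraging component.

## Order of operations

Per month, cover suitabilities are averaged over the transect (or
landscape) composition, with unsuitable area (shrub, urban, orchards,
"other") contributing 0; monthly values are then averaged over the time
window; the geometric mean is applied last. The alternative order —
geometric mean per month, then temporal average — changes results only for
nesting species and is exposed (`monthly_order=True`) for monthly
trajectory reporting, not for validation.

## Parameters and defaults

| Parameter | Default | Meaning |
|---|---|---|
| diet scoring scheme | 0 / 0.5 / 1 | not used / rare / preferred food |
| height probability scheme | 0 / 0.5 / 1 | not possible / rare / usual height |
| height preference | 0 / 1 | binary use of a height category |
| intensity scaling | yield (t/ha) | f in `1/(n·f+1)`; fallows 1 |
| time windows | full season; May; Apr–May; May–Jun; Apr–Jun | averaging spans around May surveys |
| classification rule | presence iff score ≥ threshold | threshold from the observed scores maximising sens + spec; ties broken toward the lowest threshold (favours sensitivity) |
| scenario fractions | 0.3, 0.5, 1.0 | share of each fallow type converted to dry cereal |
| robustness gate | AUC ≥ 0.6 | species below it are excluded from scenario output |

The sensitivity analysis re-runs the full pipeline under schemes 0/0/1,
0/0.25/1 and 0/0.75/1 (applied separately to height probabilities and diet
preferences) and under the unit and coarse intensity modes, reporting the
signed % change of the mean transect suitability, Pearson r against
baseline, and the % of transects whose classification flips. By default
each run re-derives its own optimal threshold — this makes the prediction-
change metric invariant to strictly monotone transforms of the scores,
which is tested; reusing the frozen baseline threshold is a config option.
Duplicate transect-years are all retained when computing suitability but
reduced to one seeded random record per transect for validation, to avoid
pseudo-replication.

Scenario conversion removes the same *fraction* of each fallow type's own
area (rather than equal absolute areas, which could drive a small source
negative) and credits the sum to dry cereal, conserving total area exactly.
Scenario classification uses thresholds frozen from baseline validation.

## The packaged study parameterisation

`packaged_study_fixture()` returns the four-species (Little Bustard male,
Stone Curlew, Calandra Lark, Red-legged Partridge), six-cover (dry and
irrigated cereal, till and no-till fallow, alfalfa, maize) encoding of the
published requirement and management tables, the study landscape
composition (71/3/7/1/9/4% + 5% other), and a monthly height-profile table
that is a **reconstruction**, flagged as such in the fixture metadata: the
original expert profiles are not reproduced in the main text, so the
package ships a phenology-consistent stand-in (winter cereal growing to
harvest in early summer, irrigated cereal taller and harvested later,
maize short in spring and tall from July, alfalfa held at low-to-mid
heights by cutting cycles, fallows persistently short). Conclusions that
depend on exact height profiles — e.g. the precise % suitability loss
under fallow conversion — are therefore checked as *properties* (loss
strictly positive and monotone in the conversion fraction for
fallow-preferring species), not as point values. The encoded food
availabilities, by contrast, reproduce all 48 published table cells at
2 decimal places (half-even rounding; computation keeps full precision).

## Synthetic data: what it emulates, and what it does not

`simulate_cover_tables` draws covers cycling five phenology archetypes
(permanent short fallow, autumn-sown tall cereal, spring-sown late-tall
row crop, cut forage, short early-harvested crop), with sow/peak/harvest
months jittered ±1, yields drawn per intensity class (1–3 t/ha
low-intensive, 5–15 t/ha high-intensive) and practice flags consistent
with the class (high-intensive: agro-chemical + irrigation; low-intensive:
at most ploughing). `simulate_transects` draws compositions
`Dirichlet(α) · (1 − u)` with `α = 0.3` — making most transects dominated
by one or two covers, as in surveys where the dominant cover averages
roughly three quarters of the surface — and unsuitable share
`u ~ Beta(1, 4)` (mean 0.2, so modelled covers hold ~80% of a transect).
Presence labels are Bernoulli with `logit P = intercept + slope · S`,
where `S` is the season-integrated total suitability the pipeline itself
assigns; slope (default 3) is the single signal-strength knob and slope 0
severs labels from habitat. All draws descend from one seed through
per-stage substreams, and identical seeds give identical outputs.

The generator does **not** emulate spatial autocorrelation between
transects, observation/detection error (presence is recorded without
false negatives), inter-annual crop rotation, or within-cover
heterogeneity. Passing signal-recovery tests therefore shows the pipeline
recovers a monotone suitability–occupancy link under clean sampling, not
that it is robust to detectability or spatial confounding in real censuses.

## Numerical choices

- Compositions must sum to 1 within 1e-6 (inputs are typically rounded
  percentages); height-frequency normalisation is exact and rejects
  all-zero score vectors naming the offending (cover, month).
- Comparisons against printed tables use banker's rounding at 2 decimals;
  nothing internal is rounded.
- AUC is rank-based with ties counted ½ and raises on single-class labels
  rather than returning a silent 0.5.
- Threshold candidates are the unique observed scores; the `≥` rule is
  used at the threshold (the published procedure does not state `≥` vs
  `>`; `≥` is adopted and documented).
- Degenerate variance in a sensitivity run yields an undefined (NaN)
  Pearson r rather than an arbitrary value.

## Problem sizes

The test suite and validation examples use 20–300 synthetic transects and
20 replicate seeds for signal-recovery checks; these sizes give stable
means (AUC standard error ≈ 0.01 at n = 300 × 20 seeds) for the properties
asserted. The study fixture itself is tiny (4 species × 6 covers × 6
months) and all fixture-derived checks are exact.

## Known limitations

- Validated only at the level the framework defines: suitability is an
  index in [0, 1], not a density or an occupancy probability; the logistic
  link in the simulator is an assumption, not an estimate.
- The reconstruction of monthly height profiles is plausible but not
  ground truth; users with local agronomic calendars should replace
  `height_scores.csv`.
- Female Little Bustard nesting requirements are not modelled (occurrence
  data cover displaying males only).
- Winter resource provision is outside the April–September season and is
  not represented.
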