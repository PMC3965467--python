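# steppehsi

Resource-based habitat-suitability modelling for farmland steppe birds.

Correlative habitat models relate species occurrence to land-cover classes
and break down as soon as management changes the resources a cover provides.
`steppehsi` instead builds suitability *mechanistically*, from two small
tables a field ecologist and an agronomist can fill in together: what
resources a species needs (diet, foraging and nesting sward height), and
what resources each cover type supplies, month by month, given the
agricultural practices applied to it. It is aimed at conservation ecologists
who want to score land-use scenarios — e.g. fallow land converted to cereal —
for ground-dwelling birds of cereal pseudo-steppe (Little Bustard, Stone
Curlew, Calandra Lark, Red-legged Partridge), before the change happens.

## Model

For species *i* and cover type (habitat unit) *k*:

- **Food availability.** The expected relative abundance of food resource
  *j* (seeds, plant material, invertebrates, vertebrates) is
  `a_kj = 1 / (n·f + 1)`, where `n` ∈ {0..3} counts the practices
  (agro-chemical inputs, irrigation, ploughing) flagged as destroying that
  resource in that cover and period, and `f` is the production-system
  intensity (field yield in t/ha; 1 for fallows). A crop that is itself the
  food (alfalfa as plant material) is exempt, forcing `n = 0`.
- **Habitat structure.** Qualitative scores (0 not possible / 0.5 rare /
  1 usual) for four sward-height categories (0–25, 25–50, 50–100, >100 cm)
  per cover and month are normalised to relative frequencies.
- **Suitability** is the scalar product `s_ik = Σ_j a_kj · r_ij` of
  availability against the species' requirement vector `r_ij`; food-based
  suitability is truncated at 1 (resources substitute until the diet is
  satisfied). Foraging suitability is the product of the structural and
  food components (both obligate); nesting suitability is structural only,
  and exists only inside the species' nesting window.
- **Integration.** Transect (or landscape) suitability is the
  composition-weighted average over cover types, with unsuitable area
  contributing 0; monthly values are averaged over a time window; total
  suitability is the geometric mean of the foraging and nesting components
  (0 if either is 0; foraging alone for species without a nesting
  component).
- **Validation** against presence/absence surveys uses AUC plus prediction
  success / sensitivity / specificity at the threshold maximising
  sensitivity + specificity. **Sensitivity analysis** re-runs the pipeline
  under alternative scoring triples (0/0/1, 0/0.25/1, 0/0.75/1) and
  intensity scalings (unit, coarse two-level). **Scenario projection**
  shifts a fraction of fallow area into dry cereal and recomputes landscape
  suitability and the fraction of transects predicted occupied, for species
  whose validation AUC ≥ 0.6.

Because the original field censuses are not public, the package ships a
synthetic-data module: phenology-consistent cover tables, Dirichlet
transect compositions, and Bernoulli presence labels with a logistic link
on true suitability, so every stage is testable and signal recovery can be
demonstrated end to end.

## Worked example

```python
import steppehsi as sh

fx = sh.packaged_study_fixture()   # 4 species, 6 covers, reconstructed heights
bundle = sh.build_availability(
    fx.practices, fx.intensity,
    sh.score_height_levels(fx.height_levels, sh.DEFAULT_SCHEME),
)
series = sh.build_suitability_series(fx.requirements, bundle)

row = series[(series.species == "calandra_lark")
             & (series.cover_type == "dry_cereal") & (series.month == 5)].iloc[0]
print(round(row.foraging, 3), round(row.monthly_total, 3))
```

prints `0.278 0.304`: in May a dry extensive cereal field is mostly 50–100 cm
tall, so only a third of it is structurally usable by a Calandra Lark
(structural 0.333), food availability supports a diet score of 0.833, and
foraging suitability is their product 0.278; combined with nesting (0.333)
the monthly total is √(0.278·0.333) ≈ 0.304. The same month on no-till
fallow scores 1.0 throughout.

Projecting fallow-to-cereal conversion over the study landscape
(71% dry cereal, 3% till fallow, 7% no-till fallow, 1% maize, 9% irrigated
cereal, 4% alfalfa, 5% other):

```python
from steppehsi.integration import FULL_SEASON
for p in (0.3, 0.5, 1.0):
    comp = sh.shift_fallow(fx.landscape, sh.ScenarioSpec(p))
    print(p, round(sh.landscape_suitability(series, comp, "stone_curlew",
                                            FULL_SEASON,
                                            fx.requirements.nesting_months["stone_curlew"])["total"], 3))
```

prints `0.3 0.232`, `0.5 0.221`, `1.0 0.193` — season-integrated Stone
Curlew suitability falling from a baseline of 0.249, i.e. by 6.6%, 11.1%
and 22.2% as 30%, 50% and 100% of fallow land becomes cereal.

A complete run (availability → suitability → integration → validation →
sensitivity → scenarios, with CSV artifacts and a manifest) is available
from the shell:

```bash
steppehsi simulate --fixture --seed 1 --n-transects 150 --outdir inputs/
steppehsi run --config config.yaml --outdir results/
```

## Layout

- `src/steppehsi/availability.py` — practices/intensity → food availability;
  height-score normalisation
- `src/steppehsi/resource_model.py` — scoring schemes, requirement tables,
  monthly suitability series
- `src/steppehsi/integration.py` — transect/landscape spatial and temporal
  integration, geometric-mean totals
- `src/steppehsi/evaluation.py` — AUC, optimal thresholds, validation
  reports, scoring-scheme sensitivity analysis
- `src/steppehsi/scenario.py` — fallow-conversion scenarios with an AUC
  robustness gate
- `src/steppehsi/synthetic_data.py` — simulators and the packaged study
  fixture
- `src/steppehsi/io_cli.py` — CSV/YAML I/O, input validation, pipeline,
  `steppehsi` CLI

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
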