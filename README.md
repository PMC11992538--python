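# focalenergy

Time-energy budgets of wintering waterbirds from focal-animal samples.

Behavioral ecologists studying piscivorous waterbirds (the motivating case
is the endangered Chinese merganser, *Mergus squamatus*, wintering on
mountain rivers) score ~5-minute focal observations into an ethogram of ten
behaviors, count successful prey captures, and record habitat covariates.
`focalenergy` turns those records into an energy ledger and runs the full
downstream analysis chain:

1. **Ethogram accounting** — time allocation, bout frequencies, and
   site-level mean ± sd summaries from long-format CSV records.
2. **Bioenergetics** — basal metabolic rate from the Aschoff–Pohl
   allometry `BMR = 307.5·M^0.734` kJ/day (M in kg), activity expenditure
   as behavior-specific BMR multiples times seconds, intake as
   `fish mass × 4000 J/g × 0.8 × successful captures`, and net energy
   `NET = EI − EE`, all also as per-second rates (the optimal-foraging
   currency).
3. **Synthetic data** — a seeded semi-Markov generator whose site profiles
   are calibrated so simulated bout frequencies, time budgets, and
   covariates reproduce the published three-river descriptive tables in
   expectation, with configurable covariate effects for
   parameter-recovery studies.
4. **Screening and GLMs** — log(x+1)/signed-cube-root transforms, Pearson
   screening, a |r| < 0.8 collinearity gate, t / Mann–Whitney site tests,
   and Gaussian identity-link GLMs with likelihood-ratio tests and an
   explained-variance pseudo-R².
5. **Path analysis** — observed-variable recursive SEM fitted by maximum
   likelihood (χ², RMSEA, SRMR, CFI, delta-method indirect effects), with
   preset environment → behavior → energy-rate mediation structures.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

```sh
focalenergy run --mode simulate --seed 1 --out out/
```

simulates the default 87-sample three-river dataset and writes
`budgets.csv`, `summary.csv`, `screen.csv`, `glm_fits.json`,
`pathfit_{ee,ei,net}.json`, and `report.md`. With seed 1 the report's
pooled row reads:

```
ei_rate 34.055 ± 39.011   ee_rate 9.767 ± 0.933   net_rate 24.288 ± 38.897  (J/s)
diving 33.304 ± 17.788 %  vigilance 18.255 ± 5.931 %  swimming 25.640 ± 12.089 %
```

— an expenditure rate pinned near the 8–10 J/s band that the BMR-multiple
model implies for dive-dominated budgets, and intake/net rates whose large
dispersions reflect the all-or-nothing capture counts. The GLM table shows
the expenditure-rate model as `good` (pseudo R² = 0.996 — expenditure is a
near-deterministic function of the time budget), and the three preset path
models fit poorly (e.g. `ee`: χ² = 127.974, df = 45, RMSEA = 0.146,
CFI = 0.878, adequate = no), the expected verdict when environment does
not drive energy rates through behaviors in the generator.

The same verbs work stage-by-stage (`simulate`, `budget`, `summarize`,
`screen`, `glm`, `path`), e.g.

```sh
focalenergy simulate --seed 5 --out data/
focalenergy glm --in data/ --response net_rate \
    --predictors sff,diving,feeding,swimming --transform cuberoot --out fit.json
focalenergy path --in data/ --preset ee --out pathfit.json
```

As a library:

```python
from focalenergy import simulate, pipeline, pathmodel

samples, truth = simulate.simulate_dataset(simulate.default_config(seed=1))
table = pipeline.analysis_table(samples)
fit = pathmodel.fit_path_model(table, pathmodel.preset_path_specs()["ee"])
print(fit.chi2, fit.df, pathmodel.evaluate_fit(fit))
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch under the given seed — simulation,
budgets, summaries, screening, all nine GLMs, and the three path presets —
writing the report bundle to `results/pipeline_out/` and the results
manifest to the `--out` path.

## Data formats

* `samples.csv`: `sample_id,site,bout_index,behavior,duration_s` (one bout
  per row).
* `sample_meta.csv`: per-sample foraging outcome and covariates
  (`success_count,failure_count,avg_fish_weight_g,fish_biomass_g_m2,
  temperature_C,river_width_m,water_depth_m,water_velocity_m_s,
  disturbance_number,disturbance_duration_s,disturbance_distance_m`);
  empty string = missing.
* `params.yaml` (optional): key-wise overrides of the bioenergetic
  constants, e.g. `multipliers: {diving: 3.5}`.
* Path models: presets or a plain-text dialect (`y ~ x1 + x2` regressions,
  `a ~~ b` free covariances).
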