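# reefshift

Quaternary coral-reef habitat dynamics and the historical signal in
present-day reef-fish distributions.

Glacial–interglacial cycles repeatedly redrew the map of shallow tropical
reef habitat: sea-level low stands exposed the shelves reefs grew on, and
cooling pushed the thermal envelope for reef growth toward a shrinking
warm core. Species that disperse poorly may still not have recolonized
all the habitat that reopened after the last deglaciation — a migration
lag written into their present ranges. `reefshift` implements, as a
tested reusable pipeline, the analysis chain used to detect and dissect
that lag in Indo-Pacific reef fishes:

1. **Paleo-habitat reconstruction** — sediment-core SST and sea-level
   series, anchored to a pre-warming SST baseline, give one boolean
   reef-suitability grid per 1,000-year slice under a sweep of thermal
   thresholds (23–28 °C) and a 0–100 m reef depth window.
2. **Isolation from stable areas** — per slice, the least-cost distance
   (8-connected grid graph, great-circle step costs, land as barrier)
   from every cell to the nearest suitable cell; integrated over time as

       IREF = (Σ_t distance to nearest suitable) / (# slices suitable),

   zero in persistent refugia, large where habitat collapsed often and
   refugia were far.
3. **Species distribution models** — per species, a binomial GLM with
   linear + quadratic terms in z-scored SST, CHL, O2, NI, SSS and IREF;
   explained deviance D² = 1 − SS_res/SS_tot partitioned into
   pure-contemporary, shared, pure-historical and unexplained fractions;
   repeated stratified 70/30 split-sample AUC and Moran's I diagnostics.
4. **Trait correlates** — all-subsets OLS with AIC model averaging
   (Akaike weights, summed per-trait importance w_AIC), phylogenetic GLS
   with ML-estimated Pagel's λ (congeneric midpoint grafting for missing
   tips), and upper-quantile regressions (q = .75, .9) that trace the
   triangular size–history envelope.
5. **Assemblage maps** — per-cell means of the historical fraction and of
   body size over occupants, and their cross-cell regression.

Because the underlying compiled datasets are not redistributable, the
package ships a seeded synthetic-world generator (`reefshift.synthetic`)
that emulates all inputs — cores, bathymetry, baseline and contemporary
fields, occurrences with size/mobility-dependent colonization lags,
traits, and a phylogeny with trait signal — together with the ground
truth needed for parameter-recovery tests.

## Worked example

```python
from reefshift import ScenarioConfig, generate_world
from reefshift.pipeline import isolation_sweep, run_sdm_stage, sweep_historical_metrics

world = generate_world(ScenarioConfig(seed=1))
print(len(world.predictors))            # 471 analysis cells (~4 deg)

irefs = isolation_sweep(world)          # one IREF layer per threshold
metrics = sweep_historical_metrics(world, irefs, n_auc_repeats=10, seed=0)
print(metrics["mean_d2_historical"].idxmax())   # 27.0

results = run_sdm_stage(world, iref=irefs[27.0], n_auc_repeats=25, seed=0)
ok = results[results["converged"]]
print(round(ok["d2_full"].mean(), 2))           # 0.41
print(round(ok["pure_historical"].mean(), 3))   # 0.113
```

The sweep recovers the generating threshold (27 °C) because the species
were simulated against the isolation field computed at that threshold;
the full models explain ~0.41 of deviance of which a mean 0.113 is purely
historical, varying strongly across species (5th–95th percentiles
0.022–0.243). Feeding the pure-historical fractions into the trait stage
gives a summed Akaike weight of 1.00 for body size with a negative
averaged slope (−7.2e−4 per cm) and a steeper q = .9 slope (−1.3e−3):
small, sedentary species carry the historical signal, large mobile ones
do not — the triangular pattern the lagged colonization model builds in.
At the assemblage level, cell-mean historical fraction regresses on
cell-mean body size with R² = 0.68 and t = −31.6: the small-fish
assemblages sit near the refugia-rich warm pool.

A command-line interface wraps each stage:

```bash
reefshift simulate --seed 1 --out world/
reefshift sdm --occ world/occurrences.csv --pred world/predictors.csv --out results.csv
reefshift traits --results results.csv --traits world/traits.csv \
    --tree world/phylogeny.nwk --out traits_out/
reefshift all --seed 1 --out run/       # full pipeline + manifest
```

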