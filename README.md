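# pollinet

A tested, reusable pipeline for community-wide analysis of honey-bee
versus wild-pollinator use of introduced and native plants:

- **io_schema** — CSV schemas, typed records, row-level validation, and
  the load-time filters that collapse raw per-group visit counts into a
  canonical (honey bee, wild) pair (ants, true bugs, and outside-flower
  contacts excluded; "excluded"-status taxa dropped).
- **abundance** — per-site floral abundance (floral units / 100 m² /
  week) as mean weekly stem count × study-wide mean floral units per
  stem, with span-based weekly averaging and configurable fallbacks.
- **visitation_models** — negative-binomial (NB2) visitation-rate
  models with a log(floral units × minutes) exposure offset,
  likelihood-ratio tests, per-group abundance slopes, max-|t|
  (Tukey-style) adjusted contrasts, and the knapweed-vs-coflowering
  comparison.
- **preference_null** — the core: abundance-scaled site-week visitation
  matrices, a from-scratch sequential-conditional (Patefield-style)
  sampler for integer contingency tables with fixed marginals, its
  decimal-marginal extension (discretize → sample → rescale), the
  one-row degenerate path, preference = observed − null-mean rate,
  species aggregation, and a crossed-random-intercept preference model.
- **diversity** — Shannon diversity (nats) and richness per netting
  period plus the mixed models relating them to native status and
  floral abundance.
- **pollen** — knapweed-pollen percentages per 300-grain sample, apiary
  means, and across-apiary summaries for bee bread and nectar.
- **synthetic_data** — a generator for all five input tables with
  recorded ground truth (preference weights, abundance exponents, NB
  dispersion), so every stage runs and is testable with no downloads.

## CLI

All stages run from one entry point; global flags are `--config`,
`--seed`, `--out`, `--log-level`.

```sh
pollinet --seed 17 --out run/ simulate      # synthetic inputs + truth.json
pollinet --seed 17 --out run/ abundance     # abundance.csv
pollinet --seed 17 --out run/ rates         # coefficients/contrasts/lrt.csv
pollinet --seed 17 --out run/ preference    # preference_* .csv, model_fit.csv
pollinet --seed 17 --out run/ diversity     # diversity_* .csv
pollinet --seed 17 --out run/ pollen        # pollen summaries
pollinet --seed 17 --out run/ report        # all of the above in order
```

A YAML config can set input CSV paths (`inputs.observations`, …),
generator parameters, and stage options, e.g.:

```yaml
seed: 17
preference:
  scaling: multiply      # multiply | divide | none
  granularity: 10000
  n_null: 1000
abundance:
  span_zeros: skip       # skip | include
models:
  abundance_transform: identity   # identity | log1p | log
```

Every stage writes a `provenance.json` (config snapshot, seed, package
version) beside its outputs, and reruns with the same config + seed are
byte-identical.

## Input CSV schemas

| table | required columns |
| --- | --- |
| `plants.csv` | plant_id, name, native_status (native / introduced / excluded) |
| `observations.csv` | obs_id, site, week, zone, plant_id, floral_units, minutes, visits_<group>… (+ optional outside_<group>…) |
| `stems.csv` | site, week, zone, plant_id, stems |
| `floral_units.csv` | site, date, plant_id, stem_id, floral_units_on_stem |
| `netting.csv` | netting_id, site, week, zone, plant_id, minutes, specimens (semicolon-separated) |
| `pollen.csv` | apiary_id, round, matrix (bee_bread / nectar), knapweed_grains, total_grains |

Visitor groups: honey_bee, other_bee_wasp, fly, butterfly_moth, ant,
true_bug.
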