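# greenwallcba

Economic valuation of green walls as soundscape measures: a tested,
reusable pipeline that

1. **transfers** published hedonic greenery valuations (property-price or
   rent premiums in mixed currencies and years) into common per-m²,
   per-household, per-year EUR unit values (`transfer`);
2. **pools** them by fixed-effect inverse-variance weighting, imputing
   standard errors from intervals, reported SEs, or a default 50% rule
   (`meta`);
3. **monetises** quiet-side noise-level reductions with a per-dB unit
   price, a 45 dB(A) cut-off, a 71 dB(A) validity cap and a 0.3 quiet-side
   conversion factor (`noise`), and amenity/aesthetic benefits from a
   per-m²-per-person unit value (`amenity`);
4. **assembles** annualized costs (recurring investment + maintenance) and
   benefits into benefit-cost ratios for green-wall scenarios (`cba`);
5. **propagates uncertainty** with truncated-normal Monte Carlo
   perturbation of the inputs and reports the central 90% band of the
   simulated B/C distribution (`mc`).

The demonstration inputs (eight reviewed valuation studies, four
green-wall scenarios, CPI and exchange-rate tables) ship as plain-text
package data; `synth` generates synthetic study collections and scenarios
with known ground truth so every stage is testable offline.

## CLI

```sh
greenwallcba transfer --out unit_values.csv          # per-m² unit values
greenwallcba weight --out meta.json --format json    # pooled mean + weights
greenwallcba cba --scenario src/greenwallcba/data/scenarios/demo_3m_high.yaml --out cba.json
greenwallcba mc  --scenario src/greenwallcba/data/scenarios/demo_3m_high.yaml \
                 --out mc.json --seed 1 [--plot band.png]
greenwallcba synth --kind studies --out synth.csv --seed 7
greenwallcba run --out results/ --seed 1             # full pipeline
```

All commands default to the packaged parameter tables, study records and
scenarios; pass `--params`/`--studies`/`--scenario` to use your own.
Logs go to stderr; results go to files, each embedding the package
version, seed and input digests.

## Layout

| module       | role                                               |
|--------------|----------------------------------------------------|
| `finance`    | discounting, annuities, CPI and currency updating  |
| `transfer`   | hedonic study records → EUR per-m² unit values     |
| `meta`       | SE imputation, inverse-variance pooling, influence |
| `noise`      | per-dB noise monetisation with quiet-side factor   |
| `amenity`    | per-m²-per-person amenity monetisation             |
| `cba`        | scenario assembly and benefit-cost ratios          |
| `mc`         | truncated-normal Monte Carlo sensitivity           |
| `synth`      | synthetic generators + packaged fixtures           |
| `io` / `cli` | CSV/YAML/JSON interchange, reports, entry points   |
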