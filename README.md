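# oilknn

Bit-accurate software model of a fixed-point k-nearest-neighbour classifier
for edible-oil quality screening, built around a LUT-level model of an
approximate 8×8 multiplier, together with a synthetic oil-measurement data
generator and weighted evaluation metrics.

## The problem

Recycled "gutter oil" chemically resembles legitimate cooking oil but is
unsafe for consumption. It can be separated from edible oils (capsicol,
soybean, colza, peanut, olive) using a handful of cheap physical
measurements: pH, electrical conductivity, peroxide value (oxidation) and
refractive index, each taken at 25 °C and 60 °C. A small k-NN classifier
over these features is simple enough to run on low-cost embedded hardware,
where multipliers dominate the area and power budget. Replacing the exact
multiplier in the distance unit with an *approximate* one saves resources —
if classification accuracy survives the arithmetic error.

This package models that entire system in software, bit-for-bit:

- **`oilknn.approx_arith`** — a 4×4 multiplier expressed as a network of
  18 lookup tables (LUTs) with an approximate carry unit, composed into an
  8×8 unsigned multiplier that drops the inter-segment carry. Includes
  exact/approximate configurations, exhaustive error profiling, and LUT
  init-vector serialisation.
- **`oilknn.knn_core`** — the fixed-point datapath: min–max quantisation to
  8-bit features, a 600-entry reference ROM, squared-distance computation
  through a pluggable multiplier, and a streaming ping-pong selection
  network (14 cache registers in two parity banks) that keeps the 7 nearest
  neighbours without sorting, followed by a plurality vote with
  deterministic tie-breaking.
- **`oilknn.oilgen`** — a reproducible generator for a 3,600-sample
  synthetic dataset: 15 base oils, seasoned pure oils, pairwise 8:2
  mixtures, and seasoned mixtures, with a contamination-aware labelling
  rule over 6 classes.
- **`oilknn.evalmetrics`** — support-weighted precision/recall/F1, Cohen's
  kappa (raw and rescaled to [0, 1]), and a one-hot bitwise Hamming loss.
- **`oilknn.pipeline`** — dataset CSV I/O, single-feature screening, greedy
  forward feature selection, and an experiment runner comparing exact vs.
  approximate arithmetic end to end.

## Model summary

Given a query vector x ∈ ℝ⁴ (default features: conductivity change
Δσ = σ₆₀ − σ₂₅, peroxide value at 60 °C and 25 °C, conductivity at 60 °C),
each feature is quantised to q ∈ {0,…,255} by min–max scaling fitted on the
training split. The classifier computes, for every ROM entry y,

    d(x, y) = Σᵢ mult(|xᵢ − yᵢ|, |xᵢ − yᵢ|)

where `mult` is either exact or the approximate 8×8 LUT multiplier, selects
the k = 7 smallest distances with the streaming network, and outputs the
plurality class (ties broken by smaller summed distance, then smaller
label). The approximate 8×8 product of a = 16·aH + aL and b = 16·bH + bL is

    P = bits 0–3 of aL·bL
      + ((aL·bL ≫ 4) + aH·bL + aL·bH + ((aH·bH mod 16) ≪ 4) mod 256) ≪ 4
      + (aH·bH ≫ 4) ≪ 12

i.e. the middle-segment carry into the top nibble pair is dropped, so
P ≤ a·b always, with equality exactly when the middle sum fits in 8 bits.
The 4×4 building block comes in two LUT configurations: `functional`
(exact) and `table10` (an area-saving variant whose generate/propagate pair
for the low carry bit is approximated; 62/256 products differ, max error
16).

## Worked example

```
$ oilknn generate --seed 0 --out oil.csv
wrote 3600 samples to oil.csv

$ oilknn evaluate --dataset oil.csv --seed 0 --out report.json
Accuracy                        0.9396
Precision                       0.9439
Recall                          0.9396
F1-score                        0.9418
Kappa                           0.9261
Hamming Loss (one-hot bitwise)  0.0201
Misclassification rate          0.0604

$ oilknn experiment --seed 0 --out exp.json
exact accuracy       0.9396
approximate accuracy 0.9396
accuracy gap         +0.0000
prediction agreement 1.0000

$ oilknn audit-multiplier --bits 4 --config table10
LUTs differing from the functional derivation:
  g0: functional=ff808000 loaded=ffeaea00
  r0: functional=807f7f80 loaded=007f7f80
{
  "error_count": 62,
  "error_rate": 0.2421875,
  "max_absolute_error": 16,
  ...
}
```

Other subcommands: `oilknn fit` (build a quantiser + ROM from a dataset and
write it as hex lines), `oilknn classify` (run the datapath over a CSV),
`oilknn screen` (single-feature and greedy forward selection). All accept
`--help`; `generate` and `experiment` accept a YAML config file.

The same workflows are available as a library:

```python
from oilknn import oilgen, pipeline

report = pipeline.run_experiment(pipeline.ExperimentConfig(
    generator=oilgen.GeneratorConfig(seed=0), split_seed=0, rom_seed=0,
    multiplier="table10",
))
print(report["exact"]["accuracy"], report["accuracy_gap"])
```

## Repository layout

```
src/oilknn/       package modules
tests/            pytest suite (unit, property-based, and acceptance tests)
scripts/          acceptance.py — standalone reproduction script
docs/methods.md   methods and design notes
```
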