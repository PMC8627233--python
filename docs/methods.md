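# Methods and design notes

This document describes the model implemented by `oilknn`, the parameters
it exposes, and the reasoning behind the main design decisions. Nothing
here is an empirical claim beyond what the test suite and
`scripts/acceptance.py` compute.

## 1. Approximate multiplier (`oilknn.approx_arith`)

### 1.1 LUT network for the 4×4 block

A 4-bit × 4-bit unsigned product `n·m` is decomposed by splitting the
multiplier into nibble halves:

    n·m = n·(m1 m0) + (n·(m3 m2) << 2)

Each output bit is produced by one lookup table (LUT). The network uses 18
LUTs:

- `p00…p05` — the six bits of the partial product `n·(m1 m0)`;
- `p11…p15` — bits 1–5 of `n·(m3 m2)` (bit 0 of that product lands on
  output bit 2 and is folded into `pp2`);
- `pp2` — output bit 2, computed carry-free as `p02 XOR (m2·n0)`;
- `g0…g2`, `r0…r2` — generate/propagate signals feeding a 4-bit
  carry-lookahead adder (CLA) that produces output bits 3–7.

The CLA recurrence is `c_{i+1} = g_i OR (r_i AND c_i)` with zero carry into
the chain; the carry discarded by the carry-free `pp2` is folded into the
bit-3 generate/propagate pair (`g0`, `r0`).

**Init-vector convention.** A LUT's inputs are listed most-significant
address bit first (`I5 … I0`, with `I0` the least significant address bit),
and bit *j* of the init constant is the output at address *j*. An input
written `"1"` is tied high; addresses where a tied-high bit is 0 are
unreachable in hardware, and the package fills them with 0 when deriving an
init vector from a Boolean function (`LutConfig.from_function`). This
matches the convention used by the shipped hex constants.

### 1.2 Exact vs. approximate configurations

Two 4×4 configurations ship with the package:

- **`functional`** — every init vector is derived symbolically from the
  partial-product and CLA equations. It reproduces `n·m` exactly on all
  256 input pairs (verified exhaustively in the tests).
- **`table10`** — the hardware configuration. It is identical to
  `functional` except for the bit-3 carry pair: `g0` is `ffeaea00` instead
  of the exact `ff808000`, and `r0` is `007f7f80` instead of the exact
  `807f7f80`. The pair effectively replaces an AND in the folded-carry
  term with an OR and forces one corner case to 0, which shortens the
  logic at the cost of arithmetic error.

Measured exhaustively over all 256 pairs, the `table10` block differs from
the exact product on 62 pairs, with maximum absolute error 16, mean error
distance 3.6875, and a signed-error histogram concentrated on {−8, 0, +16}.
It is not commutative (6 of 256 unordered pairs differ by operand order).
`oilknn audit-multiplier` recomputes these numbers from the loaded
configuration.

The shipped hex constants include two clean-ups of the original listing we
transcribed: one digit that could only validly be `c` (`6ac0`), and three
low-partial-product rows whose input labels were printed as `m2 m1` but
whose init vectors are consistent only with `m1 m0` (the corresponding
high rows correctly read `m3 m2`). Both corrections are forced by the
requirement that every non-carry LUT match its defining equation, which
the test suite checks LUT by LUT.

### 1.3 8×8 composition

For 8-bit operands `a = 16·aH + aL`, `b = 16·bH + bL`, four 4×4 blocks
produce `P0 = aL·bL`, `P1 = aH·bL`, `P2 = aL·bH`, `P3 = aH·bH`. The
composed product takes:

- result bits 0–3 from `P0`;
- result bits 4–11 from `((P0 >> 4) + P1 + P2 + ((P3 & 15) << 4)) mod 256`;
- result bits 12–15 from `P3 >> 4`, **with no carry in** from the middle
  segment.

Dropping that carry is the structural approximation: over exact blocks the
result never exceeds the true product, and equals it exactly when the
middle sum is < 256 (both properties are tested exhaustively over all
65,536 pairs). The worst case is `255·255 → 60929` (exact: 65025). With
`table10` blocks the block-level and structural errors compose.

## 2. Fixed-point k-NN datapath (`oilknn.knn_core`)

| Parameter | Value | Rationale |
|---|---|---|
| k | 7 | fixed by the selection-network depth (7 registers per bank) |
| ROM capacity | 600 entries | 100 per class; fits the stratified training subsample |
| Feature width | 8 bits | matches the 8×8 multiplier |
| `MAX_DISTANCE` | 4·255² = 260100 | sentinel above any reachable 4-feature distance |

**Quantisation.** Min–max scaling per feature, fitted on training data
only, mapping the observed range to [0, 255] with round-half-up
(`floor(x + 0.5)`) and clamping out-of-range queries. A constant training
feature raises `DegenerateFeatureError` rather than silently dividing by
zero.

**ROM construction.** 100 entries per class, drawn from the training split
by seeded subsampling. If a class has fewer than 100 training samples, the
shortfall is redistributed over the remaining classes by largest remainder
so the ROM always holds exactly 600 entries.

**Distance.** `d(x, y) = Σ mult(|xᵢ − yᵢ|, |xᵢ − yᵢ|)` with a pluggable
`mult`. Only squares of byte differences are ever multiplied, so a
256-entry square table fully characterises any multiplier's effect on the
classifier; the batch path exploits this for vectorisation.

**Streaming selection (SNLF).** 14 cache registers in two banks of 7. ROM
entries are streamed in order; entry *i* goes to the even bank when
`i % 2 == 0`, else to the odd bank. A candidate replaces its bank's
current maximum if it beats it; "beats" means strictly smaller distance,
or equal distance with smaller ROM index (keeping results independent of
register layout). The final top-7 is the best 7 of the 14 registers under
the same ordering. The tests prove this equals a full stable sort by
(distance, ROM index) for every query tried, including engineered
duplicate-distance cases.

**Vote.** Plurality over the 7 labels; ties broken by smaller summed
distance, then smaller label index. All tie-breaking is deterministic so
runs are byte-reproducible.

## 3. Synthetic data generator (`oilknn.oilgen`)

The generator emulates a bench-measurement campaign; it is not fitted to
real measurements. Its goal is a dataset with the right *structure*
(classes, ranges, orderings, mixing design) on which the datapath can be
exercised end to end.

**Feature schema** (9 columns): pH at 25 °C and 60 °C; conductivity
(µS/cm) at 25 °C and 60 °C and the difference `dvconduc`; peroxide value
(meq/kg) at 25 °C and 60 °C and the difference `dvox`; refractive index
`reindex`. The two `dv*` columns are derived, so 7 primitive values define
an oil.

**Base oils** (15): 2 gutter, 4 capsicol, 2 soybean, 2 colza, 3 peanut,
2 olive — 6 classes, labelled 0–5 in that order. Each base oil has a
7-value anchor. The pH anchors are the measured values the generator is
designed around (e.g. gutter oils are markedly acidic, pH ≈ 3.4–4.0 at
60 °C, while edible oils sit near neutral). The conductivity, peroxide and
refractive-index anchors are synthetic, chosen to satisfy the qualitative
orderings that make gutter oil detectable: higher conductivity, higher
peroxide value, larger temperature deltas, and slightly elevated
refractive index relative to edible oils. The tests assert these orderings
on generated data rather than any specific numeric value.

**Sampling.** Each drawn sample is its profile's anchor plus independent
Gaussian noise with per-feature scales
`(0.05, 0.05, 0.15, 0.35, 0.15, 0.25, 0.0004)` (pH, pH, µS/cm, µS/cm,
meq/kg, meq/kg, RI units) — roughly 1–3 % of the inter-class separation,
so classes overlap but remain learnable. Values are clipped to physical
ranges (pH ∈ [0, 14], RI ∈ [1.40, 1.50], others ≥ 0).

**Seasonings.** 6 seasonings (salt, MSG, sugar, vinegar, soy sauce,
chicken essence) with additive per-feature effects, applied in the
C(6,4) = 15 four-seasoning combinations.

**Groups.** Group 1: the 15 pure oils. Group 2: 15 oils × 15 seasoning
combos = 225. Group 3: all 15·14 = 210 ordered pairs mixed 8:2 by mass
(features mix linearly in the ratio, with fresh noise scaled by
`mix_noise_factor`). Group 4: 210 mixtures × 15 combos = 3,150. Total
3,600.

**Labelling rule.** A sample is labelled gutter (class 0) if *any*
component is a gutter oil; otherwise it takes the class of its major
(80 %) component. Seasoning never changes the label. This is a food-safety
convention: contamination dominates. The rule fixes the gutter counts per
group by combinatorics alone — 2/15 pure oils, 30/225 in Group 2,
54/210 in Group 3 (2·13 pairs with a gutter major + 13·2 with a gutter
minor + 2·1 gutter–gutter), 810/3,150 in Group 4 — independent of seed.
`scripts/acceptance.py` recomputes these from a full generation run.

**Split.** Stratified 60:40 train/test by class with largest-remainder
rounding: 2,160/1,440 samples, per-class proportions within ±1 sample.

All generation is driven by `numpy.random.default_rng(seed)` and row
construction is order-deterministic, so equal seeds give byte-identical
CSVs.

## 4. Evaluation metrics (`oilknn.evalmetrics`)

All metrics are computed from a 6×6 confusion matrix.

- **Weighted precision/recall/F1.** Per-class values weighted by support
  proportion. Weighted recall telescopes to accuracy (asserted to 1e-12 in
  the tests). A class present in the truth but never predicted has
  undefined precision; it contributes 0 and emits a warning rather than
  failing or silently inflating the score.
- **Cohen's kappa.** Raw κ = (P₀ − Pₑ)/(1 − Pₑ), plus a rescaled
  (κ + 1)/2 ∈ [0, 1] variant reported alongside. The degenerate case
  Pₑ ≥ 1 (a single class on both axes) is defined as raw 0.
- **Hamming loss, one-hot bitwise** (`hamming_loss_eq8`). Labels are
  one-hot encoded over the 6 classes and bitwise disagreement is averaged;
  every misclassification flips exactly 2 of 6 bits, so this equals
  2/6 × the misclassification rate. The plain misclassification rate
  (`zero_one_loss`) is reported alongside, never substituted — the two
  differ by the fixed 1/3 factor and conflating them misstates error
  rates by 3×.

scikit-learn is used in the tests as an independent oracle for precision,
recall and kappa, but is not a runtime dependency.

## 5. Pipeline and experiment conventions (`oilknn.pipeline`)

- Deployed feature set: `("dvconduc", "60ox", "25ox", "60conduc")` — the
  conductivity delta plus the three features that screen strongest
  individually; 4 features match the datapath width.
- `run_experiment` fits one quantiser + ROM on the training split, then
  classifies the test split twice — exact multiplier and the configured
  approximate one — reporting both metric sets, their accuracy gap, and
  the fraction of identical predictions. The exact branch is verified in
  the tests against a brute-force full-sort k-NN oracle.
- Feature screening quantises each candidate feature alone and measures
  held-out accuracy; greedy forward selection extends the best set one
  feature at a time.
- All file writes (CSV, ROM hex, JSON) are atomic (write temp + rename)
  and schema-validated on read; JSON keys are sorted so equal
  configurations give byte-identical reports.

## 6. Numerical choices

- All datapath arithmetic is integer; floats appear only in generation,
  quantiser fitting and metrics.
- Round-half-up (`floor(x + 0.5)`) rather than banker's rounding for
  quantisation, matching hardware adders.
- The batch classifier uses a stable argsort on (distance, index), which
  the tests show is prediction-identical to the streaming network; the
  streaming implementation remains the reference for the hardware
  behaviour.
- Metric identities are asserted to 1e-12 absolute tolerance; frozen
  multiplier error profiles are asserted exactly (they are integer
  counts).

## 7. Limitations

- The generator's conductivity, peroxide and refractive-index anchors are
  synthetic; absolute accuracy numbers on this data say nothing about
  real oils — only the *relative* exact-vs-approximate comparison and the
  structural/combinatorial results transfer.
- Linear feature mixing is a first-order model; real oil blends can mix
  non-linearly (especially conductivity).
- Only the squared-difference use of the multiplier is exercised by the
  classifier; general-purpose error behaviour of the 8×8 composition is
  characterised exhaustively but not consumed downstream.
- The selection network models functional behaviour (register contents per
  cycle), not timing or power.
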