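# Methods

This note documents the models, conventions and numerical choices
behind `fcdbkit`, and what the synthetic fixtures do and do not show
about real data.

## Harmonization model

A source food table is a rectangle of text: one row per food, columns
for metadata and component values. The mapping configuration
(`SourceMapping`) declares, per source, which column holds the food
identifier and FoodEx2 code, which component columns exist, the unit
each is expressed in, the reporting basis (`per_100g` or `per_100mL`)
and two conventions: whether a literal 0 means a logical zero, and
whether the source uses the decimal comma.

Conventions fixed in the core model:

* **Closed unit set** — `g`, `mg`, `µg` for masses; `kcal`, `kJ` for
  energy. IU and percentages are not supported; no density model
  exists, so per-100 g and per-100 mL values are never interconverted
  and unify only within the same basis.
* **Exact mass conversion** — converting between mass units shifts the
  decimal exponent of the value's shortest decimal representation
  (`Decimal(str(v)).scaleb(d)`), not a float multiplication. IEEE
  multiplication by 1000 is *not* exactly invertible (for example
  `0x1.7afa29e023e71p+9 * 1e6 / 1e6` changes the value), whereas the
  decimal shift is bit-exact for every value with ≤ 15 significant
  decimal digits — i.e. every value that entered the pipeline as text,
  which is the only entry path. This matters because the
  management-stage transfer check demands bit-exact round-trips.
* **Energy conversion** uses the thermochemical calorie, 1 kcal =
  4.184 kJ, stated once in `fcdbkit.core.KJ_PER_KCAL`.
* **Value status** — `measured`, `zero`, `logical_zero`, `trace`,
  `missing`. A `trace` computes as 0 but is preserved distinctly in
  storage. Blank cells are `missing`; rows with unparseable FoodEx2
  codes, negative values or out-of-range edible portions are rejected
  to a JSON-lines log, never silently dropped.
* **Exclusion filter** — record classes `branded`, `fortified`,
  `supplement`, `recipe_or_dish` are excluded from database
  construction with the class as the reason; unknown classes are kept
  and logged. Cooked foods and generic unbranded processed foods are
  ordinary generic records.

## Unification

Foods are matched across sources by exact (case-insensitive) FoodEx2
code equality within a basis; no fuzzy or name-based linkage is
attempted. Per component:

1. Plain zeros are recoded as missing before pooling. Experience with
   multi-source compilations shows most literal zeros are
   missing-value stand-ins whose inclusion wrecks dispersion
   statistics and drags medians down.
2. The pool of measured values gives n, mean, median (midpoint of the
   central pair for even n) and sample SD (n−1 denominator; 0 for
   n = 1).
3. The **median** is the chosen value. It is robust to a minority of
   wild source values, which is the dominant error mode when merging
   databases of varying quality.
4. Logical zeros and traces are excluded from the pool but reinstated
   as a consensus 0 when *no* source measured the component and at
   least one coded it as a genuine zero/trace.
5. Chosen values are rounded half-up (via decimal arithmetic, so ties
   are deterministic): 1 decimal for proximates and energy, 3
   significant figures for minerals, vitamins, fatty acids, sterols,
   polyphenols and other components. These digit rules follow the
   common FAO/INFOODS compilation convention.

Singleton foods (one source) pass through with their single values as
chosen values, still rounded. A unified food's name and group come
from the contributing record with the most non-missing components
(ties broken by lexicographic source id); its edible portion is the
median of the contributors' edible portions. The `UnifiedFood` keeps
an edible portion even though it is a consensus object, because the
recipe engine needs a default EP for ingredients that reference
unified foods.

**Outlier screen.** A contributor is flagged when its robust z-score
|v − median| / (1.4826·MAD) exceeds 3.5 (only assignable with ≥ 3
sources; with MAD = 0 any deviating value is flagged), and a whole
component is flagged when CV = sd/mean exceeds 2.0. Both thresholds
are configurable (`OutlierConfig`); 3.5 is the conventional robust
cut-off, and CV > 2 marks dispersion far beyond anything biological
variability explains. Flags are review triggers only — chosen values
are never altered automatically, because such corrections belong to a
human, traceability-driven step.

## Quality control

Checks are pure functions producing findings; severity is `error` for
range and transfer violations and `warning` for implausibility and
outliers (historically resolved by manual review). The
implausible-value screen is decomposed into three individually
toggleable rules: (a) total fat = 0 while a fatty acid or cholesterol
is positive; (b) total fat > 1 g with no fatty-acid or cholesterol
detail at all (suspicious completeness); (c) fibre > 0 in a
fish-group food. Fish foods are recognized by a configurable list of
group-label substrings (default `"fish"`), since food-group labels
vary across sources. The proximate window 95–105 g per 100 g is
treated as a **closed** interval: a food summing to exactly 95 or 105
passes. The transfer check requires bit-exact equality (NaN matching
NaN) between the flat export and the store round-trip, and names every
offending key and cell.

## Energy

General Atwater factors (protein 4, fat 9, carbohydrate 4, alcohol 7
kcal/g) with an optional fibre term of 2 kcal/g, off by default —
whether a fibre term belongs in a given compilation is a policy
choice, so it lives in `AtwaterFactors` where it is auditable. The
carbohydrate input is selectable (`CHOAVL` available carbohydrate by
default, `CHOCDF` by difference as the alternative). Recalculated
energy is returned alongside any source energy value; nothing is
overwritten.

## Recipe engine (EuroFIR mixed method)

Yield factors apply once at recipe level, keyed by cooking method (and
optionally food group; the default lookup uses the wildcard group,
since a whole recipe rarely has a single well-defined group).
Retention factors apply per ingredient per component with
most-specific-wins precedence: (tagname, group, method) >
(tagname, ANY, method) > (class, group, method) > (class, ANY,
method) > 1.0. RF > 1 is allowed (gains during cooking, e.g. fat
uptake in frying). Water is not separately rebalanced beyond the yield
factor. A component missing from some — but not all — ingredients
contributes 0 and is marked *partial* in the result rather than
propagating missingness, which would systematically underestimate
intake; it stays missing only when no ingredient has it. Every
computed amount carries a factor audit (EP, RF rule, YF used).

## Storage

A single-file SQLite database with eight interrelated tables;
`schema.sql` is the single DDL source. Contributor provenance is
denormalized into `component_values` (one row per contributing source
record, repeating the per-component statistics), keeping the table
count at eight while guaranteeing every unified value references at
least one original (source, food id) pair — logical-zero consensus
values carry their zero-coding sources as contributors. Values are
REAL (binary64), so round-trips are bit-exact. A server-based RDBMS
would add nothing at desk scale; the DDL is portable if one is needed.

## Synthetic fixtures

`generate_sources` emulates the multi-source compilation setting:

* Ground truth per food: proximate proportions drawn from a Dirichlet
  over (water, protein, fat, carbohydrate, ash) scaled to 100 g
  (alcohol is a logical zero; fibre 0.5–3 g except in fish, meat,
  dairy and fats, where it is a logical zero), fatty-acid detail
  consistent with total fat, cholesterol only in animal-source groups,
  polyphenols only in plant groups, micronutrients lognormal around
  per-component typical scales. Truth values are pre-rounded by the
  standard rounding rules so noiseless recovery can be exact.
* Source values: truth × exp(σZ) with σ = √ln(1 + CV²) — positive,
  median-unbiased multiplicative noise. Default CV 0.15, a realistic
  between-database spread for composition values.
* Planted defects: with the configured rates a cell becomes a literal
  0 or is multiplied by the outlier factor (default ×10); every
  planted position is recorded, and nothing else deviates from
  truth × noise, so defect labels are exhaustive and exclusive.
* Default conditions: 7 sources, 60 foods, 30 components, 60 %
  overlap, 5 % zeros, 5 % outliers. One source codes zeros as logical
  zeros; under `unit_scramble`, odd-numbered sources report
  mg-standard components in grams with the mapping declaring the true
  unit.

`generate_recipes` emits random recipes plus expected results computed
by an independent straight-line implementation of the mixed-method
formula (its own factor resolution via explicit dict lookups), which
serves as the oracle for the engine.

What the fixtures do **not** emulate: real marginal distributions of
any national FCDB, correlated errors between sources, coding mistakes
(wrong FoodEx2 assignments), name/translation noise, or systematic
unit errors undeclared in the mapping. Passing tests therefore
demonstrate correctness of the pipeline's arithmetic, matching,
robustness and bookkeeping under controlled corruption — not that any
particular real compilation is error-free.

## Verification sizes and numerical tolerances

The acceptance script and test suite use: 50 random fixtures (2–10
sources × 10–200 foods × 13–50 components) for oracle equivalence of
the unifier, bit-exact after identical rounding (the oracle rounds via
exact rational arithmetic, a different code path from the production
decimal quantization); 7 × 60 × 120 at full overlap for median-vs-mean
recovery (≥ 119 scored components); 100 random recipes at relative
tolerance 1e-9 against the closed-form oracle, with mass bookkeeping
(cooked weight = YF·Σ raw·EP) required exactly; 1000 random macro
vectors for the energy closed form, required exactly (identical
operation order); and byte-identical JSON/CSV exports across two full
pipeline runs for determinism. These sizes keep the whole verification
under a minute while leaving every property statistically
unambiguous.

## Known limitations

* FoodEx2 codes are validated opaque tokens; the official catalogue,
  facets and hierarchy are not consulted, so miscoded but well-formed
  codes unify incorrectly — exactly as they would for a human compiler.
* No record linkage beyond exact code equality; no translation.
* Unification assumes sources are exchangeable; no source weighting
  or quality scoring is applied.
* The proximate check needs `CHOCDF` (total carbohydrate); sources
  reporting only available carbohydrate will under-sum unless the
  compiler maps a derived column.
* Deduplication *within* a source is logged but not resolved.
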