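# Methods

`recall24` implements an interviewer-administered, automated 24-hour dietary
recall (24HR) engine of the kind used in nutritional epidemiology in
Spanish-speaking settings: a multiple-pass interview workflow over a local
food catalogue, household-measure portion quantification, cooking-method
semantics, and a fixed-schema nutrient-totals report. This note documents
the model, the numerical choices, and what the synthetic data does and does
not emulate.

## The five-pass interview model

A recall session is a state machine over the passes

    QUICK_LIST → FORGOTTEN → TIME_OCCASION → DETAIL → FINAL_PROBE → FINALIZED

with strictly forward transitions; the final probe may drop back into
detailing (items recalled at the end are appended undetailed and detailed in
place). The pass semantics:

* **Quick list** — free-text labels only, in report order; no quantification.
* **Forgotten foods** — a fixed, ordered category checklist (sweets, sodas,
  snacks, dressings, broths, condiments, others) is returned once and marked
  asked; re-probing after the time pass is a state error.
* **Time and occasion** — 24-hour clock times (`HH:MM[:SS]`, stored
  zero-filled), free-text place with two canonical values ("At home",
  "Out of home"), and an occasion from a configurable vocabulary
  (Breakfast/Lunch/Snack/Dinner/Dessert by default). The empty occasion is
  always legal: water between meals carries none.
* **Detailed cycle** — each entry resolves to a catalogue food (optionally
  through a drop-down variant), is quantified through the equivalence table,
  and may trigger the cooking-oil rule (below).
* **Final probe / finalisation** — finalisation succeeds exactly when every
  entry is detailed; the error otherwise names each undetailed label. The
  output is an immutable stored recall; later corrections operate on the
  stored copy by delete-and-reload through the normal detailing path, with
  an audit note.

Whether the listing passes are strictly ordered or interleaved in live
interviews is genuinely open; the machine enforces the strict order above as
a deliberate, testable stand-in, and the randomized-sequence property test
pins exactly this contract.

Sessions are scriptable: a JSON transcript of operations replays headlessly
(`recall24 interview`), which is how the worked-recall example and all
end-to-end tests run.

## Portions and the equivalence table

Portion statements come in three modes: a count (fractions allowed) of one
of 16 registered household measures; a count of sized units (small / medium
/ large / unit); or an exact amount in g, mL, mg, μg or IU (the last three
for supplements, which pass through as entries with absent profiles).
Conversion multiplies the quantity by the stored per-measure or per-unit
weight using exact rational arithmetic, with a single half-up rounding to
one decimal at the output. Exactness matters: 2.5 coffee spoons of sugar at
2 g per spoon must print 5.0 g, never 4.999…; the rounding rule itself is a
documented choice (the convention that reproduces the worked example at one
printed decimal).

Liquids are carried in millilitres through the same machinery — the
conversion output for a liquid *is* its mL figure — and the report consumes
that number directly against per-100 mL profiles. An exact-mL statement for
a non-liquid food with a declared density converts to grams through it;
density defaults to 1.0 g/mL otherwise.

Missing (food, measure) rows are not defaulted: a measure is simply not
offered for a food without a weight on file, and conversion raises a
"no equivalence" error naming both.

**Group inference.** Foods whose utensil weights were never weighed directly
take their 16-measure vector from a density group (flours, oils, …): the
componentwise mean of the measured members, scaled by a reference ratio
anchored on whatever measures the target shares with the group (mean
target/group-mean ratio), or ratio 1 flagged `unscaled` when there is no
anchor. The method presumes near-exact proportionality of utensil weights
within a group; `group_correlation` verifies it as pairwise Pearson r over
shared measures (≥ 3 required), flagging any pair under 0.99.

## Recipes and the portion-share equation

Amounts consumed from multi-portion preparations use

    quantity = (portions consumed / total portions prepared) × total ingredient amount

in exact rationals, rounded to two decimals on output. Standard recipes
(predefined ingredient lists) expand through this equation per ingredient,
with exclusions (a vegetarian respondent drops the animal fat) refused for
ingredients marked structural. Compound recipes — built ad hoc from the
interview — expand identically; the substitution rationale is kept in an
`origin_note`. Fractional portions consumed are allowed: the equation is
well-defined on rationals even though worked examples use integers.
Unit-denominated ingredients ("4 tomatoes, medium") convert to grams only at
expansion time, keeping the stored recipe faithful to the interview wording.

## Cooking semantics

Frying adds an automatic oil entry worth 10% of the food's net weight;
baking, 3%; boiling, steaming and sautéing add nothing (sautéed catalogue
items embed their oil in the food description — whether sautéing should also
auto-add oil is not settled, and the default here is no). The fractions are
config-overridable but overrides are logged, since they change totals. The
oil entry inherits the food's time/place/occasion and must resolve to a food
in the oils group. Applying a method to an already-cooked catalogue item is
refused: the rule fires once, at detailed loading, and compounding it would
double-count oil.

Cooked counterparts of raw foods are selected only within the same
composition source (`source_tag`), via the `<raw-id>-<method>` id convention
or the raw food's variant list; there is deliberately no raw→cooked yield or
nutrient-retention model — raw and cooked are distinct catalogue items.

## The 49-component report

The report schema is a fixed, ordered list of 49 components (water in mL,
energy in kcal, macronutrients and fatty-acid classes in g, minerals in mg
except selenium in μg, vitamins in their conventional units; vitamin D is
stored in μg with a ×40 IU view). Totals are `Σ grams_i × density_i,c /
100` at full precision, rounded to three decimals only when formatted.
A component absent from a food's source contributes zero and increments that
component's coverage-gap count — reports therefore separate "measured zero"
from "no data" instead of silently conflating them. A protein split by the
food group's broad origin (animal / vegetable) is computed as an
experimental extra; it is not part of the 49-row schema.

Participant names never appear in report output: a deterministic code
(questionnaire number, recall index, and a SHA-256 prefix over the full
triple) stands in, injective over its inputs and structurally unable to
contain a name substring.

## Synthetic data

No real composition content ships with the package; the generators stand in
for it, deterministically under a seed (byte-identical re-runs).

* **Composition database** — defaults of 968 foods and 100 standard recipes,
  matching the scale of the catalogue the engine is modelled on. Nutrient
  densities are drawn from log-uniform ranges per component class so totals
  are well-conditioned; each trace component is absent with probability
  0.05 to exercise coverage accounting; energy is derived from the stored
  macronutrients through the Atwater factors (4/4/9/7 kcal/g) with jitter
  well inside a 1% tolerance. A quarter of raw foods get a cooked
  counterpart sharing their source tag.
* **Equivalence table** — 100 foods × 16 utensils (1,600 weights) in density
  groups of 2–6; each member's vector is a group base vector times a
  per-food scale with multiplicative noise of sd ≤ 1%, which keeps all
  within-group correlations ≥ 0.99 by construction. The generator records
  its ground-truth scales so inference tests have an exact oracle.
* **Worked recall** — a hand-written 24-entry interview transcript with the
  per-measure weights each row implies; replaying it reproduces the grams
  column digit for digit. Its demo catalogue's nutrient values are synthetic
  placeholders (Atwater-consistent, plausible magnitudes), *not* real
  composition data — so report tests are oracle-based and no published
  nutrient total is asserted or reproduced.

What passing tests therefore show: the interview mechanics, conversion
arithmetic, rule constants and aggregation are correct. What they do not
show: agreement with any real composition database, realistic inter-nutrient
correlations (generated densities are independent across components), or
behaviour under the messiness of live interviews (misheard names, foods
truly absent from the catalogue).

## Numerical and design choices

* Matching is Unicode-NFKD + combining-mark-strip + casefold throughout
  (accented Spanish names are first-class); search ranks exact name >
  name prefix > all-tokens-substring, ties broken lexicographically, so
  results are deterministic.
* Quantities, weights and fractions stay `Fraction`s until a single
  rounding at each output boundary (1 decimal for grams, 2 for portion
  shares, 3 for report formatting); floats given as inputs are interpreted
  by their printed decimal (`repr`), not their binary expansion.
* Persistence is canonical (sorted rows, shortest round-trip float form), so
  save→load→save is byte-stable; `foods.csv` carries a `variants` column in
  addition to the documented food fields because drop-down variants must
  survive round trips.
* `food_id` is a human-readable slug, never reused; deletes are refused
  while recipes or variant lists still reference the food.
* The component schema is fixed at the 49 rows of the report table; prose
  descriptions of "50 nutrients" count energy or split lutein+zeaxanthin
  differently, and the enumerated table wins.
* Test and acceptance runs use scaled-down generator sizes (60–500 foods)
  where the full 968-food scale adds nothing to the property being checked;
  the published-scale defaults are exercised once each in the loader-count
  and equivalence-scale tests.

## Known limitations

No gross-vs-net refuse factors, no cooking yield or nutrient retention, no
dietary-reference-intake comparison, no usual-intake modelling over repeated
recalls, and no interactive prompt UI (transcript replay only). Supplements
are carried as entries but contribute nothing to totals without profiles.
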