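# recall24

A scriptable engine for **interviewer-administered 24-hour dietary recalls
(24HR)** — the structured interview nutritionists and epidemiologists use to
capture everything a respondent ate and drank over the previous day. It is
aimed at research settings (FFQ validation, intervention monitoring,
clinical follow-up) where the recall must be driven through the five-pass
multiple-pass protocol, quantified against local household measures, and
reduced to nutrient totals — reproducibly and without a GUI.

The engine provides, as a Python library plus a thin CLI:

* a **food catalogue** (simple and complex foods, Spanish names with accents
  as first-class data, drop-down variants, raw/cooked counterparts) with
  per-100 g / per-100 mL nutrient profiles over a fixed 49-component schema,
  canonical CSV/JSON persistence, accent-insensitive ranked search, and
  logged add/modify/delete with referential integrity;
* the **five-pass interview state machine** — quick list → forgotten-foods
  probe → time/place/occasion → detailed cycle → final probe — with
  completeness-enforced finalisation and headless replay from JSON
  transcripts;
* **portion quantification**: 16 registered household measures, sized units
  and exact amounts, converted to net grams by exact rational arithmetic
  (`grams = quantity × table weight`, half-up to 1 decimal), plus
  group-based inference of unmeasured foods' utensil weights with the
  within-group Pearson r ≥ 0.99 proportionality check;
* **recipe handling** with the portion-share equation
  `quantity = (portions consumed / total portions) × total ingredient amount`,
  ingredient exclusion and interview-built compound recipes;
* **cooking transforms**: fried and baked foods automatically add an oil
  entry worth 10% and 3% of the food's net weight respectively; cooked
  variants are selected within the same composition source;
* a **49-component nutrient-totals report** (totals = Σ grams × density/100,
  absent data counted as coverage gaps, 3-decimal formatting) with
  anonymised participant codes;
* deterministic **synthetic generators** for all of the above — no licensed
  composition content is bundled or required.

## Worked example

The package ships a 24-entry worked recall (one day: breakfast, lunch,
dinner, water between meals) as a replayable transcript with a small demo
catalogue and the equivalence weights its rows imply:

```bash
python - <<'EOF'
import json
from recall24.fixtures import worked_recall_fixture
from recall24.database import save_database
from recall24.measures import save_equivalences
fx = worked_recall_fixture()
save_database(fx.db, "demo"); save_equivalences(fx.eq, "demo")
open("demo/transcript.json", "w").write(json.dumps(fx.transcript))
EOF
recall24 validate demo
recall24 interview demo/transcript.json --db demo --out demo/recall.json --report demo/report.csv
```

prints

```
ok: 27 foods, 1 recipes, 13 equivalence rows, 7 unit weights
ok: recall demo-recall-1 with 24 entries
```

The recall's grams column comes out of the conversion arithmetic, e.g. raw
oats reported as 3 tablespoons at 6 g per tablespoon → 18.0 g; ground white
sugar as 2.5 coffee spoons at 2 g per spoon → 5.0 g (exact rationals, one
half-up rounding). The first lines of `demo/report.csv`:

```
component_id,name,amount,unit,entries_without_data
water,Water,1941.827,mL,0
energy,Energy,1809.849,kcal,0
protein,Protein,88.750,g,5
fat,Total lipid (fat),65.705,g,8
```

Amounts are the day's totals in each component's canonical unit; the last
column counts entries whose composition source had no value for that
component (the demo profiles are synthetic placeholders, so gap counts are
non-trivial). The report always has exactly 49 rows in fixed order.

Full-scale synthetic fixtures (968 foods, 100 recipes, a 100 × 16
equivalence table) are one command away:

```bash
recall24 fixtures make --seed 1 --out fixtures/
recall24 validate fixtures/
```

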