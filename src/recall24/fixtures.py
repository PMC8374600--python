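"""Synthetic data generators: composition databases, equivalence tables, and
the worked-recall demo.

Nothing in this package ships real composition data — national composition
tables are licensed content and out of scope. Instead this module generates,
deterministically under a seed:

* a **composition database** at the scale of the real catalogue (968 foods,
  100 standard recipes by default) whose nutrient densities are drawn from
  log-uniform ranges per component class and whose energy obeys the Atwater
  identity 4·protein + 4·carbohydrate + 9·fat + 7·alcohol within a
  configured tolerance;
* an **equivalence table** of 100 foods × 16 utensils (1,600 weights)
  organised in density groups, each member's weight vector a scaled,
  lightly-noised copy of a group base vector so that within-group pairwise
  correlations stay ≥ 0.99 — the structure the group-inference machinery
  assumes;
* the **worked-recall fixture**: a 24-entry interview transcript with the
  per-measure weights each printed row implies, plus a small hand-written
  demo catalogue (synthetic profiles, not real composition values) rich
  enough to exercise variants, cooked-variant selection, automatic oil, and
  a standard recipe with an excludable animal fat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction
from pathlib import Path
import json

import numpy as np

from .components import COMPONENT_IDS, atwater_energy
from .database import FoodDatabase, FoodItem, NutrientProfile, save_database
from .errors import ValidationError
from .measures import EquivalenceTable, MEASURE_REGISTRY, save_equivalences
from .recipes import Ingredient, StandardRecipe
from .text import normalize

__all__ = [
    "GeneratorConfig",
    "generate_composition_db",
    "EquivalenceFixture",
    "generate_equivalence_table",
    "WorkedRecallFixture",
    "worked_recall_fixture",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generators; defaults match the published scale."""

    seed: int = 0
    n_foods: int = 968
    n_recipes: int = 100
    n_eq_foods: int = 100
    n_groups: int = 20
    noise_sd: float = 0.01       # multiplicative sd for group-weight scaling
    atwater_tol: float = 0.01    # relative tolerance of the energy identity

    def __post_init__(self):
        if self.n_foods < 1 or self.n_recipes < 0 or self.n_groups < 1:
            raise ValidationError("generator sizes must be positive")
        if not (0 <= self.noise_sd <= 0.01):
            raise ValidationError(
                "noise_sd must lie in [0, 0.01]: larger noise breaks the "
                "within-group correlation guarantee"
            )
        if self.atwater_tol <= 0:
            raise ValidationError("atwater_tol must be > 0")


# ---------------------------------------------------------------------------
# composition database

_NOUNS = [
    "arroz", "harina", "pan", "queso", "carne", "pollo", "pescado", "manzana",
    "banana", "naranja", "tomate", "lechuga", "zanahoria", "papa", "batata",
    "zapallo", "lenteja", "garbanzo", "poroto", "yogur", "leche", "aceite",
    "galletita", "torta", "empanada", "milanesa", "guiso", "sopa", "jugo",
    "gaseosa", "café", "té", "mate", "azúcar", "miel", "mermelada", "manteca",
    "crema", "huevo", "choclo", "acelga", "espinaca", "cebolla", "ajo",
    "pimiento", "durazno", "pera", "uva", "sandía", "melón",
]
_QUALIFIERS = [
    "blanco", "integral", "casero", "light", "fresco", "seco", "dulce",
    "salado", "criollo", "común", "entero", "descremado", "fortificado",
    "natural", "tostado",
]
_GROUPS = [
    "flour", "oils", "dairy", "fruits", "vegetables", "meat", "beverages",
    "sweets", "cereals", "legumes",
]
_SOURCES = ["Survey", "SR Legacy", "Foundation", "SARA"]
_COOK_METHODS = ["boiled", "fried", "baked", "steamed", "sauteed"]

# log-uniform (lo, hi) density ranges per trace component, canonical units
_TRACE_RANGES = {
    "calcium": (1, 300), "iron": (0.1, 10), "magnesium": (1, 150),
    "phosphorus": (10, 400), "potassium": (20, 800), "sodium": (1, 1000),
    "zinc": (0.05, 8), "copper": (0.01, 1), "manganese": (0.01, 3),
    "selenium": (0.5, 40), "vitamin_c": (0.1, 60), "thiamin": (0.01, 0.8),
    "riboflavin": (0.01, 0.8), "niacin": (0.05, 10),
    "pantothenic_acid": (0.05, 3), "vitamin_b6": (0.01, 1),
    "folate": (1, 200), "choline": (1, 100), "vitamin_b12": (0.01, 3),
    "vitamin_a_rae": (1, 300), "retinol": (0.5, 300),
    "carotene_beta": (1, 2000), "carotene_alpha": (0.5, 300),
    "cryptoxanthin_beta": (0.1, 50), "lycopene": (0.5, 3000),
    "lutein_zeaxanthin": (1, 1000), "vitamin_e": (0.01, 5),
    "vitamin_d": (0.01, 5), "vitamin_k": (0.1, 100),
    "cholesterol": (0.5, 150),
}


def _slug(name: str) -> str:
    return normalize(name).replace(" ", "-")


def _round3(x: float) -> float:
    return float(round(x, 3))


def _random_profile(rng: np.random.Generator, group: str, liquid: bool,
                    atwater_tol: float) -> NutrientProfile:
    shares = rng.dirichlet([8.0, 1.5, 1.5, 3.0, 1.0, 4.0])
    water = _round3(shares[0] * 100)
    protein = _round3(shares[1] * 100)
    fat = _round3(shares[2] * 100)
    carb = _round3(shares[3] * 100)
    other = shares[4] * 100
    fiber = _round3(0.4 * other)
    ash = _round3(0.2 * other)
    sugars = _round3(carb * rng.uniform(0, 0.8))
    alcohol = 0.0
    if group == "beverages" and rng.uniform() < 0.15:
        alcohol = _round3(rng.uniform(0.5, 6.0))
    # energy from the *stored* (rounded) macros, jittered well inside tolerance
    energy = _round3(atwater_energy(protein, carb, fat, alcohol)
                     * (1 + rng.uniform(-0.4, 0.4) * atwater_tol))

    values: dict[str, float] = {
        "water": water, "energy": energy, "protein": protein, "fat": fat,
        "ash": ash, "carbohydrate": carb, "fiber": fiber, "sugars": sugars,
        "alcohol": alcohol,
    }
    fa = rng.dirichlet([1.0, 1.0, 1.0]) * fat * 0.9
    values["sfa"], values["mufa"], values["pufa"] = map(_round3, fa)
    values["la_18_2"] = _round3(0.6 * values["pufa"])
    values["ala_18_3"] = _round3(0.1 * values["pufa"])
    for cid, share in (("epa_20_5", 0.01), ("dpa_22_5", 0.005), ("dha_22_6", 0.02)):
        values[cid] = _round3(share * values["pufa"])
    for cid, (lo, hi) in _TRACE_RANGES.items():
        if rng.uniform() < 0.05:
            continue  # absent from the composition source
        values[cid] = _round3(float(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    values["caffeine"] = _round3(rng.uniform(10, 60)) if group == "beverages" else 0.0
    values["theobromine"] = _round3(rng.uniform(50, 200)) if group == "sweets" and rng.uniform() < 0.3 else 0.0
    basis = "per_100_mL" if liquid else "per_100_g"
    return NutrientProfile(values=values, basis=basis)


def generate_composition_db(config: GeneratorConfig) -> FoodDatabase:
    """Random but reproducible food catalogue with recipes.

    Raw/cooked counterpart pairs share a ``source_tag`` and follow the
    ``<raw-id>-<method>`` id convention the cooked-variant selector expects.
    Roughly one food in forty carries a drop-down variant list. Every food's
    energy satisfies the Atwater identity within ``config.atwater_tol``.
    """
    rng = np.random.default_rng(config.seed)
    foods: dict[str, FoodItem] = {}
    i = 0
    while len(foods) < config.n_foods:
        i += 1
        noun = _NOUNS[int(rng.integers(len(_NOUNS)))]
        qual = _QUALIFIERS[int(rng.integers(len(_QUALIFIERS)))]
        name = f"{noun.capitalize()} {qual} {i}"
        fid = _slug(name)
        group = _GROUPS[int(rng.integers(len(_GROUPS)))]
        source = _SOURCES[int(rng.integers(len(_SOURCES)))]
        liquid = group == "beverages"
        kind = "complex" if rng.uniform() < 0.2 else "simple"
        synonyms = [f"{qual} {noun}"] if rng.uniform() < 0.3 else []
        foods[fid] = FoodItem(
            food_id=fid, name=name, synonyms=synonyms, kind=kind, group=group,
            state="raw", source_tag=source, is_liquid=liquid,
            density_g_per_mL=_round3(rng.uniform(0.9, 1.2)) if liquid else None,
            profile=_random_profile(rng, group, liquid, config.atwater_tol),
        )
        if len(foods) < config.n_foods and not liquid and rng.uniform() < 0.25:
            method = _COOK_METHODS[int(rng.integers(len(_COOK_METHODS)))]
            cid = f"{fid}-{method}"
            foods[cid] = FoodItem(
                food_id=cid, name=f"{name} ({method})", kind=kind, group=group,
                state="cooked", cooking_method=method, source_tag=source,
                profile=_random_profile(rng, group, False, config.atwater_tol),
            )

    ids = list(foods)
    for k in range(0, len(ids), 40):
        fid = ids[k]
        targets = [ids[int(rng.integers(len(ids)))] for _ in range(2)]
        foods[fid].variants = [(f"variante {j + 1}", t) for j, t in enumerate(dict.fromkeys(targets))]

    recipes: dict[str, StandardRecipe] = {}
    for r in range(config.n_recipes):
        n_ing = int(rng.integers(2, 7))
        member_ids = list(dict.fromkeys(
            ids[int(rng.integers(len(ids)))] for _ in range(n_ing)))
        ingredients = [
            Ingredient(food_id=mid, amount_g=Fraction(Decimal(str(round(float(rng.uniform(10, 300)), 1)))),
                       excludable=bool(j > 0 or rng.uniform() < 0.5))
            for j, mid in enumerate(member_ids)
        ]
        rid = f"recipe-{r + 1:03d}"
        recipes[rid] = StandardRecipe(
            recipe_id=rid, name=f"Receta estándar {r + 1}", ingredients=ingredients,
            yield_portions=int(rng.integers(1, 9)))

    return FoodDatabase(foods=foods, recipes=recipes,
                        version=f"fixture-seed{config.seed}")


# ---------------------------------------------------------------------------
# grouped equivalence table

@dataclass
class EquivalenceFixture:
    """A generated equivalence table plus its ground truth for oracle tests."""

    table: EquivalenceTable
    groups: dict[str, list[str]]          # group name -> member food ids
    scales: dict[str, float]              # food id -> true scale factor
    base_vectors: dict[str, dict[int, float]]  # group name -> base 16-vector


def generate_equivalence_table(config: GeneratorConfig) -> EquivalenceFixture:
    """Equivalence table of ``n_eq_foods`` × 16 utensil weights in density groups.

    Each group has a base weight vector over the 16 measures; each member's
    vector is the base scaled by a per-food factor with multiplicative noise
    of sd ``noise_sd`` (≤ 1%), preserving within-group Pearson r ≥ 0.99.
    """
    rng = np.random.default_rng(config.seed + 1)
    measures = sorted(MEASURE_REGISTRY)
    sizes = _partition(config.n_eq_foods, config.n_groups, rng)
    table = EquivalenceTable()
    fixture = EquivalenceFixture(table=table, groups={}, scales={}, base_vectors={})
    for gi, gsize in enumerate(sizes):
        gname = f"group-{gi + 1:02d}"
        base = {m: float(np.exp(rng.uniform(np.log(2.0), np.log(400.0)))) for m in measures}
        fixture.base_vectors[gname] = base
        members = []
        for j in range(gsize):
            fid = f"eq-{gname}-f{j + 1}"
            scale = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
            fixture.scales[fid] = scale
            for m in measures:
                noise = 1.0 + config.noise_sd * float(rng.standard_normal())
                w = max(base[m] * scale * noise, 1e-3)
                table.rows[(fid, m)] = Fraction(Decimal(str(round(w, 4))))
                table.provenance[(fid, m)] = "weighed" if j == 0 else "inferred"
            members.append(fid)
        fixture.groups[gname] = members
    return fixture


def _partition(n: int, k: int, rng: np.random.Generator) -> list[int]:
    # k parts of 2..6 summing to n where feasible, echoing groups of 2-6 foods
    sizes = [max(2, n // k)] * k
    deficit = n - sum(sizes)
    idx = 0
    while deficit != 0:
        step = 1 if deficit > 0 else -1
        if 2 <= sizes[idx % k] + step:
            sizes[idx % k] += step
            deficit -= step
        idx += 1
    return sizes


# ---------------------------------------------------------------------------
# the worked-recall demo

def _profile(basis="per_100_g", **values) -> NutrientProfile:
    p, c, f = values.get("protein", 0.0), values.get("carbohydrate", 0.0), values.get("fat", 0.0)
    values.setdefault("energy", atwater_energy(p, c, f, values.get("alcohol", 0.0)))
    return NutrientProfile(values=values, basis=basis)


def _demo_foods() -> dict[str, FoodItem]:
    """Hand-written demo catalogue. All nutrient values are synthetic
    placeholders chosen only to be plausible and Atwater-consistent — they are
    not real composition data."""
    def food(fid, name, **kw):
        return FoodItem(food_id=fid, name=name, **kw)

    items = [
        food("water", "Agua", synonyms=["Water (mL)"], group="beverages",
             is_liquid=True, profile=_profile("per_100_mL", water=100.0)),
        food("oats", "Avena cruda", synonyms=["Raw oats"], group="cereals",
             source_tag="SR Legacy",
             profile=_profile(water=8.0, protein=13.0, fat=6.5, carbohydrate=68.0,
                              fiber=10.0, sugars=1.0, ash=1.8, iron=4.2, magnesium=138.0)),
        food("milk-powder", "Leche entera en polvo", synonyms=["Whole milk powder"],
             group="dairy", source_tag="Survey",
             profile=_profile(water=2.5, protein=26.0, fat=26.5, carbohydrate=38.0,
                              sugars=38.0, ash=6.0, calcium=912.0)),
        food("raisins", "Pasas de uva", synonyms=["Raisins"], group="fruits",
             source_tag="SR Legacy",
             profile=_profile(water=15.0, protein=3.0, fat=0.5, carbohydrate=79.0,
                              sugars=59.0, fiber=4.5, potassium=744.0)),
        food("sugar", "Azúcar blanca molida", synonyms=["Ground white sugar"],
             group="sweets", source_tag="SR Legacy",
             profile=_profile(water=0.02, carbohydrate=99.8, sugars=99.8)),
        food("coffee", "Café marrón", synonyms=["Brown coffee (mL)"], group="beverages",
             is_liquid=True, source_tag="Survey",
             profile=_profile("per_100_mL", water=99.0, protein=0.1, carbohydrate=0.2,
                              caffeine=40.0)),
        food("water-cookie", "Galletita de agua sin sal",
             synonyms=["Unsalted water cookie"], kind="complex", group="cereals",
             source_tag="SARA",
             profile=_profile(water=5.0, protein=10.0, fat=12.0, carbohydrate=70.0,
                              sodium=420.0)),
        food("creamy-cheese", "Queso cremoso", synonyms=["Creamy cheese"],
             group="dairy", source_tag="Survey",
             profile=_profile(water=52.0, protein=19.0, fat=24.0, carbohydrate=2.0,
                              calcium=550.0, sodium=480.0)),
        food("beef-lean", "Carne vacuna magra cruda",
             synonyms=["Beef, separable lean only, raw"], group="meat",
             source_tag="Survey",
             profile=_profile(water=73.0, protein=21.5, fat=4.5, iron=1.9, zinc=4.1)),
        food("potato", "Papa cruda", synonyms=["Raw potato"], group="vegetables",
             source_tag="Survey",
             profile=_profile(water=79.0, protein=2.0, fat=0.1, carbohydrate=17.5,
                              fiber=2.1, potassium=425.0)),
        FoodItem(food_id="potato-boiled", name="Papas hervidas en cubos",
                 synonyms=["Boiled potatoes in cubes"], group="vegetables",
                 state="cooked", cooking_method="boiled", source_tag="Survey",
                 profile=_profile(water=77.0, protein=1.9, fat=0.1, carbohydrate=20.0,
                                  fiber=1.8, potassium=379.0)),
        FoodItem(food_id="potato-fried", name="Papas fritas en cubos",
                 synonyms=["Fried potatoes in cubes"], group="vegetables",
                 state="cooked", cooking_method="fried", source_tag="Foundation",
                 profile=_profile(water=60.0, protein=2.5, fat=10.0, carbohydrate=25.0)),
        food("tomato", "Tomate en cubos", synonyms=["Tomato cut into cubes"],
             group="vegetables", source_tag="SR Legacy",
             profile=_profile(water=94.5, protein=0.9, fat=0.2, carbohydrate=3.9,
                              lycopene=2573.0, vitamin_c=13.7)),
        food("egg", "Huevo", synonyms=["Egg"], group="eggs", source_tag="Survey",
             profile=_profile(water=76.0, protein=12.6, fat=9.5, carbohydrate=0.7,
                              cholesterol=372.0, choline=294.0)),
        food("mantecol", "Mantecol (porción)", synonyms=["Mantecol (portion)"],
             kind="complex", group="sweets", source_tag="SARA",
             profile=_profile(water=2.0, protein=12.0, fat=30.0, carbohydrate=52.0,
                              sugars=45.0)),
        food("pizza-slice", "Porción de pizza (huevo, tomate y aceitunas)",
             synonyms=["Three slices of pizza (egg, tomato and olives)"],
             kind="complex", group="cereals", source_tag="SARA",
             profile=_profile(water=48.0, protein=11.0, fat=9.8, carbohydrate=28.0,
                              sodium=600.0)),
        food("milk-fluid", "Leche fluida entera",
             synonyms=["Fluid whole cow's milk (mL)"], group="dairy",
             is_liquid=True, source_tag="Survey", density_g_per_mL=1.03,
             profile=_profile("per_100_mL", water=88.0, protein=3.3, fat=3.5,
                              carbohydrate=4.9, sugars=4.9, calcium=119.0)),
        food("soymilk", "Leche de soja", synonyms=["Soymilk"], group="beverages",
             is_liquid=True, source_tag="SR Legacy",
             profile=_profile("per_100_mL", water=92.0, protein=2.9, fat=1.6,
                              carbohydrate=3.0)),
        food("milk", "Leche", synonyms=["Milk"], group="dairy", is_liquid=True,
             source_tag="Survey",
             variants=[("milk powder", "milk-powder"), ("whole milk", "milk-fluid"),
                       ("soymilk", "soymilk")],
             profile=_profile("per_100_mL", water=88.0, protein=3.3, fat=3.5,
                              carbohydrate=4.9)),
        food("bread-slice", "Pan (rebanada)", synonyms=["Bread (slice / slice)"],
             kind="complex", group="cereals", source_tag="SARA",
             profile=_profile(water=36.0, protein=9.0, fat=3.2, carbohydrate=49.0,
                              sodium=490.0)),
        food("spread-cheese", "Queso untable entero",
             synonyms=["Whole spreadable cheese"], group="dairy", source_tag="Survey",
             profile=_profile(water=60.0, protein=8.0, fat=23.0, carbohydrate=3.5)),
        food("honey", "Miel", synonyms=["Honey"], group="sweets", source_tag="SR Legacy",
             profile=_profile(water=17.0, protein=0.3, carbohydrate=82.0, sugars=82.0)),
        food("jam", "Mermelada de frutas", synonyms=["Fruit jam"], group="sweets",
             source_tag="SARA",
             profile=_profile(water=30.0, protein=0.4, fat=0.1, carbohydrate=69.0,
                              sugars=49.0)),
        food("oil-sunflower", "Aceite de girasol", synonyms=["Sunflower oil"],
             group="oils", source_tag="SR Legacy",
             profile=_profile(fat=100.0, vitamin_e=41.1, sfa=10.3, mufa=57.3,
                              pufa=28.9, la_18_2=28.9)),
        food("flour-wheat", "Harina de trigo", synonyms=["Wheat flour"],
             group="flour", source_tag="SARA",
             profile=_profile(water=12.0, protein=10.3, fat=1.0, carbohydrate=73.0,
                              fiber=2.7)),
        food("beef-fat", "Grasa vacuna", synonyms=["Animal fat"], group="oils",
             source_tag="SARA",
             profile=_profile(water=2.0, protein=1.5, fat=94.0, cholesterol=99.0)),
        food("margarine", "Margarina vegetal", synonyms=["Plant margarine"],
             group="oils", source_tag="SARA",
             profile=_profile(water=16.0, protein=0.2, fat=80.0, carbohydrate=0.7)),
    ]
    return {f.food_id: f for f in items}


#: (label, time, place, occasion, food_id, portion-spec, printed grams)
_WORKED_RECALL_ROWS: list[tuple] = [
    ("Water (mL)", "7:30:00", "At home", "", "water",
     {"mode": "household_measure", "measure_id": 8, "quantity": "1"}, 300.0),
    ("Raw oats", "8:00:00", "At home", "Breakfast", "oats",
     {"mode": "household_measure", "measure_id": 11, "quantity": "3"}, 18.0),
    ("Whole milk powder", "8:00:00", "At home", "Breakfast", "milk-powder",
     {"mode": "household_measure", "measure_id": 13, "quantity": "2"}, 4.0),
    ("Raisins", "8:00:00", "At home", "Breakfast", "raisins",
     {"mode": "unit", "size": "medium", "quantity": "10"}, 4.0),
    ("Ground white sugar", "8:00:00", "At home", "Breakfast", "sugar",
     {"mode": "household_measure", "measure_id": 14, "quantity": "1"}, 2.0),
    ("Brown coffee (mL)", "8:00:00", "At home", "Breakfast", "coffee",
     {"mode": "household_measure", "measure_id": 8, "quantity": "1"}, 300.0),
    ("Unsalted water cookie", "8:00:00", "At home", "Breakfast", "water-cookie",
     {"mode": "unit", "size": "unit", "quantity": "5"}, 30.0),
    ("Creamy cheese", "8:00:00", "At home", "Breakfast", "creamy-cheese",
     {"mode": "household_measure", "measure_id": 13, "quantity": "5"}, 41.1),
    ("Ground white sugar", "8:00:00", "At home", "Breakfast", "sugar",
     {"mode": "household_measure", "measure_id": 14, "quantity": "2.5"}, 5.0),
    ("Water (mL)", "9:30:00", "At home", "", "water",
     {"mode": "household_measure", "measure_id": 5, "quantity": "1"}, 285.0),
    ("Beef, separable lean only, raw", "13:00:00", "At home", "Lunch", "beef-lean",
     {"mode": "unit", "size": "medium", "quantity": "1"}, 110.0),
    ("Boiled potatoes in cubes", "13:00:00", "At home", "Lunch", "potato-boiled",
     {"mode": "household_measure", "measure_id": 15, "quantity": "1"}, 103.0),
    ("Tomato cut into cubes", "13:00:00", "At home", "Lunch", "tomato",
     {"mode": "household_measure", "measure_id": 15, "quantity": "1"}, 82.0),
    ("Egg", "13:00:00", "At home", "Lunch", "egg",
     {"mode": "unit", "size": "unit", "quantity": "1"}, 42.0),
    ("Unsalted water cookie", "13:00:00", "At home", "Lunch", "water-cookie",
     {"mode": "unit", "size": "unit", "quantity": "2"}, 12.0),
    ("Mantecol (portion)", "13:00:00", "At home", "Dessert", "mantecol",
     {"mode": "unit", "size": "unit", "quantity": "1"}, 20.0),
    ("Three slices of pizza (egg, tomato and olives)", "19:00:00", "Out of home",
     "Dinner", "pizza-slice",
     {"mode": "unit", "size": "unit", "quantity": "3"}, 301.5),
    ("Water (mL)", "19:00:00", "Out of home", "Dinner", "water",
     {"mode": "household_measure", "measure_id": 5, "quantity": "1"}, 285.0),
    ("Brown coffee (mL)", "19:00:00", "Out of home", "Dinner", "coffee",
     {"mode": "household_measure", "measure_id": 8, "quantity": "1"}, 300.0),
    ("Fluid whole cow's milk (mL)", "19:00:00", "Out of home", "Dinner", "milk-fluid",
     {"mode": "household_measure", "measure_id": 11, "quantity": "2"}, 12.4),
    ("Bread (slice / slice)", "19:00:00", "Out of home", "Dinner", "bread-slice",
     {"mode": "unit", "size": "unit", "quantity": "4"}, 48.0),
    ("Whole spreadable cheese", "19:00:00", "Out of home", "Dinner", "spread-cheese",
     {"mode": "household_measure", "measure_id": 14, "quantity": "4"}, 7.9),
    ("Honey", "19:00:00", "Out of home", "Dinner", "honey",
     {"mode": "household_measure", "measure_id": 13, "quantity": "2"}, 12.6),
    ("Fruit jam", "19:00:00", "Out of home", "Dinner", "jam",
     {"mode": "household_measure", "measure_id": 13, "quantity": "2"}, 10.0),
]

# per-measure / per-unit weights implied by the worked-recall rows
# (printed grams ÷ quantity, exact decimals)
_WORKED_RECALL_MEASURE_WEIGHTS: dict[tuple[str, int], str] = {
    ("water", 8): "300", ("water", 5): "285",
    ("oats", 11): "6", ("milk-powder", 13): "2",
    ("sugar", 14): "2", ("coffee", 8): "300",
    ("creamy-cheese", 13): "8.22",
    ("potato-boiled", 15): "103", ("tomato", 15): "82",
    ("milk-fluid", 11): "6.2",
    ("spread-cheese", 14): "1.975",
    ("honey", 13): "6.3", ("jam", 13): "5",
}
_WORKED_RECALL_UNIT_WEIGHTS: dict[tuple[str, str], str] = {
    ("raisins", "medium"): "0.4",
    ("water-cookie", "unit"): "6",
    ("beef-lean", "medium"): "110",
    ("egg", "unit"): "42",
    ("mantecol", "unit"): "20",
    ("pizza-slice", "unit"): "100.5",
    ("bread-slice", "unit"): "12",
}


@dataclass
class WorkedRecallFixture:
    """Demo catalogue + equivalences + transcript of the worked recall."""

    db: FoodDatabase
    eq: EquivalenceTable
    transcript: list[dict]
    expected_grams: list[float] = field(default_factory=list)
    expected_rows: list[tuple] = field(default_factory=list)


def worked_recall_fixture() -> WorkedRecallFixture:
    """Build the 24-entry worked-recall fixture.

    Replaying the transcript against the demo catalogue and the implied
    equivalence weights reproduces the printed grams column row for row.
    """
    foods = _demo_foods()
    recipes = {
        "masa-criolla": StandardRecipe(
            recipe_id="masa-criolla", name="Masa criolla",
            ingredients=[
                Ingredient(food_id="flour-wheat", amount_g=Fraction(500), excludable=False),
                Ingredient(food_id="water", amount_g=Fraction(250)),
                Ingredient(food_id="beef-fat", amount_g=Fraction(100)),
            ],
            yield_portions=4),
    }
    db = FoodDatabase(foods=foods, recipes=recipes, version="demo-1")
    eq = EquivalenceTable(
        rows={k: Fraction(Decimal(v)) for k, v in _WORKED_RECALL_MEASURE_WEIGHTS.items()},
        unit_weights={k: Fraction(Decimal(v)) for k, v in _WORKED_RECALL_UNIT_WEIGHTS.items()},
        provenance={k: "literature" for k in _WORKED_RECALL_MEASURE_WEIGHTS},
    )

    transcript: list[dict] = [{
        "op": "start_session", "participant_id": "p001", "name": "demo participant",
        "interviewer_id": "int01", "recall_date": "2020-06-15",
        "day_type": "habitual", "session_id": "demo-recall-1",
    }]
    for label, *_ in _WORKED_RECALL_ROWS:
        transcript.append({"op": "add_quick_item", "label": label})
    transcript.append({"op": "forgotten_probe"})
    for i, (_, time, place, occasion, *_rest) in enumerate(_WORKED_RECALL_ROWS):
        transcript.append({
            "op": "assign_time_place_occasion", "index": i, "time": time,
            "place": place, "occasion": occasion,
        })
    for i, (_, _, _, _, fid, portion, _) in enumerate(_WORKED_RECALL_ROWS):
        transcript.append({
            "op": "detail_entry", "index": i, "food_id": fid, "portion": portion,
        })
    transcript.append({"op": "begin_final_probe"})
    transcript.append({"op": "finalize"})

    return WorkedRecallFixture(
        db=db, eq=eq, transcript=transcript,
        expected_grams=[row[-1] for row in _WORKED_RECALL_ROWS],
        expected_rows=list(_WORKED_RECALL_ROWS),
    )


# ---------------------------------------------------------------------------
# bundle writer (backs `recall24 fixtures make`)

def write_fixture_bundle(out_dir: str | Path, config: GeneratorConfig) -> dict[str, Path]:
    """Write foods.csv, recipes.json, equivalences.csv, unit_weights.csv and
    transcript.json under *out_dir*; returns the paths written.

    The composition database and equivalence table are generated from the
    config; the transcript (and the unit weights it relies on) come from the
    worked-recall demo, whose foods are appended to the generated catalogue so
    the bundle is self-consistent.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    demo = worked_recall_fixture()
    gen_db = generate_composition_db(config)
    for fid, food in demo.db.foods.items():
        gen_db.foods.setdefault(fid, food)
    for rid, recipe in demo.db.recipes.items():
        gen_db.recipes.setdefault(rid, recipe)
    gen_db.check_integrity()
    save_database(gen_db, out_dir)

    eq_fixture = generate_equivalence_table(config)
    table = eq_fixture.table
    table.rows.update(demo.eq.rows)
    table.provenance.update(demo.eq.provenance)
    table.unit_weights.update(demo.eq.unit_weights)
    save_equivalences(table, out_dir)

    transcript_path = out_dir / "transcript.json"
    with open(transcript_path, "w", encoding="utf-8", newline="") as fh:
        json.dump(demo.transcript, fh, ensure_ascii=False, indent=2)
        fh.write("\n")
    return {
        "foods": out_dir / "foods.csv",
        "recipes": out_dir / "recipes.json",
        "equivalences": out_dir / "equivalences.csv",
        "unit_weights": out_dir / "unit_weights.csv",
        "transcript": transcript_path,
    }
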