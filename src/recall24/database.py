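"""Food catalogue: simple/complex foods, nutrient profiles, persistence.

The catalogue is the backbone of the recall engine: every interview entry,
recipe ingredient and report line resolves to a :class:`FoodItem` here. Foods
carry a per-100 g (per-100 mL for liquids) :class:`NutrientProfile` over the
canonical 49-component schema, Spanish display names with accents as
first-class data, and optional drop-down *variants* (e.g. "milk" resolving to
milk powder / whole milk / soymilk).

Persistence is two UTF-8 text files in a directory: ``foods.csv`` (one row
per food, fixed column order, the 49 component columns by component id) and
``recipes.json`` (standard recipes plus the database version string and the
append-only modification log). Saving is canonical — rows sorted by food id,
numbers in shortest round-trip form — so save→load→save is byte-stable.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from fractions import Fraction
from pathlib import Path

from .components import COMPONENT_IDS
from .errors import IntegrityError, ParseError, ValidationError
from .recipes import Ingredient, StandardRecipe
from .text import normalize

__all__ = [
    "NutrientProfile",
    "FoodItem",
    "FoodDatabase",
    "load_database",
    "save_database",
    "search_foods",
    "mutate_database",
    "resolve_variant",
    "COOKING_METHODS",
    "FOOD_COLUMNS",
]

COOKING_METHODS = ("fried", "baked", "boiled", "steamed", "sauteed")

#: Normative column order of foods.csv (the 49 component columns follow).
FOOD_COLUMNS = (
    "food_id", "name", "synonyms", "kind", "group", "state", "cooking_method",
    "source_tag", "is_liquid", "density_g_per_mL", "basis", "variants",
)


@dataclass(frozen=True)
class NutrientProfile:
    """Component densities per 100 g (``per_100_g``) or 100 mL (``per_100_mL``).

    ``values`` holds only the components with known data; a component absent
    from the map is *absent from the source*, which is distinct from a
    measured zero and is surfaced as a coverage gap in reports.
    """

    values: dict[str, float] = field(default_factory=dict)
    basis: str = "per_100_g"

    def __post_init__(self):
        if self.basis not in ("per_100_g", "per_100_mL"):
            raise ValidationError(f"unknown profile basis {self.basis!r}")
        unknown = set(self.values) - set(COMPONENT_IDS)
        if unknown:
            raise ValidationError(f"unknown nutrient component(s): {sorted(unknown)}")
        for cid, v in self.values.items():
            if v is None or v < 0:
                raise ValidationError(f"component {cid!r}: value must be a number >= 0, got {v!r}")
        object.__setattr__(self, "values", dict(self.values))

    def get(self, component_id: str) -> float | None:
        """Density of one component, or None when absent from the source."""
        if component_id not in COMPONENT_IDS:
            raise ValidationError(f"unknown nutrient component {component_id!r}")
        return self.values.get(component_id)

    @property
    def absent_components(self) -> tuple[str, ...]:
        return tuple(c for c in COMPONENT_IDS if c not in self.values)


@dataclass
class FoodItem:
    """One catalogue food, simple (single ingredient) or complex (a few)."""

    food_id: str
    name: str
    profile: NutrientProfile
    synonyms: list[str] = field(default_factory=list)
    kind: str = "simple"
    group: str = ""
    state: str = "raw"
    cooking_method: str | None = None
    source_tag: str = ""
    is_liquid: bool = False
    density_g_per_mL: float | None = None
    variants: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.food_id:
            raise ValidationError("food_id must be non-empty")
        if not self.name.strip():
            raise ValidationError(f"food {self.food_id!r}: name must be non-empty")
        if self.kind not in ("simple", "complex"):
            raise ValidationError(f"food {self.food_id!r}: kind must be simple|complex")
        if self.state not in ("raw", "cooked"):
            raise ValidationError(f"food {self.food_id!r}: state must be raw|cooked")
        if self.cooking_method in ("", "none"):
            self.cooking_method = None
        if self.state == "cooked" and self.cooking_method is None:
            raise ValidationError(f"food {self.food_id!r}: a cooked item needs a cooking_method")
        if self.state == "raw" and self.cooking_method is not None:
            raise ValidationError(f"food {self.food_id!r}: a raw item cannot have a cooking_method")
        if self.cooking_method is not None and self.cooking_method not in COOKING_METHODS:
            raise ValidationError(
                f"food {self.food_id!r}: cooking_method must be one of {COOKING_METHODS}"
            )
        if self.is_liquid and self.profile.basis != "per_100_mL" and self.density_g_per_mL is None:
            raise ValidationError(
                f"food {self.food_id!r}: a liquid needs a per_100_mL profile or a density"
            )
        if self.density_g_per_mL is not None and self.density_g_per_mL <= 0:
            raise ValidationError(f"food {self.food_id!r}: density must be > 0")


@dataclass
class FoodDatabase:
    """The full catalogue plus standard recipes and a modification log."""

    foods: dict[str, FoodItem] = field(default_factory=dict)
    recipes: dict[str, StandardRecipe] = field(default_factory=dict)
    version: str = "0"
    log: list[tuple[str, str, str]] = field(default_factory=list)  # (timestamp, op, food_id)

    def __post_init__(self):
        self.check_integrity()

    def check_integrity(self) -> None:
        """Raise IntegrityError on any dangling recipe-ingredient or variant reference."""
        for rid, recipe in self.recipes.items():
            for ing in recipe.ingredients:
                if ing.food_id not in self.foods:
                    raise IntegrityError(
                        f"recipe {rid!r}: ingredient {ing.food_id!r} not in food catalogue"
                    )
        for fid, food in self.foods.items():
            for label, target in food.variants:
                if target not in self.foods:
                    raise IntegrityError(
                        f"food {fid!r}: variant {label!r} points to unknown food {target!r}"
                    )

    def recipes_using(self, food_id: str) -> list[str]:
        return [rid for rid, r in self.recipes.items()
                if any(ing.food_id == food_id for ing in r.ingredients)]


# ---------------------------------------------------------------------------
# persistence

def _fmt_float(v: float | None) -> str:
    return "" if v is None else repr(float(v))


def _food_to_row(food: FoodItem) -> list[str]:
    row = [
        food.food_id,
        food.name,
        ";".join(food.synonyms),
        food.kind,
        food.group,
        food.state,
        food.cooking_method or "none",
        food.source_tag,
        "true" if food.is_liquid else "false",
        _fmt_float(food.density_g_per_mL),
        food.profile.basis,
        ";".join(f"{label}={fid}" for label, fid in food.variants),
    ]
    row.extend(_fmt_float(food.profile.get(cid)) for cid in COMPONENT_IDS)
    return row


def _row_to_food(row: dict[str, str], line: int) -> FoodItem:
    def bad(field_: str, msg: str):
        raise ParseError(msg, line=line, field=field_)

    values: dict[str, float] = {}
    for cid in COMPONENT_IDS:
        cell = row.get(cid, "").strip()
        if cell:
            try:
                values[cid] = float(cell)
            except ValueError:
                bad(cid, f"not a number: {cell!r}")
    density = row.get("density_g_per_mL", "").strip()
    variants = []
    for part in filter(None, row.get("variants", "").split(";")):
        if "=" not in part:
            bad("variants", f"expected 'label=food_id', got {part!r}")
        label, _, fid = part.partition("=")
        variants.append((label, fid))
    try:
        return FoodItem(
            food_id=row["food_id"],
            name=row["name"],
            synonyms=[s for s in row.get("synonyms", "").split(";") if s],
            kind=row.get("kind", "simple"),
            group=row.get("group", ""),
            state=row.get("state", "raw"),
            cooking_method=row.get("cooking_method") or None,
            source_tag=row.get("source_tag", ""),
            is_liquid=row.get("is_liquid", "false") == "true",
            density_g_per_mL=float(density) if density else None,
            variants=variants,
            profile=NutrientProfile(values=values, basis=row.get("basis", "per_100_g")),
        )
    except ValidationError as e:
        raise ParseError(str(e), line=line) from e


def save_database(db: FoodDatabase, directory: str | Path) -> None:
    """Write ``foods.csv`` and ``recipes.json`` canonically under *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = list(FOOD_COLUMNS) + list(COMPONENT_IDS)
    with open(directory / "foods.csv", "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for fid in sorted(db.foods):
            writer.writerow(_food_to_row(db.foods[fid]))
    payload = {
        "version": db.version,
        "log": [list(entry) for entry in db.log],
        "recipes": [
            {
                "recipe_id": r.recipe_id,
                "name": r.name,
                "yield_portions": r.yield_portions,
                "ingredients": [
                    {
                        "food_id": ing.food_id,
                        **({"amount_g": str(ing.amount_g)} if ing.amount_g is not None
                           else {"amount_units": str(ing.amount_units), "size": ing.size}),
                        "excludable": ing.excludable,
                    }
                    for ing in r.ingredients
                ],
            }
            for rid, r in sorted(db.recipes.items())
        ],
    }
    with open(directory / "recipes.json", "w", encoding="utf-8", newline="") as fh:
        json.dump(payload, fh, ensure_ascii=False, indent=2, sort_keys=True)
        fh.write("\n")


def load_database(directory: str | Path) -> FoodDatabase:
    """Load a catalogue directory written by :func:`save_database`.

    Raises :class:`ParseError` naming the offending line/field on malformed
    input and :class:`IntegrityError` on duplicate food ids or dangling
    references.
    """
    directory = Path(directory)
    foods_path = directory / "foods.csv"
    if not foods_path.exists():
        raise ParseError(f"missing foods file: {foods_path}")
    foods: dict[str, FoodItem] = {}
    with open(foods_path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError("foods.csv is empty (no header)", line=1)
        missing_cols = [c for c in FOOD_COLUMNS if c not in reader.fieldnames]
        if missing_cols:
            raise ParseError(f"foods.csv missing column(s) {missing_cols}", line=1)
        for i, row in enumerate(reader, start=2):
            food = _row_to_food(row, line=i)
            if food.food_id in foods:
                raise IntegrityError(f"duplicate food_id {food.food_id!r} (line {i})")
            foods[food.food_id] = food

    recipes: dict[str, StandardRecipe] = {}
    version = "0"
    log: list[tuple[str, str, str]] = []
    recipes_path = directory / "recipes.json"
    if recipes_path.exists():
        with open(recipes_path, encoding="utf-8") as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as e:
                raise ParseError(f"recipes.json: {e}", line=e.lineno) from e
        version = str(payload.get("version", "0"))
        log = [tuple(entry) for entry in payload.get("log", [])]
        for spec in payload.get("recipes", []):
            ingredients = []
            for item in spec["ingredients"]:
                if "amount_g" in item:
                    ingredients.append(Ingredient(
                        food_id=item["food_id"], amount_g=Fraction(item["amount_g"]),
                        excludable=item.get("excludable", True)))
                else:
                    ingredients.append(Ingredient(
                        food_id=item["food_id"], amount_units=Fraction(item["amount_units"]),
                        size=item.get("size"), excludable=item.get("excludable", True)))
            recipe = StandardRecipe(
                recipe_id=spec["recipe_id"], name=spec["name"],
                ingredients=ingredients, yield_portions=spec.get("yield_portions", 1))
            if recipe.recipe_id in recipes:
                raise IntegrityError(f"duplicate recipe_id {recipe.recipe_id!r}")
            recipes[recipe.recipe_id] = recipe

    return FoodDatabase(foods=foods, recipes=recipes, version=version, log=log)


# ---------------------------------------------------------------------------
# search

def search_foods(db: FoodDatabase, query: str) -> list[FoodItem]:
    """Rank catalogue foods against a free-text query.

    Matching is case- and accent-insensitive. Ranking tiers:

    1. exact normalised name,
    2. normalised name prefix,
    3. every query token appears as a substring of the name or a synonym.

    Ties break lexicographically by name, so results are deterministic.
    """
    q = normalize(query)
    if not q:
        raise ValidationError("search query must be non-empty")
    q_tokens = q.split()
    scored: list[tuple[int, str, str]] = []
    for fid, food in db.foods.items():
        name_n = normalize(food.name)
        haystack = " | ".join([name_n, *(normalize(s) for s in food.synonyms)])
        if name_n == q:
            tier = 0
        elif name_n.startswith(q):
            tier = 1
        elif all(t in haystack for t in q_tokens):
            tier = 2
        else:
            continue
        scored.append((tier, name_n, fid))
    scored.sort()
    return [db.foods[fid] for _, _, fid in scored]


# ---------------------------------------------------------------------------
# mutation

def mutate_database(db: FoodDatabase, action: str, payload: FoodItem | str) -> FoodDatabase:
    """Apply an add / modify / delete to the catalogue, in place, with logging.

    ``delete`` is refused while any standard recipe still references the
    food; the error names the referencing recipes.
    """
    stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    if action == "add":
        if not isinstance(payload, FoodItem):
            raise ValidationError("add requires a FoodItem payload")
        if payload.food_id in db.foods:
            raise IntegrityError(f"food_id {payload.food_id!r} already exists")
        db.foods[payload.food_id] = payload
        db.log.append((stamp, "add", payload.food_id))
    elif action == "modify":
        if not isinstance(payload, FoodItem):
            raise ValidationError("modify requires a FoodItem payload")
        if payload.food_id not in db.foods:
            raise IntegrityError(f"food_id {payload.food_id!r} does not exist")
        db.foods[payload.food_id] = payload
        db.log.append((stamp, "modify", payload.food_id))
    elif action == "delete":
        food_id = payload.food_id if isinstance(payload, FoodItem) else payload
        if food_id not in db.foods:
            raise IntegrityError(f"food_id {food_id!r} does not exist")
        users = db.recipes_using(food_id)
        if users:
            raise IntegrityError(
                f"cannot delete {food_id!r}: referenced by recipe(s) {users}"
            )
        referrers = [fid for fid, f in db.foods.items() if fid != food_id
                     and any(t == food_id for _, t in f.variants)]
        if referrers:
            raise IntegrityError(
                f"cannot delete {food_id!r}: listed as a variant of {referrers}"
            )
        del db.foods[food_id]
        db.log.append((stamp, "delete", food_id))
    else:
        raise ValidationError(f"unknown action {action!r}; expected add|modify|delete")
    return db


def resolve_variant(db: FoodDatabase, food: FoodItem, option_label: str = "") -> FoodItem:
    """Resolve a drop-down option of *food* to its concrete FoodItem.

    A food without variants resolves to itself for an empty option label.
    For a food with variants an option must be chosen; an unknown (or empty)
    label raises an error listing the available options.
    """
    label_n = normalize(option_label) if option_label else ""
    if not food.variants:
        if label_n == "":
            return food
        raise ValidationError(
            f"food {food.name!r} has no variant options (got {option_label!r})"
        )
    for label, target in food.variants:
        if normalize(label) == label_n:
            return db.foods[target]
    options = ", ".join(label for label, _ in food.variants)
    raise ValidationError(
        f"unknown option {option_label!r} for {food.name!r}; available options: {{{options}}}"
    )
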