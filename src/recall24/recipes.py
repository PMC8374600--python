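"""Recipes: predefined standard preparations and interview-built compound ones.

A *standard recipe* is a traditional preparation with a predefined
ingredient list; at interview time individual ingredients may be excluded
(e.g. dropping the animal fat from a dough for a vegetarian respondent). A
*compound recipe* is constructed ad hoc from what the respondent describes
when no catalogue recipe matches.

Amounts consumed from a multi-portion preparation follow the portion-share
equation::

    quantity = (portions consumed / total portions prepared) × total ingredient amount

evaluated in exact rational arithmetic and rounded to 2 decimals only on
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from numbers import Rational

from .errors import IntegrityError, ValidationError

__all__ = [
    "Ingredient",
    "StandardRecipe",
    "CompoundRecipe",
    "CompoundPortionQuery",
    "compound_portion_quantity",
    "expand_standard_recipe",
    "build_compound_recipe",
]


def _as_fraction(x) -> Fraction:
    """Exact Fraction from int/Fraction/Decimal/str/float (floats via str repr)."""
    if isinstance(x, Rational):
        return Fraction(x)
    if isinstance(x, Decimal):
        return Fraction(x)
    if isinstance(x, float):
        # treat the printed decimal, not the binary expansion, as the datum
        return Fraction(Decimal(repr(x)))
    return Fraction(x)


@dataclass(frozen=True)
class Ingredient:
    """One ingredient of a preparation.

    ``amount_g`` is the total amount in the whole preparation. Alternatively
    an ingredient may be stated in units (``amount_units`` + ``size``, e.g.
    "4 tomatoes, medium"); unit amounts are converted to grams only at
    expansion time so the recipe stays faithful to the interview wording.
    """

    food_id: str
    amount_g: Fraction | None = None
    amount_units: Fraction | None = None
    size: str | None = None
    excludable: bool = True

    def __post_init__(self):
        if (self.amount_g is None) == (self.amount_units is None):
            raise ValidationError(
                f"ingredient {self.food_id!r}: exactly one of amount_g / amount_units required"
            )
        if self.amount_g is not None:
            object.__setattr__(self, "amount_g", _as_fraction(self.amount_g))
            if self.amount_g <= 0:
                raise ValidationError(f"ingredient {self.food_id!r}: amount must be > 0")
        else:
            object.__setattr__(self, "amount_units", _as_fraction(self.amount_units))
            if self.amount_units <= 0:
                raise ValidationError(f"ingredient {self.food_id!r}: amount must be > 0")


@dataclass
class StandardRecipe:
    recipe_id: str
    name: str
    ingredients: list[Ingredient]
    yield_portions: int = 1

    def __post_init__(self):
        if not self.ingredients:
            raise ValidationError(f"recipe {self.recipe_id!r}: needs at least one ingredient")
        if int(self.yield_portions) != self.yield_portions or self.yield_portions < 1:
            raise ValidationError(f"recipe {self.recipe_id!r}: yield_portions must be a positive integer")
        self.yield_portions = int(self.yield_portions)


@dataclass
class CompoundRecipe:
    name: str
    ingredients: list[Ingredient]
    total_portions: int = 1
    origin_note: str = ""

    def __post_init__(self):
        if not self.ingredients:
            raise ValidationError(f"compound recipe {self.name!r}: needs at least one ingredient")


@dataclass(frozen=True)
class CompoundPortionQuery:
    """Inputs to the portion-share equation (amounts in g or counted units)."""

    portion_consumed: Fraction
    total_portions: Fraction
    total_amount_of_ingredient: Fraction

    def __post_init__(self):
        object.__setattr__(self, "portion_consumed", _as_fraction(self.portion_consumed))
        object.__setattr__(self, "total_portions", _as_fraction(self.total_portions))
        object.__setattr__(self, "total_amount_of_ingredient",
                           _as_fraction(self.total_amount_of_ingredient))
        if self.total_portions <= 0:
            raise ValidationError("total_portions must be > 0")
        if not (0 <= self.portion_consumed <= self.total_portions):
            raise ValidationError(
                f"portion_consumed must lie in [0, total_portions]; "
                f"got {self.portion_consumed} of {self.total_portions}"
            )
        if self.total_amount_of_ingredient < 0:
            raise ValidationError("total_amount_of_ingredient must be >= 0")


def compound_portion_quantity(q: CompoundPortionQuery, *, exact: bool = False):
    """Amount of one ingredient actually consumed, in the amount's own unit.

    Returns a float rounded half-up to 2 decimals, or the exact
    :class:`~fractions.Fraction` when ``exact=True`` (used internally to
    avoid double rounding in recipe expansion).
    """
    value = q.portion_consumed / q.total_portions * q.total_amount_of_ingredient
    if exact:
        return value
    dec = Decimal(value.numerator) / Decimal(value.denominator)
    return float(dec.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def expand_standard_recipe(
    recipe: StandardRecipe | CompoundRecipe,
    exclusions: set[str] | frozenset[str] = frozenset(),
    portions_consumed: Fraction | float | int | None = None,
    *,
    unit_weight_fn=None,
) -> list[tuple[str, float]]:
    """Scale a recipe to the portions actually eaten.

    Returns ``[(food_id, grams consumed), ...]`` in ingredient order with
    excluded ingredients absent. ``portions_consumed`` defaults to the full
    yield. Ingredients denominated in units need ``unit_weight_fn(food_id,
    size) -> grams per unit`` (normally :func:`recall24.measures.unit_weight`
    closed over the equivalence table).
    """
    if isinstance(recipe, StandardRecipe):
        total = Fraction(recipe.yield_portions)
        rid = recipe.recipe_id
    else:
        total = Fraction(recipe.total_portions)
        rid = recipe.name
    consumed = total if portions_consumed is None else _as_fraction(portions_consumed)
    if not (0 < consumed <= total):
        raise ValidationError(
            f"recipe {rid!r}: portions_consumed must be in (0, {total}]; got {consumed}"
        )
    member_ids = {ing.food_id for ing in recipe.ingredients}
    unknown = set(exclusions) - member_ids
    if unknown:
        raise ValidationError(
            f"recipe {rid!r}: cannot exclude non-member ingredient(s) {sorted(unknown)}"
        )
    locked = [ing.food_id for ing in recipe.ingredients
              if ing.food_id in exclusions and not ing.excludable]
    if locked:
        raise ValidationError(
            f"recipe {rid!r}: ingredient(s) {locked} are structural and cannot be excluded"
        )

    out: list[tuple[str, float]] = []
    for ing in recipe.ingredients:
        if ing.food_id in exclusions:
            continue
        if ing.amount_g is not None:
            total_g = ing.amount_g
        else:
            if unit_weight_fn is None:
                raise ValidationError(
                    f"recipe {rid!r}: ingredient {ing.food_id!r} is unit-denominated; "
                    "a unit_weight_fn is required to expand it"
                )
            total_g = ing.amount_units * _as_fraction(unit_weight_fn(ing.food_id, ing.size))
        share = compound_portion_quantity(
            CompoundPortionQuery(consumed, total, total_g), exact=True
        )
        dec = Decimal(share.numerator) / Decimal(share.denominator)
        out.append((ing.food_id, float(dec.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))))
    return out


def build_compound_recipe(db, name: str, ingredients: list[Ingredient],
                          total_portions: int = 1, origin_note: str = "") -> CompoundRecipe:
    """Assemble an interview-described preparation against the food catalogue.

    Every ingredient's ``food_id`` must resolve in *db*; substitution
    rationale (e.g. "animal fat replaced with plant margarine, vegetarian
    respondent") belongs in ``origin_note``.
    """
    if not ingredients:
        raise ValidationError(f"compound recipe {name!r}: at least one ingredient required")
    missing = [ing.food_id for ing in ingredients if ing.food_id not in db.foods]
    if missing:
        raise IntegrityError(
            f"compound recipe {name!r}: unknown food id(s) {missing}"
        )
    return CompoundRecipe(name=name, ingredients=list(ingredients),
                          total_portions=total_portions, origin_note=origin_note)
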