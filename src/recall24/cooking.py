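"""Cooking-method semantics: automatic oil absorption and cooked-variant lookup.

Two rules operate at detailed-loading time:

* **Oil absorption.** A food reported as *fried* automatically contributes an
  extra oil entry worth 10% of the food's net weight; *baked*, 3%. Boiled,
  steamed and sautéed foods add nothing (sautéed preparations in the
  catalogue embed their oil in the food description). The fractions are
  configurable but the 10%/3% defaults are the standard absorption rule.

* **Cooked-variant selection.** When a raw catalogue food is reported cooked,
  the cooked counterpart is chosen from the same composition source
  (matching ``source_tag``), never across sources, so raw and cooked figures
  stay mutually consistent.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction

from .database import COOKING_METHODS, FoodDatabase, FoodItem
from .errors import IntegrityError, ValidationError
from .recipes import _as_fraction
from .text import normalize

__all__ = [
    "DEFAULT_OIL_FRACTIONS",
    "oil_fraction",
    "apply_cooking_method",
    "select_cooked_variant",
]

#: Proportion of the food's net weight added as oil, by cooking method.
DEFAULT_OIL_FRACTIONS: dict[str, Fraction] = {
    "fried": Fraction(10, 100),
    "baked": Fraction(3, 100),
    "boiled": Fraction(0),
    "steamed": Fraction(0),
    "sauteed": Fraction(0),
}


def oil_fraction(method: str, fractions: dict[str, Fraction] | None = None) -> Fraction:
    table = DEFAULT_OIL_FRACTIONS if fractions is None else fractions
    if method not in table:
        raise ValidationError(
            f"unknown cooking method {method!r}; expected one of {sorted(table)}"
        )
    f = _as_fraction(table[method])
    if not (0 <= f <= 1):
        raise ValidationError(f"oil fraction for {method!r} must lie in [0, 1]")
    return f


def apply_cooking_method(
    entry: tuple[FoodItem, float],
    method: str,
    oil_food: FoodItem,
    fractions: dict[str, Fraction] | None = None,
) -> list[tuple[FoodItem, float]]:
    """Expand one (food, grams) entry under a cooking method.

    Fried/baked return the original entry followed by an oil entry of the
    configured fraction of the food's net weight (half-up to 1 decimal); all
    other methods return the entry unchanged. Applying a method to an
    already-cooked catalogue item is refused — the absorption rule fires once,
    during detailed loading, and compounding it would double-count oil.
    """
    food, grams = entry
    if grams <= 0:
        raise ValidationError(f"entry grams must be > 0, got {grams}")
    if food.state == "cooked":
        raise ValidationError(
            f"{food.name!r} is already a cooked item ({food.cooking_method}); "
            "cooking methods apply to raw entries only"
        )
    frac = oil_fraction(method, fractions)
    if frac == 0:
        return [entry]
    if normalize(oil_food.group) not in ("oils", "aceites", "oil"):
        raise IntegrityError(
            f"oil food {oil_food.food_id!r} is in group {oil_food.group!r}, not an oils group"
        )
    oil_exact = _as_fraction(grams) * frac
    dec = Decimal(oil_exact.numerator) / Decimal(oil_exact.denominator)
    oil_g = float(dec.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return [entry, (oil_food, oil_g)]


def select_cooked_variant(db: FoodDatabase, raw_food: FoodItem, method: str) -> FoodItem:
    """Find the cooked counterpart of *raw_food* for *method*.

    Candidates are catalogue items derived from the raw food (food ids of the
    form ``<raw_id>-<suffix>``, or listed among the raw food's variants) with
    ``state = cooked`` and the requested method; among them the one whose
    ``source_tag`` matches the raw food's is selected. Deterministic: on the
    (unexpected) event of several source-matched candidates the smallest
    food id wins.
    """
    if raw_food.state != "raw":
        raise ValidationError(f"{raw_food.food_id!r} is not a raw item")
    if method not in COOKING_METHODS:
        raise ValidationError(f"unknown cooking method {method!r}")
    variant_ids = {target for _, target in raw_food.variants}
    candidates = [
        f for fid, f in db.foods.items()
        if f.state == "cooked"
        and (fid.startswith(raw_food.food_id + "-") or fid in variant_ids)
    ]
    matching = sorted(
        (f for f in candidates
         if f.cooking_method == method and f.source_tag == raw_food.source_tag),
        key=lambda f: f.food_id,
    )
    if matching:
        return matching[0]
    available = sorted({
        f.cooking_method for f in candidates if f.source_tag == raw_food.source_tag
    })
    raise IntegrityError(
        f"no {method!r} variant of {raw_food.name!r} in source {raw_food.source_tag!r}; "
        f"methods available: {{{', '.join(available)}}}"
    )
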