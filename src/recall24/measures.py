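"""Household measures, equivalence tables, and portion→gram conversion.

Portion sizes in the interview are stated against a registry of 16 common
household measures (glasses, cups, spoons, ladles — the utensils of the
portion-size photo album), against per-unit weights by size (small / medium
/ large / unit), or as exact gram/millilitre amounts. The equivalence table
maps (food, measure) to the net weight in grams of that food filling that
measure; missing rows mean the measure is simply not offered for that food.

Conversion arithmetic is exact (rational) until a single half-up rounding to
one decimal at the output, so fractional quantities like 2.5 coffee spoons
reproduce printed worked examples digit for digit.

Foods whose utensil weights were never measured directly can have their full
16-measure vector inferred from measured members of the same density group
(flours, oils, ...), exploiting the near-exact proportionality of utensil
weights within a group; :func:`group_correlation` checks that
proportionality (pairwise Pearson r, flagged below 0.99).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import stats

from .database import FoodItem
from .errors import (
    InsufficientDataError,
    NoEquivalenceError,
    ParseError,
    ValidationError,
)
from .recipes import _as_fraction

__all__ = [
    "HouseholdMeasure",
    "MEASURE_REGISTRY",
    "EquivalenceTable",
    "PortionSpec",
    "convert_quantity",
    "unit_weight",
    "infer_group_weights",
    "group_correlation",
    "load_equivalences",
    "save_equivalences",
]

UNIT_SIZES = ("small", "medium", "large", "unit")
EXACT_UNITS = ("g", "mL", "mg", "ug", "IU")


@dataclass(frozen=True)
class HouseholdMeasure:
    measure_id: int
    label: str
    is_volume: bool = False


def _default_registry() -> dict[int, HouseholdMeasure]:
    # ids 1-16 are immutable; labels are configurable defaults. The labelled
    # ones are fixed by convention (5 big glass, 8 big cup, 11 tablespoon,
    # 13 teaspoon, 14 coffee spoon, 15 big ladle).
    labels = {
        1: ("Small glass", True),
        2: ("Medium glass", True),
        3: ("Wine glass", True),
        4: ("Jar glass", True),
        5: ("Big glass", True),
        6: ("Small cup", True),
        7: ("Tea cup", True),
        8: ("Big cup", True),
        9: ("Bowl", True),
        10: ("Soup plate", False),
        11: ("Tablespoon", False),
        12: ("Dessert spoon", False),
        13: ("Teaspoon", False),
        14: ("Coffee spoon", False),
        15: ("Big ladle", False),
        16: ("Small ladle", False),
    }
    return {i: HouseholdMeasure(i, name, vol) for i, (name, vol) in labels.items()}


#: The 16-measure registry keyed by measure id.
MEASURE_REGISTRY: dict[int, HouseholdMeasure] = _default_registry()


@dataclass
class EquivalenceTable:
    """Per-food gram weights for household measures and counted units.

    ``rows[(food_id, measure_id)]`` is the net weight in grams of the food
    filling that measure; ``unit_weights[(food_id, size)]`` the grams of one
    unit of the stated size. ``provenance`` records how each measure row was
    obtained: from literature, weighed in the laboratory, or inferred from
    its density group.
    """

    rows: dict[tuple[str, int], Fraction] = field(default_factory=dict)
    unit_weights: dict[tuple[str, str], Fraction] = field(default_factory=dict)
    provenance: dict[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self):
        for key, w in {**self.rows}.items():
            self.rows[key] = _as_fraction(w)
            if self.rows[key] <= 0:
                raise ValidationError(f"equivalence weight for {key} must be > 0")
            fid, mid = key
            if mid not in MEASURE_REGISTRY:
                raise ValidationError(f"unknown measure_id {mid} for food {fid!r}")
        for key, w in {**self.unit_weights}.items():
            self.unit_weights[key] = _as_fraction(w)
            if self.unit_weights[key] <= 0:
                raise ValidationError(f"unit weight for {key} must be > 0")
            if key[1] not in UNIT_SIZES:
                raise ValidationError(f"unknown unit size {key[1]!r} for food {key[0]!r}")

    def measures_for(self, food_id: str) -> list[int]:
        return sorted(m for f, m in self.rows if f == food_id)

    def sizes_for(self, food_id: str) -> list[str]:
        return [s for s in UNIT_SIZES if (food_id, s) in self.unit_weights]


@dataclass(frozen=True)
class PortionSpec:
    """One portion statement from the interview.

    mode ``household_measure``: ``quantity`` utensils of ``measure_id``
    (fractions allowed); mode ``unit``: ``quantity`` units of ``size``; mode
    ``exact``: ``exact_amount`` in ``exact_unit`` (g, mL, mg, ug, IU — the
    mg/ug/IU forms exist for supplements).
    """

    mode: str
    measure_id: int | None = None
    size: str | None = None
    quantity: Fraction = Fraction(1)
    exact_amount: Fraction | None = None
    exact_unit: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "quantity", _as_fraction(self.quantity))
        if self.mode == "household_measure":
            if self.measure_id is None:
                raise ValidationError("household_measure portion needs a measure_id")
            if self.quantity <= 0:
                raise ValidationError("portion quantity must be > 0")
        elif self.mode == "unit":
            if self.size is None:
                object.__setattr__(self, "size", "unit")
            if self.size not in UNIT_SIZES:
                raise ValidationError(f"unknown unit size {self.size!r}")
            if self.quantity <= 0:
                raise ValidationError("portion quantity must be > 0")
        elif self.mode == "exact":
            if self.exact_amount is None or self.exact_unit is None:
                raise ValidationError("exact portion needs exact_amount and exact_unit")
            object.__setattr__(self, "exact_amount", _as_fraction(self.exact_amount))
            if self.exact_amount < 0:
                raise ValidationError("exact amount must be >= 0")
            if self.exact_unit not in EXACT_UNITS:
                raise ValidationError(f"exact unit must be one of {EXACT_UNITS}")
        else:
            raise ValidationError(f"unknown portion mode {self.mode!r}")

    def describe(self, registry: dict[int, HouseholdMeasure] = MEASURE_REGISTRY) -> str:
        if self.mode == "household_measure":
            m = registry[self.measure_id]
            return f"1 {m.label} ({m.measure_id})"
        if self.mode == "unit":
            return "Unit / pot" if self.size == "unit" else f"{self.size.capitalize()} unit"
        return f"exact {self.exact_unit}"


def _round1(x: Fraction) -> float:
    dec = Decimal(x.numerator) / Decimal(x.denominator)
    return float(dec.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def convert_quantity(food: FoodItem, portion: PortionSpec, eq: EquivalenceTable) -> float:
    """Net amount of *food* in grams (mL for liquids), half-up to 1 decimal.

    household-measure and unit modes multiply the quantity by the stored
    per-measure / per-unit weight. Exact gram or millilitre statements pass
    through (mL converts to grams through the food's density only for
    non-liquid foods that declare one — liquid amounts stay in mL, matching
    how liquid rows are carried through the report). Exact mg / ug convert
    to grams; IU passes through numerically for supplement entries.
    """
    if portion.mode == "household_measure":
        key = (food.food_id, portion.measure_id)
        if key not in eq.rows:
            label = MEASURE_REGISTRY[portion.measure_id].label
            have = eq.measures_for(food.food_id)
            raise NoEquivalenceError(
                f"no equivalence for {food.name!r} in measure {label!r} "
                f"(id {portion.measure_id}); measures on file: {have}"
            )
        grams = portion.quantity * eq.rows[key]
    elif portion.mode == "unit":
        grams = portion.quantity * _unit_weight_fraction(food, portion.size, eq)
    else:  # exact
        amount = portion.exact_amount
        if portion.exact_unit == "g":
            grams = amount
        elif portion.exact_unit == "mL":
            if not food.is_liquid and food.density_g_per_mL is not None:
                grams = amount * _as_fraction(food.density_g_per_mL)
            else:
                grams = amount
        elif portion.exact_unit == "mg":
            grams = amount / 1000
        elif portion.exact_unit == "ug":
            grams = amount / 1_000_000
        else:  # IU
            grams = amount
    return _round1(grams)


def _unit_weight_fraction(food: FoodItem, size: str, eq: EquivalenceTable) -> Fraction:
    key = (food.food_id, size)
    if key not in eq.unit_weights:
        have = eq.sizes_for(food.food_id)
        raise NoEquivalenceError(
            f"no {size!r} unit weight for {food.name!r}; sizes on file: {{{', '.join(have)}}}"
        )
    return eq.unit_weights[key]


def unit_weight(food: FoodItem, size: str, eq: EquivalenceTable) -> float:
    """Grams of one *size* unit of *food* from the equivalence table."""
    if size not in UNIT_SIZES:
        raise ValidationError(f"unknown unit size {size!r}; expected one of {UNIT_SIZES}")
    return float(_unit_weight_fraction(food, size, eq))


# ---------------------------------------------------------------------------
# group-based inference of unmeasured foods

def infer_group_weights(
    measured: dict[str, dict[int, float]],
    target_food_id: str,
    reference_ratio: float | None = None,
    target_partial: dict[int, float] | None = None,
) -> tuple[dict[int, Fraction], str]:
    """Estimate a food's full 16-measure weight vector from its density group.

    *measured* maps member food ids to complete 16-measure weight vectors.
    The inferred vector is the componentwise mean of the measured members
    scaled by a reference ratio anchoring the target's overall density:
    either supplied, or derived as the mean ratio target/groupmean over the
    measures in *target_partial*. With no anchor at all the group mean is
    returned unscaled with provenance ``"unscaled"``; otherwise provenance is
    ``"inferred"``.

    Returns ``(vector, provenance)``.
    """
    if not measured:
        raise InsufficientDataError("group weight inference needs >=1 fully measured member")
    vectors = list(measured.values())
    measure_ids = sorted(vectors[0])
    for fid, vec in measured.items():
        if sorted(vec) != measure_ids:
            raise ValidationError(
                f"measured member {fid!r} does not cover the same measures as the group"
            )
    mean_vec = {
        m: sum(_as_fraction(vec[m]) for vec in vectors) / len(vectors)
        for m in measure_ids
    }
    provenance = "inferred"
    if reference_ratio is not None:
        ratio = _as_fraction(reference_ratio)
    elif target_partial:
        shared = [m for m in target_partial if m in mean_vec]
        if not shared:
            raise ValidationError("target_partial shares no measures with the group")
        ratio = sum(_as_fraction(target_partial[m]) / mean_vec[m] for m in shared) / len(shared)
    else:
        ratio = Fraction(1)
        provenance = "unscaled"
    if ratio <= 0:
        raise ValidationError("reference ratio must be > 0")
    return {m: mean_vec[m] * ratio for m in measure_ids}, provenance


def group_correlation(
    vectors: dict[str, dict[int, float]], r_threshold: float = 0.99
) -> list[tuple[str, str, float, bool]]:
    """Pairwise Pearson r between group members' utensil-weight vectors.

    Each pair is correlated over its shared measures (at least 3 required).
    Returns ``(food_a, food_b, r, ok)`` tuples with ``ok = r >= r_threshold``
    — the proportionality acceptance rule for density groups.
    """
    ids = sorted(vectors)
    if len(ids) < 2:
        raise InsufficientDataError("group correlation needs >=2 members")
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            shared = sorted(set(vectors[a]) & set(vectors[b]))
            if len(shared) < 3:
                raise InsufficientDataError(
                    f"members {a!r} and {b!r} share only {len(shared)} measures (need >=3)"
                )
            xa = np.array([float(vectors[a][m]) for m in shared])
            xb = np.array([float(vectors[b][m]) for m in shared])
            if np.allclose(xa, xa[0]) or np.allclose(xb, xb[0]):
                r = 1.0 if np.allclose(xa / xa[0], xb / xb[0]) else float("nan")
            else:
                r = float(stats.pearsonr(xa, xb).statistic)
            out.append((a, b, r, bool(r >= r_threshold)))
    return out


# ---------------------------------------------------------------------------
# persistence

def save_equivalences(eq: EquivalenceTable, directory: str | Path) -> None:
    """Write ``equivalences.csv`` and ``unit_weights.csv`` canonically."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "equivalences.csv", "w", encoding="utf-8", newline="") as fh:
        fh.write("food_id,measure_id,weight_g,provenance\n")
        for (fid, mid) in sorted(eq.rows):
            w = eq.rows[(fid, mid)]
            prov = eq.provenance.get((fid, mid), "literature")
            fh.write(f"{fid},{mid},{_fraction_str(w)},{prov}\n")
    with open(directory / "unit_weights.csv", "w", encoding="utf-8", newline="") as fh:
        fh.write("food_id,size,weight_g\n")
        for (fid, size) in sorted(eq.unit_weights):
            fh.write(f"{fid},{size},{_fraction_str(eq.unit_weights[(fid, size)])}\n")


def _fraction_str(x: Fraction) -> str:
    # decimal form when exact, fraction form otherwise, for human-readable CSVs
    dec = Decimal(x.numerator) / Decimal(x.denominator)
    if Fraction(dec) == x:
        s = format(dec.normalize(), "f")
        return s
    return f"{x.numerator}/{x.denominator}"


def _parse_weight(cell: str, line: int, path: str) -> Fraction:
    try:
        return Fraction(cell) if "/" in cell else Fraction(Decimal(cell))
    except (ValueError, ArithmeticError) as e:
        raise ParseError(f"{path}: bad weight {cell!r}", line=line) from e


def load_equivalences(directory: str | Path) -> EquivalenceTable:
    """Load the equivalence CSVs written by :func:`save_equivalences`."""
    directory = Path(directory)
    rows: dict[tuple[str, int], Fraction] = {}
    prov: dict[tuple[str, int], str] = {}
    units: dict[tuple[str, str], Fraction] = {}
    eq_path = directory / "equivalences.csv"
    if eq_path.exists():
        with open(eq_path, encoding="utf-8") as fh:
            header = fh.readline().strip().split(",")
            if header[:3] != ["food_id", "measure_id", "weight_g"]:
                raise ParseError(f"{eq_path}: unexpected header {header}", line=1)
            for i, raw in enumerate(fh, start=2):
                if not raw.strip():
                    continue
                parts = raw.rstrip("\n").split(",")
                if len(parts) < 3:
                    raise ParseError(f"{eq_path}: expected >=3 fields", line=i)
                fid, mid, w = parts[0], int(parts[1]), _parse_weight(parts[2], i, str(eq_path))
                key = (fid, mid)
                if key in rows:
                    raise ParseError(f"{eq_path}: duplicate row for {key}", line=i)
                rows[key] = w
                prov[key] = parts[3] if len(parts) > 3 and parts[3] else "literature"
    uw_path = directory / "unit_weights.csv"
    if uw_path.exists():
        with open(uw_path, encoding="utf-8") as fh:
            header = fh.readline().strip().split(",")
            if header != ["food_id", "size", "weight_g"]:
                raise ParseError(f"{uw_path}: unexpected header {header}", line=1)
            for i, raw in enumerate(fh, start=2):
                if not raw.strip():
                    continue
                fid, size, w = raw.rstrip("\n").split(",")
                units[(fid, size)] = _parse_weight(w, i, str(uw_path))
    return EquivalenceTable(rows=rows, unit_weights=units, provenance=prov)
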