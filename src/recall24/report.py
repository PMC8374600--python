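"""Nutrient-totals report over the canonical 49-component schema.

Totals for one finalized recall are the grams-weighted sum of each food's
per-100 g (per-100 mL for liquids) densities::

    total_c = Σ_i  amount_i × density_{i,c} / 100

where ``amount_i`` is the entry's net grams (mL for liquids — the same
number the conversion step produced). A component absent from a food's
composition source contributes 0 to the total and increments that
component's *coverage gap* count, so reports distinguish "measured zero"
from "no data".

Internally totals are kept at full precision; the 3-decimal rounding happens
only at formatting. Participant identity is replaced in report output by a
deterministic anonymised code derived from the participant id, questionnaire
number and recall index.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
from dataclasses import dataclass, field

from .components import COMPONENT_IDS, COMPONENT_SCHEMA, COMPONENT_INDEX
from .database import FoodDatabase
from .errors import IntegrityError, ValidationError
from .session import FinalizedRecall, RecallEntry
from .text import normalize

__all__ = [
    "NutrientReport",
    "compute_report",
    "format_report",
    "report_to_csv",
    "report_to_json",
    "anonymize_code",
    "vitamin_d_iu",
]


@dataclass
class NutrientReport:
    """Per-recall totals plus per-component coverage-gap counts."""

    totals: dict[str, float]
    coverage: dict[str, int]
    recall_ref: str = ""
    participant_code: str = ""
    #: experimental: protein split by the food group's broad origin
    protein_by_origin: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for cid in COMPONENT_IDS:
            if self.totals.get(cid, 0.0) < 0:
                raise ValidationError(f"total for {cid!r} is negative")


_ANIMAL_GROUPS = {
    "meat", "beef", "poultry", "fish", "seafood", "dairy", "milk", "cheese",
    "egg", "eggs", "carnes", "lacteos", "huevos",
}


def compute_report(
    entries: list[RecallEntry] | FinalizedRecall,
    db: FoodDatabase,
    recall_ref: str = "",
    participant_code: str = "",
) -> NutrientReport:
    """Aggregate detailed recall entries into 49-component totals.

    Every entry must carry a resolvable ``food_id`` and non-negative grams.
    """
    if isinstance(entries, FinalizedRecall):
        recall_ref = recall_ref or entries.session_id
        entries = entries.entries
    totals = {cid: 0.0 for cid in COMPONENT_IDS}
    coverage = {cid: 0 for cid in COMPONENT_IDS}
    protein_origin = {"animal": 0.0, "vegetable": 0.0, "unclassified": 0.0}
    for e in entries:
        if e.food_id is None:
            raise ValidationError(f"entry {e.label!r} has no food_id; detail it first")
        if e.grams is None or e.grams < 0:
            raise ValidationError(f"entry {e.label!r} has invalid grams {e.grams!r}")
        if e.food_id not in db.foods:
            raise IntegrityError(f"entry {e.label!r}: unknown food id {e.food_id!r}")
        food = db.foods[e.food_id]
        values = food.profile.values
        scale = e.grams / 100.0
        for cid in COMPONENT_IDS:
            v = values.get(cid)
            if v is None:
                coverage[cid] += 1
            else:
                totals[cid] += scale * v
        p = values.get("protein")
        if p is not None:
            origin = ("animal" if normalize(food.group) in _ANIMAL_GROUPS
                      else "vegetable" if food.group else "unclassified")
            protein_origin[origin] += scale * p
    return NutrientReport(
        totals=totals, coverage=coverage, recall_ref=recall_ref,
        participant_code=participant_code, protein_by_origin=protein_origin,
    )


def format_report(report: NutrientReport) -> list[tuple[str, str, str]]:
    """Rows ``(Name, Amount, Unit)`` in schema order, amounts to 3 decimals."""
    rows = []
    for comp in COMPONENT_SCHEMA:
        if comp.component_id not in report.totals:
            raise ValidationError(f"report lacks component {comp.component_id!r}")
        rows.append((comp.name, f"{report.totals[comp.component_id]:.3f}", comp.unit))
    return rows


def report_to_csv(report: NutrientReport) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["component_id", "name", "amount", "unit", "entries_without_data"])
    for comp, (name, amount, unit) in zip(COMPONENT_SCHEMA, format_report(report)):
        writer.writerow([comp.component_id, name, amount, unit,
                         report.coverage[comp.component_id]])
    return buf.getvalue()


def report_to_json(report: NutrientReport) -> str:
    payload = {
        "recall_ref": report.recall_ref,
        "participant_code": report.participant_code,
        "components": [
            {
                "component_id": comp.component_id,
                "name": name,
                "amount": float(amount),
                "unit": unit,
                "entries_without_data": report.coverage[comp.component_id],
            }
            for comp, (name, amount, unit) in zip(COMPONENT_SCHEMA, format_report(report))
        ],
    }
    return json.dumps(payload, ensure_ascii=False, indent=2) + "\n"


def vitamin_d_iu(report: NutrientReport) -> float:
    """Vitamin D total viewed in International Units (1 μg = 40 IU)."""
    return 40.0 * report.totals["vitamin_d"]


def anonymize_code(participant_id: str, questionnaire_number: str | int,
                   recall_index: int) -> str:
    """Deterministic anonymised participant code for report output.

    Injective over (participant_id, questionnaire_number, recall_index) up to
    hash collision, and free of any name substring: the identifying part is
    a hex digest, which cannot spell a name containing non-hex letters and is
    in practice unlinkable either way.
    """
    if not str(participant_id) or not str(questionnaire_number):
        raise ValidationError("participant_id and questionnaire_number must be non-empty")
    if recall_index < 1:
        raise ValidationError("recall_index must be >= 1")
    digest = hashlib.sha256(
        f"{participant_id}\x1f{questionnaire_number}\x1f{recall_index}".encode()
    ).hexdigest()[:12]
    return f"Q{questionnaire_number}-R{recall_index}-{digest}"
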