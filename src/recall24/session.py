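"""Five-pass 24-hour recall interview as an explicit state machine.

The multiple-pass protocol structures one 24HR interview as five ordered
passes:

1. **Quick list** — every food, drink and recipe the respondent remembers,
   names only, no amounts.
2. **Forgotten foods** — a fixed checklist of commonly forgotten categories
   (sweets, sodas, snacks, dressings, broths, condiments, others).
3. **Time and occasion** — clock time, place and eating occasion per item.
4. **Detailed cycle** — each quick-list item is resolved against the food
   catalogue, quantified through the equivalence table, and (when the
   respondent reports frying/baking) expanded with the automatic oil entry.
5. **Final probe** — last sweep for missing items; anything recalled here
   joins the list and is detailed immediately; the recall can only be
   finalised once every entry is detailed.

A session enforces this order strictly: passes advance forward only (the
final probe may drop back into detailing), and finalisation emits an
immutable stored recall. Sessions are driven either programmatically or by
replaying a JSON transcript of operations, which makes the whole interview
testable headlessly.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field, asdict
from datetime import date
from fractions import Fraction
from pathlib import Path

from .cooking import apply_cooking_method, DEFAULT_OIL_FRACTIONS, oil_fraction
from .database import FoodDatabase, FoodItem, resolve_variant
from .errors import (
    CompletenessError,
    IntegrityError,
    StateError,
    ValidationError,
)
from .measures import EquivalenceTable, PortionSpec, convert_quantity

__all__ = [
    "STATES",
    "FORGOTTEN_CATEGORIES",
    "DEFAULT_OCCASIONS",
    "Participant",
    "RecallEntry",
    "RecallSession",
    "FinalizedRecall",
    "start_session",
    "add_quick_item",
    "forgotten_probe",
    "assign_time_place_occasion",
    "detail_entry",
    "begin_final_probe",
    "edit_entry",
    "finalize",
    "replay_transcript",
    "load_transcript",
]

#: Pass order; transitions move forward only.
STATES = ("QUICK_LIST", "FORGOTTEN", "TIME_OCCASION", "DETAIL", "FINAL_PROBE", "FINALIZED")
_ORDER = {s: i for i, s in enumerate(STATES)}

#: Categories probed for commonly forgotten items, in asking order.
FORGOTTEN_CATEGORIES = (
    "sweets", "sodas", "snacks", "dressings", "broths", "condiments", "others",
)

#: Default eating-occasion vocabulary (an empty occasion is always allowed,
#: e.g. water taken between meals).
DEFAULT_OCCASIONS = ("Breakfast", "Lunch", "Snack", "Dinner", "Dessert")

_TIME_RE = re.compile(r"^(\d{1,2}):(\d{2})(?::(\d{2}))?$")


def _canonical_time(text: str) -> str:
    m = _TIME_RE.match(text.strip())
    if not m:
        raise ValidationError(f"malformed time {text!r}; expected HH:MM[:SS]")
    h, mi, s = int(m.group(1)), int(m.group(2)), int(m.group(3) or 0)
    if not (0 <= h <= 23 and 0 <= mi <= 59 and 0 <= s <= 59):
        raise ValidationError(f"time out of range: {text!r}")
    return f"{h:02d}:{mi:02d}:{s:02d}"


@dataclass
class Participant:
    participant_id: str
    name: str
    contact: str = ""
    sociodemographic: dict = field(default_factory=dict)
    health: dict = field(default_factory=dict)


@dataclass
class RecallEntry:
    """One reported food/drink within the recall day."""

    label: str
    food_id: str | None = None
    time: str | None = None
    place: str = ""
    occasion: str = ""
    portion: PortionSpec | None = None
    grams: float | None = None
    quality_note: str = ""
    detailed: bool = False

    def require_detailed_consistency(self):
        if self.detailed and (self.food_id is None or self.portion is None
                              or self.grams is None or self.grams < 0):
            raise ValidationError(f"entry {self.label!r} marked detailed but incomplete")


@dataclass
class RecallSession:
    session_id: str
    participant_id: str
    interviewer_id: str
    recall_date: date
    day_type: str = "habitual"
    state: str = "QUICK_LIST"
    entries: list[RecallEntry] = field(default_factory=list)
    probe_checklist: dict[str, bool] = field(
        default_factory=lambda: {c: False for c in FORGOTTEN_CATEGORIES})
    audit: list[str] = field(default_factory=list)


@dataclass
class FinalizedRecall:
    """Immutable record of one completed 24HR (every entry detailed)."""

    session_id: str
    participant_id: str
    interviewer_id: str
    recall_date: date
    day_type: str
    entries: list[RecallEntry]
    audit: list[str] = field(default_factory=list)


def _require_state(session: RecallSession, allowed: tuple[str, ...], op: str) -> None:
    if session.state not in allowed:
        raise StateError(
            f"{op} is not allowed in pass {session.state}; allowed in {allowed}"
        )


def _advance(session: RecallSession, to_state: str) -> None:
    if _ORDER[to_state] > _ORDER[session.state]:
        session.state = to_state


# ---------------------------------------------------------------------------
# pass 0: opening

def start_session(
    participant: Participant,
    interviewer_id: str,
    recall_date: date,
    day_type: str = "habitual",
    registry: dict[str, Participant] | None = None,
    session_id: str | None = None,
    today: date | None = None,
) -> RecallSession:
    """Open a recall for one participant/day in the quick-list pass.

    *registry*, when given, must contain the participant (a recall belongs
    to a registered interviewee). The recall day cannot lie in the future.
    """
    if registry is not None and participant.participant_id not in registry:
        raise IntegrityError(f"unknown participant {participant.participant_id!r}")
    if day_type not in ("habitual", "atypical"):
        raise ValidationError(f"day_type must be habitual|atypical, got {day_type!r}")
    if recall_date > (today or date.today()):
        raise ValidationError(f"recall date {recall_date} lies in the future")
    sid = session_id or f"{participant.participant_id}:{recall_date.isoformat()}"
    return RecallSession(
        session_id=sid,
        participant_id=participant.participant_id,
        interviewer_id=interviewer_id,
        recall_date=recall_date,
        day_type=day_type,
    )


# ---------------------------------------------------------------------------
# passes 1, 2, 5: listing

def add_quick_item(session: RecallSession, label: str) -> RecallSession:
    """Append an undetailed item, preserving report order.

    Legal during the quick list, the forgotten-foods pass, and the final
    probe (a food recalled at the very end joins the list and is then
    detailed like any other).
    """
    _require_state(session, ("QUICK_LIST", "FORGOTTEN", "FINAL_PROBE"), "add_quick_item")
    if not label.strip():
        raise ValidationError("quick-list label must be non-empty")
    session.entries.append(RecallEntry(label=label.strip()))
    return session


def forgotten_probe(session: RecallSession) -> list[str]:
    """Return the forgotten-food categories to ask, marking them asked.

    Advances the session into the forgotten-foods pass; re-probing later
    passes is a state error.
    """
    _require_state(session, ("QUICK_LIST", "FORGOTTEN"), "forgotten_probe")
    to_ask = [c for c in FORGOTTEN_CATEGORIES]
    for c in FORGOTTEN_CATEGORIES:
        session.probe_checklist[c] = True
    _advance(session, "FORGOTTEN")
    return to_ask


# ---------------------------------------------------------------------------
# pass 3: time, place, occasion

def assign_time_place_occasion(
    session: RecallSession,
    entry_index: int,
    time: str,
    place: str,
    occasion: str = "",
    occasions: tuple[str, ...] = DEFAULT_OCCASIONS,
) -> RecallSession:
    """Record when/where/at which occasion an entry was consumed.

    Times are 24-hour ``HH:MM[:SS]``, stored zero-filled. The occasion must
    come from the configured vocabulary or be empty (e.g. water between
    meals carries no occasion).
    """
    _require_state(session, ("FORGOTTEN", "TIME_OCCASION", "DETAIL", "FINAL_PROBE"),
                   "assign_time_place_occasion")
    entry = _get_entry(session, entry_index)
    if occasion and occasion not in occasions:
        raise ValidationError(
            f"occasion {occasion!r} not in vocabulary {occasions} (or empty)"
        )
    entry.time = _canonical_time(time)
    entry.place = place
    entry.occasion = occasion
    _advance(session, "TIME_OCCASION")
    return session


def _get_entry(session_or_recall, entry_index: int) -> RecallEntry:
    entries = session_or_recall.entries
    if not (0 <= entry_index < len(entries)):
        raise ValidationError(
            f"entry index {entry_index} out of range (0..{len(entries) - 1})"
        )
    return entries[entry_index]


# ---------------------------------------------------------------------------
# pass 4: detailed cycle

def detail_entry(
    session: RecallSession,
    entry_index: int,
    food: FoodItem | str,
    portion: PortionSpec,
    *,
    db: FoodDatabase,
    eq: EquivalenceTable,
    variant_option: str = "",
    cooking_method: str | None = None,
    oil_food_id: str | None = None,
    quality_note: str = "",
) -> RecallSession:
    """Resolve, quantify and check off one quick-list item.

    *food* may be a FoodItem or a food id; a drop-down *variant_option*
    resolves it further. Grams come from :func:`convert_quantity`. When a
    *cooking_method* with oil absorption (fried/baked) is given, the
    automatic oil entry is inserted right after the food, already detailed
    and inheriting its time/place/occasion.
    """
    _require_state(session, ("TIME_OCCASION", "DETAIL", "FINAL_PROBE"), "detail_entry")
    entry = _get_entry(session, entry_index)
    if entry.detailed:
        raise ValidationError(
            f"entry {entry.label!r} is already detailed; use edit_entry to change it"
        )
    if isinstance(food, str):
        if food not in db.foods:
            raise IntegrityError(f"unknown food id {food!r}")
        food = db.foods[food]
    food = resolve_variant(db, food, variant_option)
    grams = convert_quantity(food, portion, eq)

    oil_entry = None
    if cooking_method is not None and oil_fraction(cooking_method) > 0:
        if oil_food_id is None:
            oil_food_id = _default_oil_food(db)
        if oil_food_id not in db.foods:
            raise IntegrityError(f"oil food id {oil_food_id!r} not in catalogue")
        expanded = apply_cooking_method((food, grams), cooking_method, db.foods[oil_food_id])
        if len(expanded) == 2:
            oil_food, oil_g = expanded[1]
            oil_entry = RecallEntry(
                label=f"{oil_food.name} (added, {cooking_method} {entry.label})",
                food_id=oil_food.food_id,
                time=entry.time, place=entry.place, occasion=entry.occasion,
                portion=PortionSpec(mode="exact", exact_amount=Fraction(str(oil_g)),
                                    exact_unit="g"),
                grams=oil_g, detailed=True,
            )

    entry.food_id = food.food_id
    entry.portion = portion
    entry.grams = grams
    entry.quality_note = quality_note
    entry.detailed = True
    if oil_entry is not None:
        session.entries.insert(entry_index + 1, oil_entry)
    _advance(session, "DETAIL")
    return session


def _default_oil_food(db: FoodDatabase) -> str:
    from .text import normalize
    for fid, f in db.foods.items():
        if normalize(f.group) in ("oils", "aceites", "oil"):
            return fid
    raise IntegrityError("no oil-group food in the catalogue for automatic oil addition")


def begin_final_probe(session: RecallSession) -> RecallSession:
    """Enter the final probe once the detailed cycle has started."""
    _require_state(session, ("DETAIL",), "begin_final_probe")
    session.state = "FINAL_PROBE"
    return session


# ---------------------------------------------------------------------------
# editing and finalisation

def edit_entry(
    target: RecallSession | FinalizedRecall,
    entry_index: int,
    *,
    db: FoodDatabase,
    eq: EquivalenceTable,
    food: FoodItem | str | None = None,
    portion: PortionSpec | None = None,
    variant_option: str = "",
    cooking_method: str | None = None,
    oil_food_id: str | None = None,
    quality_note: str | None = None,
):
    """Replace one detailed record by delete-and-reload through the normal path.

    Works on a live session or on a stored (finalized) recall; a finalized
    session object itself is immutable, edits apply to the stored copy. The
    replacement keeps the original label/time/place/occasion and re-derives
    grams from the new food/portion; an audit note records the change.
    """
    old = _get_entry(target, entry_index)
    food = food if food is not None else (old.food_id or "")
    portion = portion if portion is not None else old.portion
    if portion is None:
        raise ValidationError("edit_entry needs a portion for an undetailed original")
    if isinstance(food, str):
        if food not in db.foods:
            raise IntegrityError(f"unknown food id {food!r}")
        food = db.foods[food]
    food = resolve_variant(db, food, variant_option)
    grams = convert_quantity(food, portion, eq)
    replacement = RecallEntry(
        label=old.label, food_id=food.food_id, time=old.time, place=old.place,
        occasion=old.occasion, portion=portion, grams=grams,
        quality_note=old.quality_note if quality_note is None else quality_note,
        detailed=True,
    )
    # delete the record, then append the reloaded row at its position
    target.entries.pop(entry_index)
    target.entries.insert(entry_index, replacement)
    target.audit.append(
        f"edit entry {entry_index} ({old.label!r}): {old.food_id} {old.grams} g "
        f"-> {replacement.food_id} {replacement.grams} g"
    )
    return target


def finalize(session: RecallSession) -> FinalizedRecall:
    """Close the recall: succeeds iff every entry is detailed.

    Emits the immutable stored recall and marks the session FINALIZED; the
    error on failure names every still-undetailed label.
    """
    _require_state(session, ("FINAL_PROBE",), "finalize")
    undetailed = [e.label for e in session.entries if not e.detailed]
    if undetailed:
        raise CompletenessError(undetailed)
    for e in session.entries:
        e.require_detailed_consistency()
    session.state = "FINALIZED"
    recall = FinalizedRecall(
        session_id=session.session_id,
        participant_id=session.participant_id,
        interviewer_id=session.interviewer_id,
        recall_date=session.recall_date,
        day_type=session.day_type,
        entries=[RecallEntry(**{**asdict(e), "portion": e.portion}) for e in session.entries],
        audit=list(session.audit),
    )
    return recall


# ---------------------------------------------------------------------------
# serialisation

def _portion_to_json(p: PortionSpec | None) -> dict | None:
    if p is None:
        return None
    d = {"mode": p.mode, "quantity": str(p.quantity)}
    if p.measure_id is not None:
        d["measure_id"] = p.measure_id
    if p.mode == "unit":
        d["size"] = p.size
    if p.exact_amount is not None:
        d["exact_amount"] = str(p.exact_amount)
        d["exact_unit"] = p.exact_unit
    return d


def _portion_from_json(d: dict | None) -> PortionSpec | None:
    if d is None:
        return None
    kwargs = dict(mode=d["mode"], quantity=Fraction(d.get("quantity", "1")))
    if "measure_id" in d:
        kwargs["measure_id"] = int(d["measure_id"])
    if "size" in d:
        kwargs["size"] = d["size"]
    if "exact_amount" in d:
        kwargs["exact_amount"] = Fraction(d["exact_amount"])
        kwargs["exact_unit"] = d["exact_unit"]
    return PortionSpec(**kwargs)


def recall_to_json(recall: FinalizedRecall) -> dict:
    return {
        "session_id": recall.session_id,
        "participant_id": recall.participant_id,
        "interviewer_id": recall.interviewer_id,
        "recall_date": recall.recall_date.isoformat(),
        "day_type": recall.day_type,
        "audit": list(recall.audit),
        "entries": [
            {
                "label": e.label, "food_id": e.food_id, "time": e.time,
                "place": e.place, "occasion": e.occasion,
                "portion": _portion_to_json(e.portion), "grams": e.grams,
                "quality_note": e.quality_note, "detailed": e.detailed,
            }
            for e in recall.entries
        ],
    }


def recall_from_json(payload: dict) -> FinalizedRecall:
    return FinalizedRecall(
        session_id=payload["session_id"],
        participant_id=payload["participant_id"],
        interviewer_id=payload["interviewer_id"],
        recall_date=date.fromisoformat(payload["recall_date"]),
        day_type=payload["day_type"],
        audit=list(payload.get("audit", [])),
        entries=[
            RecallEntry(
                label=e["label"], food_id=e["food_id"], time=e["time"],
                place=e["place"], occasion=e["occasion"],
                portion=_portion_from_json(e["portion"]), grams=e["grams"],
                quality_note=e.get("quality_note", ""), detailed=e["detailed"],
            )
            for e in payload["entries"]
        ],
    )


def recall_to_csv(recall: FinalizedRecall) -> str:
    """Worked-recall export: Food, Schedule, Place, Occasion, Portion, Quantity, Grams."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["Food", "Schedule", "Place", "Occasion", "Portion", "Quantity", "Grams"])
    for e in recall.entries:
        qty = ""
        portion = ""
        if e.portion is not None:
            portion = e.portion.describe()
            q = e.portion.quantity
            qty = str(q.numerator) if q.denominator == 1 else str(float(q))
        writer.writerow([e.label, e.time or "", e.place, e.occasion, portion, qty,
                         "" if e.grams is None else f"{e.grams:.1f}"])
    return buf.getvalue()


# ---------------------------------------------------------------------------
# transcript replay (headless interview)

def load_transcript(path: str | Path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        ops = json.load(fh)
    if not isinstance(ops, list):
        raise ValidationError("transcript must be a JSON array of operations")
    return ops


def replay_transcript(
    ops: list[dict],
    db: FoodDatabase,
    eq: EquivalenceTable,
    registry: dict[str, Participant] | None = None,
) -> tuple[RecallSession, FinalizedRecall | None]:
    """Replay an ordered operation log through the state machine.

    Returns the session and, if the transcript finalises, the stored recall.
    Any engine error is re-raised annotated with the failing step index.
    """
    session: RecallSession | None = None
    recall: FinalizedRecall | None = None
    for i, op in enumerate(ops):
        kind = op.get("op")
        try:
            if kind == "start_session":
                participant = Participant(op["participant_id"], op.get("name", ""))
                session = start_session(
                    participant, op.get("interviewer_id", ""),
                    date.fromisoformat(op["recall_date"]),
                    op.get("day_type", "habitual"), registry=registry,
                    session_id=op.get("session_id"),
                )
                continue
            if session is None:
                raise StateError("transcript must begin with a start_session operation")
            if kind == "add_quick_item":
                add_quick_item(session, op["label"])
            elif kind == "forgotten_probe":
                forgotten_probe(session)
            elif kind == "assign_time_place_occasion":
                assign_time_place_occasion(
                    session, op["index"], op["time"], op.get("place", ""),
                    op.get("occasion", ""))
            elif kind == "detail_entry":
                detail_entry(
                    session, op["index"], op["food_id"],
                    _portion_from_json(op["portion"]),
                    db=db, eq=eq,
                    variant_option=op.get("variant_option", ""),
                    cooking_method=op.get("cooking_method"),
                    oil_food_id=op.get("oil_food_id"),
                    quality_note=op.get("quality_note", ""),
                )
            elif kind == "begin_final_probe":
                begin_final_probe(session)
            elif kind == "edit_entry":
                edit_entry(
                    session, op["index"], db=db, eq=eq,
                    food=op.get("food_id"),
                    portion=_portion_from_json(op["portion"]) if op.get("portion") else None,
                    variant_option=op.get("variant_option", ""),
                )
            elif kind == "finalize":
                recall = finalize(session)
            else:
                raise ValidationError(f"unknown transcript operation {kind!r}")
        except Exception as e:
            e.add_note(f"at transcript step {i} ({kind})")
            raise
    if session is None:
        raise ValidationError("empty transcript")
    return session, recall
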