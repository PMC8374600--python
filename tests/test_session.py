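"""Five-pass interview state machine: pass order, detailing, finalisation."""

import random
from datetime import date
from fractions import Fraction

import pytest

from recall24.errors import (
    CompletenessError,
    IntegrityError,
    NoEquivalenceError,
    StateError,
    ValidationError,
)
from recall24.measures import PortionSpec
from recall24.session import (
    FORGOTTEN_CATEGORIES,
    Participant,
    add_quick_item,
    assign_time_place_occasion,
    begin_final_probe,
    detail_entry,
    edit_entry,
    finalize,
    forgotten_probe,
    recall_from_json,
    recall_to_json,
    replay_transcript,
    start_session,
)

P = Participant("p001", "demo participant")
DAY = date(2020, 6, 15)


def fresh():
    return start_session(P, "int01", DAY, today=date(2020, 6, 16))


class TestStartSession:
    def test_opens_in_quick_list_with_no_entries(self):
        s = fresh()
        assert (s.state, s.entries) == ("QUICK_LIST", [])
        assert all(not asked for asked in s.probe_checklist.values())

    def test_future_recall_date_rejected(self):
        with pytest.raises(ValidationError):
            start_session(P, "int01", date(2020, 6, 17), today=date(2020, 6, 16))

    def test_day_type_vocabulary_is_closed(self):
        with pytest.raises(ValidationError):
            start_session(P, "int01", DAY, day_type="ordinary", today=DAY)

    def test_unknown_participant_against_registry(self):
        with pytest.raises(IntegrityError):
            start_session(P, "int01", DAY, registry={}, today=DAY)

    def test_multiple_recalls_per_participant_are_distinct_sessions(self):
        a = start_session(P, "int01", date(2020, 6, 14), today=DAY)
        b = start_session(P, "int01", date(2020, 6, 15), today=DAY)
        assert a.session_id != b.session_id


class TestQuickListAndProbe:
    def test_quick_items_preserve_report_order_undetailed(self, worked_recall):
        s = fresh()
        for label, *_ in worked_recall.expected_rows:
            add_quick_item(s, label)
        assert len(s.entries) == 24
        assert [e.label for e in s.entries] == [r[0] for r in worked_recall.expected_rows]
        assert not any(e.detailed for e in s.entries)

    def test_empty_label_rejected(self):
        with pytest.raises(ValidationError):
            add_quick_item(fresh(), "   ")

    def test_forgotten_probe_returns_the_seven_categories_in_order(self):
        s = fresh()
        assert tuple(forgotten_probe(s)) == FORGOTTEN_CATEGORIES
        assert s.state == "FORGOTTEN"
        assert all(s.probe_checklist.values())

    def test_probe_after_time_pass_is_a_state_error(self):
        s = fresh()
        add_quick_item(s, "pan")
        forgotten_probe(s)
        assign_time_place_occasion(s, 0, "12:00", "At home", "Lunch")
        with pytest.raises(StateError):
            forgotten_probe(s)


class TestTimePlaceOccasion:
    def test_fields_stored_with_zero_filled_time(self):
        s = fresh()
        add_quick_item(s, "carne")
        forgotten_probe(s)
        assign_time_place_occasion(s, 0, "13:00:00", "At home", "Lunch")
        e = s.entries[0]
        assert (e.time, e.place, e.occasion) == ("13:00:00", "At home", "Lunch")

    def test_seconds_optional_on_input(self):
        s = fresh()
        add_quick_item(s, "agua")
        forgotten_probe(s)
        assign_time_place_occasion(s, 0, "7:30", "At home")
        assert s.entries[0].time == "07:30:00"

    def test_occasion_may_be_empty(self):
        s = fresh()
        add_quick_item(s, "agua")
        forgotten_probe(s)
        assign_time_place_occasion(s, 0, "09:30", "At home", "")
        assert s.entries[0].occasion == ""

    @pytest.mark.parametrize("bad", ["25:00", "12:61", "noon", "12", "12:00:99"])
    def test_malformed_times_rejected(self, bad):
        s = fresh()
        add_quick_item(s, "agua")
        forgotten_probe(s)
        with pytest.raises(ValidationError):
            assign_time_place_occasion(s, 0, bad, "At home")

    def test_occasion_outside_vocabulary_rejected(self):
        s = fresh()
        add_quick_item(s, "agua")
        forgotten_probe(s)
        with pytest.raises(ValidationError):
            assign_time_place_occasion(s, 0, "10:00", "At home", "Brunch")


def detailed_session(worked_recall, n=1):
    s = fresh()
    for label, *_ in worked_recall.expected_rows[:n]:
        add_quick_item(s, label)
    forgotten_probe(s)
    for i, (_, time, place, occasion, *_rest) in enumerate(worked_recall.expected_rows[:n]):
        assign_time_place_occasion(s, i, time, place, occasion)
    return s


class TestDetailing:
    def test_oats_three_tablespoons_detail_to_18_grams(self, worked_recall):
        s = detailed_session(worked_recall, n=2)
        detail_entry(s, 1, "oats",
                     PortionSpec(mode="household_measure", measure_id=11, quantity=3),
                     db=worked_recall.db, eq=worked_recall.eq)
        assert s.entries[1].grams == 18.0 and s.entries[1].detailed

    def test_missing_equivalence_leaves_entry_undetailed(self, worked_recall):
        s = detailed_session(worked_recall)
        with pytest.raises(NoEquivalenceError):
            detail_entry(s, 0, "honey",
                         PortionSpec(mode="household_measure", measure_id=11, quantity=1),
                         db=worked_recall.db, eq=worked_recall.eq)
        assert not s.entries[0].detailed

    def test_fried_detail_inserts_a_detailed_oil_entry(self, worked_recall):
        s = detailed_session(worked_recall)
        detail_entry(s, 0, "potato",
                     PortionSpec(mode="exact", exact_amount=200, exact_unit="g"),
                     db=worked_recall.db, eq=worked_recall.eq, cooking_method="fried",
                     oil_food_id="oil-sunflower")
        assert len(s.entries) == 2
        oil = s.entries[1]
        assert (oil.food_id, oil.grams, oil.detailed) == ("oil-sunflower", 20.0, True)
        assert (oil.time, oil.place, oil.occasion) == (
            s.entries[0].time, s.entries[0].place, s.entries[0].occasion)

    def test_variant_option_resolves_during_detailing(self, worked_recall):
        s = detailed_session(worked_recall)
        detail_entry(s, 0, "milk",
                     PortionSpec(mode="exact", exact_amount=100, exact_unit="mL"),
                     db=worked_recall.db, eq=worked_recall.eq, variant_option="soymilk")
        assert s.entries[0].food_id == "soymilk"

    def test_detailing_twice_directs_to_edit(self, worked_recall):
        s = detailed_session(worked_recall)
        portion = PortionSpec(mode="exact", exact_amount=50, exact_unit="g")
        detail_entry(s, 0, "honey", portion, db=worked_recall.db, eq=worked_recall.eq)
        with pytest.raises(ValidationError, match="edit_entry"):
            detail_entry(s, 0, "honey", portion, db=worked_recall.db, eq=worked_recall.eq)


class TestEditing:
    def test_quantity_edit_rederives_grams(self, worked_recall):
        s = detailed_session(worked_recall)
        detail_entry(s, 0, "sugar",
                     PortionSpec(mode="household_measure", measure_id=14, quantity=1),
                     db=worked_recall.db, eq=worked_recall.eq)
        assert s.entries[0].grams == 2.0
        edit_entry(s, 0, db=worked_recall.db, eq=worked_recall.eq,
                   portion=PortionSpec(mode="household_measure", measure_id=14,
                                       quantity=Fraction("2.5")))
        assert s.entries[0].grams == 5.0
        assert len(s.audit) == 1

    def test_identical_edit_is_content_idempotent_but_audited(self, worked_recall):
        s = detailed_session(worked_recall)
        portion = PortionSpec(mode="household_measure", measure_id=13, quantity=2)
        detail_entry(s, 0, "honey", portion, db=worked_recall.db, eq=worked_recall.eq)
        before = s.entries[0]
        edit_entry(s, 0, db=worked_recall.db, eq=worked_recall.eq)
        after = s.entries[0]
        assert (after.food_id, after.grams, after.label) == (
            before.food_id, before.grams, before.label)
        assert len(s.audit) == 1

    def test_stored_recall_is_editable_while_session_stays_finalized(self, worked_recall):
        _, recall = replay_transcript(worked_recall.transcript, worked_recall.db, worked_recall.eq)
        session, _ = replay_transcript(worked_recall.transcript, worked_recall.db, worked_recall.eq)
        edit_entry(recall, 4, db=worked_recall.db, eq=worked_recall.eq,
                   portion=PortionSpec(mode="household_measure", measure_id=14,
                                       quantity=3))
        assert recall.entries[4].grams == 6.0
        assert session.state == "FINALIZED"

    def test_out_of_range_index_is_an_error(self, worked_recall):
        s = detailed_session(worked_recall)
        with pytest.raises(ValidationError):
            edit_entry(s, 5, db=worked_recall.db, eq=worked_recall.eq)


class TestFinalize:
    def test_fully_detailed_recall_finalizes(self, worked_recall):
        session, recall = replay_transcript(worked_recall.transcript, worked_recall.db, worked_recall.eq)
        assert recall is not None and len(recall.entries) == 24
        assert session.state == "FINALIZED"

    def test_undetailed_entry_blocks_finalisation_naming_it(self, worked_recall):
        s = detailed_session(worked_recall)
        detail_entry(s, 0, "water",
                     PortionSpec(mode="household_measure", measure_id=8, quantity=1),
                     db=worked_recall.db, eq=worked_recall.eq)
        begin_final_probe(s)
        add_quick_item(s, "caramelos")
        with pytest.raises(CompletenessError, match="caramelos"):
            finalize(s)

    def test_item_added_in_final_probe_can_be_detailed_then_finalized(self, worked_recall):
        s = detailed_session(worked_recall)
        detail_entry(s, 0, "water",
                     PortionSpec(mode="household_measure", measure_id=8, quantity=1),
                     db=worked_recall.db, eq=worked_recall.eq)
        begin_final_probe(s)
        add_quick_item(s, "caramelos")
        assert not s.entries[-1].detailed
        detail_entry(s, len(s.entries) - 1, "sugar",
                     PortionSpec(mode="exact", exact_amount=10, exact_unit="g"),
                     db=worked_recall.db, eq=worked_recall.eq)
        recall = finalize(s)
        assert len(recall.entries) == 2

    def test_finalize_twice_is_a_state_error(self, worked_recall):
        s, _ = replay_transcript(worked_recall.transcript[:-1], worked_recall.db, worked_recall.eq)
        finalize(s)
        with pytest.raises(StateError):
            finalize(s)

    def test_recall_round_trips_through_json(self, worked_recall):
        _, recall = replay_transcript(worked_recall.transcript, worked_recall.db, worked_recall.eq)
        assert recall_from_json(recall_to_json(recall)) == recall


class TestReachability:
    """Randomised operation sequences: legal orders succeed, illegal orders error.

    An independent mirror of the documented pass rules predicts legality;
    the session must agree on every step. Finalisation succeeds exactly when
    every entry is detailed (completeness), and FINALIZED is reachable only
    through the full pass order.
    """

    OPS = ("add", "probe", "assign", "detail", "final_probe", "finalize")

    @staticmethod
    def predict(model, op, index):
        state, n, detailed = model["state"], model["n"], model["detailed"]
        if op == "add":
            return state in ("QUICK_LIST", "FORGOTTEN", "FINAL_PROBE")
        if op == "probe":
            return state in ("QUICK_LIST", "FORGOTTEN")
        if op == "assign":
            return state in ("FORGOTTEN", "TIME_OCCASION", "DETAIL",
                             "FINAL_PROBE") and 0 <= index < n
        if op == "detail":
            return (state in ("TIME_OCCASION", "DETAIL", "FINAL_PROBE")
                    and 0 <= index < n and not detailed[index])
        if op == "final_probe":
            return state == "DETAIL"
        if op == "finalize":
            return state == "FINAL_PROBE" and all(detailed)
        raise AssertionError(op)

    @staticmethod
    def apply_model(model, op, index):
        if op == "add":
            model["n"] += 1
            model["detailed"].append(False)
        elif op == "probe":
            model["state"] = "FORGOTTEN"
        elif op == "assign":
            if model["state"] == "FORGOTTEN":
                model["state"] = "TIME_OCCASION"
        elif op == "detail":
            model["detailed"][index] = True
            if model["state"] == "TIME_OCCASION":
                model["state"] = "DETAIL"
        elif op == "final_probe":
            model["state"] = "FINAL_PROBE"
        elif op == "finalize":
            model["state"] = "FINALIZED"

    def run_op(self, s, worked_recall, op, index):
        portion = PortionSpec(mode="exact", exact_amount=50, exact_unit="g")
        if op == "add":
            add_quick_item(s, "item")
        elif op == "probe":
            forgotten_probe(s)
        elif op == "assign":
            assign_time_place_occasion(s, index, "12:00", "At home", "Lunch")
        elif op == "detail":
            detail_entry(s, index, "honey", portion, db=worked_recall.db, eq=worked_recall.eq)
        elif op == "final_probe":
            begin_final_probe(s)
        elif op == "finalize":
            finalize(s)

    def test_random_sequences_agree_with_the_pass_order_model(self, worked_recall):
        rng = random.Random(20240615)
        for _ in range(1000):
            s = fresh()
            model = {"state": "QUICK_LIST", "n": 0, "detailed": []}
            for _ in range(rng.randint(4, 12)):
                op = rng.choice(self.OPS)
                index = rng.randrange(-1, model["n"] + 1) if model["n"] else 0
                legal = self.predict(model, op, index)
                try:
                    self.run_op(s, worked_recall, op, index)
                except (StateError, ValidationError, CompletenessError):
                    assert not legal, (op, index, model, s.state)
                else:
                    assert legal, (op, index, model, s.state)
                    self.apply_model(model, op, index)
                assert s.state == model["state"]
                assert len(s.entries) == model["n"]

    def test_transcript_missing_detail_step_fails_with_label(self, worked_recall):
        ops = [op for op in worked_recall.transcript
               if not (op["op"] == "detail_entry" and op["index"] == 3)]
        with pytest.raises(CompletenessError, match="Raisins"):
            replay_transcript(ops, worked_recall.db, worked_recall.eq)
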