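"""Portion→gram conversion, unit weights, and group-weight inference."""

from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from recall24.errors import InsufficientDataError, NoEquivalenceError
from recall24.fixtures import GeneratorConfig, generate_equivalence_table
from recall24.measures import (
    EquivalenceTable,
    MEASURE_REGISTRY,
    PortionSpec,
    convert_quantity,
    group_correlation,
    infer_group_weights,
    load_equivalences,
    save_equivalences,
    unit_weight,
)
from .conftest import vectors_of


def test_registry_has_exactly_16_measures_with_unique_ids():
    assert sorted(MEASURE_REGISTRY) == list(range(1, 17))
    labels = {5: "Big glass", 8: "Big cup", 11: "Tablespoon",
              13: "Teaspoon", 14: "Coffee spoon", 15: "Big ladle"}
    for mid, label in labels.items():
        assert MEASURE_REGISTRY[mid].label == label


class TestConvertQuantity:
    def test_every_worked_recall_row_converts_to_its_printed_grams(self, worked_recall):
        for label, _, _, _, fid, portion_json, grams in worked_recall.expected_rows:
            portion = PortionSpec(
                mode=portion_json["mode"],
                measure_id=portion_json.get("measure_id"),
                size=portion_json.get("size"),
                quantity=Fraction(portion_json["quantity"]),
            )
            got = convert_quantity(worked_recall.db.foods[fid], portion, worked_recall.eq)
            assert got == pytest.approx(grams, abs=0), (label, got, grams)

    def test_quantity_one_returns_the_table_weight(self, worked_recall):
        portion = PortionSpec(mode="household_measure", measure_id=13, quantity=1)
        assert convert_quantity(worked_recall.db.foods["honey"], portion, worked_recall.eq) == 6.3

    def test_fractional_quantities_are_exact(self, worked_recall):
        # 2.5 coffee spoons of sugar at 2 g per spoon
        portion = PortionSpec(mode="household_measure", measure_id=14,
                              quantity=Fraction("2.5"))
        assert convert_quantity(worked_recall.db.foods["sugar"], portion, worked_recall.eq) == 5.0

    def test_missing_equivalence_row_names_food_and_measure(self, worked_recall):
        portion = PortionSpec(mode="household_measure", measure_id=11, quantity=1)
        with pytest.raises(NoEquivalenceError, match="Miel.*Tablespoon"):
            convert_quantity(worked_recall.db.foods["honey"], portion, worked_recall.eq)

    def test_exact_mode_passes_grams_through(self, worked_recall):
        portion = PortionSpec(mode="exact", exact_amount=Fraction("37.5"), exact_unit="g")
        assert convert_quantity(worked_recall.db.foods["honey"], portion, worked_recall.eq) == 37.5

    def test_exact_milligrams_convert_to_grams(self, worked_recall):
        portion = PortionSpec(mode="exact", exact_amount=Fraction(500), exact_unit="mg")
        assert convert_quantity(worked_recall.db.foods["honey"], portion, worked_recall.eq) == 0.5

    @given(q1=st.fractions(min_value=Fraction(1, 100), max_value=10),
           q2=st.fractions(min_value=Fraction(1, 100), max_value=10))
    def test_linearity_up_to_rounding(self, worked_recall, q1, q2):
        food, eq = worked_recall.db.foods["creamy-cheese"], worked_recall.eq
        def grams(q):
            return convert_quantity(
                food, PortionSpec(mode="household_measure", measure_id=13, quantity=q), eq)
        assert abs(grams(q1 + q2) - (grams(q1) + grams(q2))) <= 0.1 + 1e-9

    @given(q=st.fractions(min_value=Fraction(1, 100), max_value=10),
           dq=st.fractions(min_value=Fraction(1, 10), max_value=5))
    def test_grams_strictly_increase_with_quantity(self, worked_recall, q, dq):
        food, eq = worked_recall.db.foods["potato-boiled"], worked_recall.eq
        lo = convert_quantity(food, PortionSpec(mode="household_measure",
                                                measure_id=15, quantity=q), eq)
        hi = convert_quantity(food, PortionSpec(mode="household_measure",
                                                measure_id=15, quantity=q + dq), eq)
        assert hi > lo

    def test_rows_sharing_a_measure_imply_one_consistent_weight(self, worked_recall):
        implied: dict[tuple, set] = {}
        for _, _, _, _, fid, pj, grams in worked_recall.expected_rows:
            key = (fid, pj["mode"], pj.get("measure_id"), pj.get("size"))
            implied.setdefault(key, set()).add(
                Fraction(str(grams)) / Fraction(pj["quantity"]))
        assert all(len(weights) == 1 for weights in implied.values())


class TestUnitWeight:
    def test_sized_units_convert(self, worked_recall):
        raisins = worked_recall.db.foods["raisins"]
        assert unit_weight(raisins, "medium", worked_recall.eq) == pytest.approx(0.4)
        egg = worked_recall.db.foods["egg"]
        assert unit_weight(egg, "unit", worked_recall.eq) == 42.0

    def test_absent_size_error_lists_available_sizes(self, worked_recall):
        with pytest.raises(NoEquivalenceError, match=r"\{unit\}"):
            unit_weight(worked_recall.db.foods["egg"], "small", worked_recall.eq)


class TestGroupInference:
    def test_single_member_ratio_one_returns_identical_vector(self):
        vec = {m: float(m * 10) for m in range(1, 17)}
        inferred, prov = infer_group_weights({"a": vec}, "b", reference_ratio=1.0)
        assert {m: float(w) for m, w in inferred.items()} == vec
        assert prov == "inferred"

    def test_ratio_two_doubles_every_component(self):
        vec = {m: float(m) for m in range(1, 17)}
        inferred, _ = infer_group_weights({"a": vec}, "b", reference_ratio=2.0)
        assert all(float(inferred[m]) == 2.0 * vec[m] for m in vec)

    def test_no_anchor_returns_group_mean_flagged_unscaled(self):
        vecs = {"a": {1: 10.0, 2: 20.0}, "b": {1: 30.0, 2: 40.0}}
        inferred, prov = infer_group_weights(vecs, "c")
        assert prov == "unscaled"
        assert float(inferred[1]) == 20.0 and float(inferred[2]) == 30.0

    def test_no_measured_members_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            infer_group_weights({}, "x")

    def test_inference_recovers_generator_truth_without_noise(self):
        fx = generate_equivalence_table(
            GeneratorConfig(seed=5, n_eq_foods=20, n_groups=4, noise_sd=0.0))
        gname, members = next(iter(fx.groups.items()))
        vecs = vectors_of(fx, members)
        target = members[-1]
        ratio = fx.scales[target] / (
            sum(fx.scales[m] for m in members[:-1]) / (len(members) - 1))
        inferred, _ = infer_group_weights(
            {m: vecs[m] for m in members[:-1]}, target, reference_ratio=ratio)
        for mid, w in inferred.items():
            assert float(w) == pytest.approx(vecs[target][mid], rel=0.01)

    def test_inference_homogeneity_scaling_members_scales_output(self):
        vec = {m: float(m + 1) for m in range(1, 17)}
        base, _ = infer_group_weights({"a": vec}, "t", reference_ratio=1.5)
        scaled_members = {"a": {m: 3.0 * v for m, v in vec.items()}}
        scaled, _ = infer_group_weights(scaled_members, "t", reference_ratio=1.5)
        assert all(float(scaled[m]) == pytest.approx(3.0 * float(base[m])) for m in vec)


class TestGroupCorrelation:
    def test_identical_vectors_correlate_perfectly(self):
        vec = {1: 5.0, 2: 9.0, 3: 21.0, 4: 2.0}
        [(_, _, r, ok)] = group_correlation({"a": vec, "b": dict(vec)})
        assert r == pytest.approx(1.0, abs=1e-12) and ok

    def test_generated_groups_meet_the_099_rule(self, eq_fixture):
        for members in eq_fixture.groups.values():
            for _, _, r, ok in group_correlation(vectors_of(eq_fixture, members)):
                assert ok and r >= 0.99

    def test_flags_pairs_below_threshold(self):
        a = {1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0}
        b = {1: 4.0, 2: 1.0, 3: 3.0, 4: 2.0}
        results = group_correlation({"a": a, "b": b})
        assert results[0][3] is False

    def test_two_shared_measures_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            group_correlation({"a": {1: 1.0, 2: 2.0}, "b": {1: 2.0, 2: 4.0}})

    def test_single_member_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            group_correlation({"a": {1: 1.0, 2: 2.0, 3: 3.0}})


def test_equivalence_table_round_trips_through_csv(worked_recall, tmp_path):
    save_equivalences(worked_recall.eq, tmp_path)
    reloaded = load_equivalences(tmp_path)
    assert reloaded.rows == worked_recall.eq.rows
    assert reloaded.unit_weights == worked_recall.eq.unit_weights
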