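"""Zero cleaning, median unification, rounding and the outlier screen."""

import random

import pytest
from hypothesis import given, strategies as st

from fcdbkit.core import (
    ComponentDefinition,
    ComponentRegistry,
    ComponentValue,
    FoodEx2Code,
    SourceFoodRecord,
)
from fcdbkit.fixtures import FixtureSpec, generate_sources
from fcdbkit.unify import (
    OutlierConfig,
    UnifiedFood,
    clean_zeros,
    flag_outliers,
    foods_to_json,
    round_standard,
    unify_component,
    unify_database,
)
from _helpers import assert_matches_oracle, oracle_unify, run_pipeline


def cv(value, status="measured"):
    return ComponentValue("X", value, "g" if value is not None else None, status)


class TestCleanZeros:
    def test_zeros_removed_from_pool(self):
        out = clean_zeros([cv(2.0), cv(0.0, "zero"), cv(4.0)])
        assert [c.status for c in out] == ["measured", "missing", "measured"]
        assert [c.numeric for c in out if c.status == "measured"] == [2.0, 4.0]

    def test_all_zero_input_empties_pool(self):
        out = clean_zeros([cv(0.0, "zero"), cv(0.0, "zero")])
        assert all(c.status == "missing" for c in out)

    def test_no_zeros_unchanged(self):
        vals = [cv(1.0), cv(2.0)]
        assert clean_zeros(vals) == vals

    def test_logical_zero_and_trace_pass_through(self):
        out = clean_zeros([cv(0.0, "logical_zero"), cv(0.0, "trace")])
        assert [c.status for c in out] == ["logical_zero", "trace"]


class TestUnifyComponent:
    def pool(self, values):
        return [(f"s{i}", f"f{i}", v) for i, v in enumerate(values)]

    def test_odd_n_median(self):
        uv = unify_component(self.pool([2.8, 3.1, 3.5]))
        assert uv.median == 3.1 and uv.n_sources == 3

    def test_even_n_midpoint(self):
        assert unify_component(self.pool([2.0, 4.0])).median == 3.0

    def test_median_resists_outlier_better_than_mean(self):
        uv = unify_component(self.pool([1.0, 1.2, 1.1, 9.0]))
        assert uv.median == 1.15
        assert uv.mean == 3.075
        # the median stays with the dense cluster
        assert abs(uv.median - 1.1) < abs(uv.mean - 1.1)

    def test_single_value_sd_zero(self):
        uv = unify_component(self.pool([5.0]))
        assert uv.sd == 0.0 and uv.median == 5.0

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            unify_component([])

    def test_bounds_invariant(self):
        uv = unify_component(self.pool([3.0, 9.0, 4.0, 8.0, 5.0]))
        assert min(3.0, 9.0) <= uv.median <= 9.0
        assert len(uv.contributors) == uv.n_sources


class TestRoundStandard:
    @pytest.mark.parametrize("value,cls,expected", [
        (3.1416, "proximate", 3.1),
        (165.04, "energy", 165.0),
        (0.012345, "mineral", 0.0123),
        (0.0123456, "vitamin", 0.0123),
        (123.456, "polyphenol", 123.0),
        (0, "mineral", 0.0),
        (2.25, "proximate", 2.3),      # half-up at one decimal
        (1.115, "mineral", 1.12),      # half-up at 3 significant figures
        (0.9999, "fatty_acid", 1.0),   # carry across the magnitude boundary
    ])
    def test_rounding_rules(self, value, cls, expected):
        assert round_standard(value, cls) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            round_standard(-1.0, "mineral")


class TestFlagOutliers:
    def food(self, values):
        uv = unify_component([(f"s{i}", f"f{i}", v) for i, v in enumerate(values)])
        uv.tagname = "X"
        food = UnifiedFood(FoodEx2Code("A0001"), "x", "g")
        food.values["X"] = uv
        return food

    def test_extreme_value_flagged(self):
        food = flag_outliers(self.food([10, 11, 10.5, 95]))
        flagged = food.values["X"].flagged_contributors
        assert [c.value for c in flagged] == [95.0]
        assert food.values["X"].outlier_flag

    def test_zero_dispersion_no_flags(self):
        food = flag_outliers(self.food([10, 10, 10]))
        assert not food.values["X"].outlier_flag

    def test_two_sources_never_flagged(self):
        food = flag_outliers(self.food([1.0, 1000.0]))
        assert not food.values["X"].outlier_flag

    def test_extreme_cv_flags_whole_component(self):
        food = flag_outliers(self.food([1.0, 2.0, 3.0, 4.0, 200.0]),
                             OutlierConfig(z_threshold=1e9, cv_threshold=2.0))
        uv = food.values["X"]
        assert uv.outlier_flag and not uv.flagged_contributors

    def test_flags_never_change_chosen(self):
        food = self.food([10, 11, 10.5, 95])
        before = food.values["X"].chosen
        assert flag_outliers(food).values["X"].chosen == before


def _registry():
    return ComponentRegistry([
        ComponentDefinition("PROT", "protein", "g", "proximate"),
        ComponentDefinition("VITC", "vitamin C", "mg", "vitamin"),
    ])


def _rec(sid, code, prot=None, vitc=None, fid=None, name="food", status="measured"):
    values = {}
    if prot is not None:
        values["PROT"] = ComponentValue("PROT", prot, "g")
    if vitc is not None:
        values["VITC"] = (ComponentValue("VITC", 0.0, "mg", status)
                          if vitc == "z" else ComponentValue("VITC", vitc, "mg"))
    return SourceFoodRecord(sid, fid or f"{sid}-{code}", name,
                            FoodEx2Code(code), english_name=name, values=values)


class TestUnifyDatabase:
    def test_three_sources_one_code(self):
        records = [_rec(f"s{i}", "A00MH", prot=2.8 + 0.1 * i, vitc=10.0 + i)
                   for i in range(3)]
        foods, report = unify_database(records, _registry())
        assert len(foods) == 1
        food = foods[0]
        assert food.matched and food.values["PROT"].n_sources == 3
        assert report.n_matched == 1 and report.n_singleton == 0

    def test_disjoint_codes_all_singletons(self):
        records = [_rec("s1", "A0001", prot=1.0), _rec("s2", "A0002", prot=2.0)]
        foods, report = unify_database(records, _registry())
        assert len(foods) == 2
        assert all(not f.matched for f in foods)
        assert report.n_singleton == 2

    def test_empty_input(self):
        foods, report = unify_database([], _registry())
        assert foods == [] and report.n_unified_foods == 0

    def test_all_logical_zero_reinstated_as_zero(self):
        records = [_rec(f"s{i}", "A00MH", vitc="z", status="logical_zero")
                   for i in range(3)]
        foods, _ = unify_database(records, _registry())
        uv = foods[0].values["VITC"]
        assert uv.chosen == 0.0 and uv.logical_zero

    def test_plain_zeros_leave_component_missing(self):
        records = [_rec(f"s{i}", "A00MH", vitc="z", status="zero")
                   for i in range(3)]
        foods, _ = unify_database(records, _registry())
        assert "VITC" not in foods[0].values

    def test_measured_value_beats_logical_zero(self):
        records = [_rec("s1", "A00MH", vitc="z", status="logical_zero"),
                   _rec("s2", "A00MH", vitc=8.0)]
        foods, _ = unify_database(records, _registry())
        uv = foods[0].values["VITC"]
        assert uv.chosen == 8.0 and uv.n_sources == 1

    def test_name_from_richest_source_tie_broken_lexicographically(self):
        records = [
            _rec("s2", "A00MH", prot=1.0, name="rich two"),
            _rec("s1", "A00MH", prot=1.0, vitc=3.0, name="richest"),
            _rec("s3", "A00MH", prot=1.0, name="rich three"),
        ]
        foods, _ = unify_database(records, _registry())
        assert foods[0].name == "richest"
        records = [_rec("s2", "A00MH", prot=1.0, name="from s2"),
                   _rec("s1", "A00MH", prot=1.0, name="from s1")]
        foods, _ = unify_database(records, _registry())
        assert foods[0].name == "from s1"

    def test_order_invariance(self, noisy_bundle):
        foods, _ = run_pipeline(noisy_bundle)
        records = []
        for sid in sorted(noisy_bundle.tables):
            from fcdbkit.ingest import ingest_source
            recs, _ = ingest_source(noisy_bundle.tables[sid],
                                    noisy_bundle.mappings[sid],
                                    noisy_bundle.registry)
            records.extend(recs)
        rng = random.Random(42)
        rng.shuffle(records)
        shuffled, _ = unify_database(records, noisy_bundle.registry)
        assert foods_to_json(shuffled) == foods_to_json(foods)

    def test_matches_brute_force_oracle_on_noisy_fixture(self, noisy_bundle):
        from fcdbkit.ingest import ingest_source
        records = []
        for sid in sorted(noisy_bundle.tables):
            recs, _ = ingest_source(noisy_bundle.tables[sid],
                                    noisy_bundle.mappings[sid],
                                    noisy_bundle.registry)
            records.extend(recs)
        foods, _ = unify_database(records, noisy_bundle.registry)
        assert_matches_oracle(foods, oracle_unify(records, noisy_bundle.registry))

    def test_chosen_within_contributor_bounds(self, noisy_bundle):
        foods, _ = run_pipeline(noisy_bundle)
        for food in foods:
            for uv in food.values.values():
                if not uv.contributors:
                    continue
                vals = [c.value for c in uv.contributors]
                assert min(vals) <= uv.median <= max(vals)


@given(values=st.lists(st.floats(min_value=0.001, max_value=1e4,
                                 allow_nan=False), min_size=1, max_size=9))
def test_median_bounds_property(values):
    uv = unify_component([(f"s{i}", "f", v) for i, v in enumerate(values)])
    assert min(values) <= uv.median <= max(values)
    assert uv.n_sources == len(values)
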