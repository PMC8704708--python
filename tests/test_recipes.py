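"""Mixed-method recipe computation: factor lookup precedence, the
worked single-ingredient example, limits and invariants."""

import pytest

from fcdbkit.core import ComponentDefinition, ComponentRegistry, FoodEx2Code
from fcdbkit.fixtures import generate_recipes
from fcdbkit.recipes import (
    ANY,
    FactorLookupError,
    Recipe,
    RecipeIngredient,
    RetentionFactorEntry,
    RetentionFactorTable,
    YieldFactorEntry,
    YieldFactorTable,
    compute_recipe,
    verify_recipe_model,
)
from fcdbkit.unify import UnifiedFood, UnifiedValue


def registry():
    return ComponentRegistry([
        ComponentDefinition("VITC", "vitamin C", "mg", "vitamin"),
        ComponentDefinition("PROT", "protein", "g", "proximate"),
    ])


def unified_food(code, group, values, ep=1.0):
    food = UnifiedFood(FoodEx2Code(code), f"food {code}", group,
                       edible_portion=ep)
    for tag, v in values.items():
        food.values[tag] = UnifiedValue(tagname=tag, n_sources=1, mean=v,
                                        median=v, sd=0.0, chosen=v)
    return food


class TestRetentionLookup:
    def table(self):
        return RetentionFactorTable([
            RetentionFactorEntry("boiled", 0.55, tagname="VITC",
                                 food_group="vegetables"),
            RetentionFactorEntry("boiled", 0.60, tagname="VITC"),
            RetentionFactorEntry("boiled", 0.70, component_class="vitamin",
                                 food_group="vegetables"),
            RetentionFactorEntry("boiled", 0.80, component_class="vitamin"),
        ])

    def test_most_specific_wins(self):
        m = self.table().lookup("VITC", "vitamin", "vegetables", "boiled")
        assert m.rf == 0.55

    def test_tagname_any_group(self):
        m = self.table().lookup("VITC", "vitamin", "fruit", "boiled")
        assert m.rf == 0.60

    def test_class_specific_group(self):
        m = self.table().lookup("THIA", "vitamin", "vegetables", "boiled")
        assert m.rf == 0.70

    def test_class_any_group(self):
        m = self.table().lookup("THIA", "vitamin", "fruit", "boiled")
        assert m.rf == 0.80

    def test_default_is_one(self):
        m = self.table().lookup("CA", "mineral", "fruit", "boiled")
        assert m.rf == 1.0 and m.rule is None

    def test_method_must_match(self):
        m = self.table().lookup("VITC", "vitamin", "vegetables", "fried")
        assert m.rf == 1.0

    def test_rf_bounds(self):
        with pytest.raises(ValueError):
            RetentionFactorEntry("boiled", -0.1, tagname="VITC")
        # gains through cooking are allowed
        assert RetentionFactorEntry("fried", 1.4, tagname="FAT").rf == 1.4

    def test_exactly_one_key_kind(self):
        with pytest.raises(ValueError):
            RetentionFactorEntry("boiled", 0.5)

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "rf.csv"
        table = self.table()
        table.to_csv(path)
        assert RetentionFactorTable.from_csv(path).entries == table.entries


class TestComputeRecipe:
    def setup_method(self):
        self.db = {"A0001": unified_food(
            "A0001", "vegetables", {"VITC": 20.0}, ep=0.8)}
        self.registry = registry()
        self.yf = YieldFactorTable([YieldFactorEntry(ANY, "boiled", 0.9)])
        self.rf = RetentionFactorTable([
            RetentionFactorEntry("boiled", 0.7, tagname="VITC")])

    def test_single_ingredient_worked_example(self):
        """Potato 200 g raw, EP 0.8, 20 mg/100 g vitamin C, RF 0.7, YF 0.9."""
        recipe = Recipe("R1", "boiled potato", "boiled",
                        [RecipeIngredient("A0001", 200.0)])
        res = compute_recipe(recipe, self.db, self.yf, self.rf, self.registry)
        assert res.total_cooked_weight == pytest.approx(144.0)   # 0.9 * 160
        assert res.per_component_total["VITC"] == pytest.approx(22.4)
        assert res.per_100g["VITC"] == pytest.approx(15.5556, abs=1e-4)
        (audit,) = res.factor_audit
        assert (audit.edible_portion, audit.rf, audit.yf) == (0.8, 0.7, 0.9)

    def test_identity_limit_is_weighted_mean(self):
        db = {"A0001": unified_food("A0001", "g1", {"PROT": 2.0, "VITC": 30.0}),
              "A0002": unified_food("A0002", "g2", {"PROT": 8.0, "VITC": 10.0})}
        yf = YieldFactorTable([YieldFactorEntry(ANY, "boiled", 1.0)])
        recipe = Recipe("R1", "mix", "boiled",
                        [RecipeIngredient("A0001", 100.0),
                         RecipeIngredient("A0002", 300.0)])
        res = compute_recipe(recipe, db, yf, RetentionFactorTable(), registry())
        assert res.total_cooked_weight == 400.0
        assert res.per_100g["PROT"] == pytest.approx((2.0 + 3 * 8.0) / 4)
        assert res.per_100g["VITC"] == pytest.approx((30.0 + 3 * 10.0) / 4)

    def test_doubling_weights_scale_invariance(self):
        r1 = Recipe("R1", "x", "boiled", [RecipeIngredient("A0001", 200.0)])
        r2 = Recipe("R2", "x", "boiled", [RecipeIngredient("A0001", 400.0)])
        a = compute_recipe(r1, self.db, self.yf, self.rf, self.registry)
        b = compute_recipe(r2, self.db, self.yf, self.rf, self.registry)
        assert b.per_component_total["VITC"] == pytest.approx(
            2 * a.per_component_total["VITC"])
        assert b.per_100g["VITC"] == pytest.approx(a.per_100g["VITC"])

    def test_mass_bookkeeping_exact(self):
        recipe = Recipe("R1", "x", "boiled",
                        [RecipeIngredient("A0001", 123.4,
                                          edible_portion_override=0.75)])
        res = compute_recipe(recipe, self.db, self.yf, self.rf, self.registry)
        assert res.total_cooked_weight == 0.9 * (123.4 * 0.75)

    def test_increasing_rf_never_decreases_value(self):
        recipe = Recipe("R1", "x", "boiled", [RecipeIngredient("A0001", 200.0)])
        low = compute_recipe(recipe, self.db, self.yf,
                             RetentionFactorTable([RetentionFactorEntry(
                                 "boiled", 0.5, tagname="VITC")]), self.registry)
        high = compute_recipe(recipe, self.db, self.yf,
                              RetentionFactorTable([RetentionFactorEntry(
                                  "boiled", 0.9, tagname="VITC")]), self.registry)
        assert high.per_100g["VITC"] >= low.per_100g["VITC"]

    def test_per_100g_consistent_with_totals(self):
        recipe = Recipe("R1", "x", "boiled", [RecipeIngredient("A0001", 200.0)])
        res = compute_recipe(recipe, self.db, self.yf, self.rf, self.registry)
        for tag, total in res.per_component_total.items():
            assert res.per_100g[tag] == 100.0 * total / res.total_cooked_weight

    def test_partial_components_marked(self):
        db = {"A0001": unified_food("A0001", "g1", {"PROT": 2.0, "VITC": 30.0}),
              "A0002": unified_food("A0002", "g2", {"PROT": 8.0})}
        recipe = Recipe("R1", "mix", "boiled",
                        [RecipeIngredient("A0001", 100.0),
                         RecipeIngredient("A0002", 100.0)])
        yf = YieldFactorTable([YieldFactorEntry(ANY, "boiled", 1.0)])
        res = compute_recipe(recipe, db, yf, RetentionFactorTable(), registry())
        assert res.partial_components == {"VITC"}
        assert "PROT" not in res.partial_components

    def test_unresolvable_ingredient_raises(self):
        recipe = Recipe("R1", "x", "boiled", [RecipeIngredient("A9999", 100.0)])
        with pytest.raises(KeyError):
            compute_recipe(recipe, self.db, self.yf, self.rf, self.registry)

    def test_missing_yield_factor_raises_unless_overridden(self):
        recipe = Recipe("R1", "x", "steamed", [RecipeIngredient("A0001", 100.0)])
        with pytest.raises(FactorLookupError):
            compute_recipe(recipe, self.db, self.yf, self.rf, self.registry)
        recipe.yf_override = 0.95
        res = compute_recipe(recipe, self.db, self.yf, self.rf, self.registry)
        assert res.yf == 0.95


class TestVerifyRecipeModel:
    def test_engine_matches_oracle_on_generated_recipes(self, clean_foods,
                                                        clean_bundle):
        db = {f.foodex2.code: f for f in clean_foods}
        fix = generate_recipes(db, 20, seed=5, registry=clean_bundle.registry)
        rows = verify_recipe_model(fix.recipes, db, fix.yf_table, fix.rf_table,
                                   clean_bundle.registry, fix.expected)
        assert rows and all(r["rel_diff"] <= 1e-9 for r in rows)

    def test_wrong_reference_rf_localized(self, clean_foods, clean_bundle):
        db = {f.foodex2.code: f for f in clean_foods}
        fix = generate_recipes(db, 5, seed=5, registry=clean_bundle.registry)
        target = fix.recipes[0].recipe_id
        tag = sorted(fix.expected[target].per_component_total)[0]
        fix.expected[target].per_component_total[tag] *= 1.5
        rows = verify_recipe_model(fix.recipes, db, fix.yf_table, fix.rf_table,
                                   clean_bundle.registry, fix.expected)
        bad = [r for r in rows if r["abs_diff"] > 1e-9]
        assert {(r["recipe_id"], r["component"]) for r in bad} == {(target, tag)}

    def test_empty_recipe_list(self, clean_foods, clean_bundle):
        db = {f.foodex2.code: f for f in clean_foods}
        fix = generate_recipes(db, 1, seed=5, registry=clean_bundle.registry)
        assert verify_recipe_model([], db, fix.yf_table, fix.rf_table,
                                   clean_bundle.registry, {}) == []
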