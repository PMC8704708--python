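"""Synthetic multi-source fixtures with known ground truth.

The ten source databases behind a real multi-source compilation are
licensed and cannot ship with a toolkit, so every stage here is
exercised against generated source tables that emulate the setting:
several sources describing overlapping foods under the same FoodEx2
codes, per-source multiplicative noise, discordant units, planted zeros
and planted outliers — with the true composition and the exact position
of every planted defect recorded, so unification accuracy and QC
recall/precision can be scored exactly.

Noise is multiplicative lognormal (``truth · exp(σZ)`` with
``σ = sqrt(ln(1+CV²))``), keeping values positive and centred on the
truth in the median; the default CV of 0.15 reflects the typical
between-database spread of composition values.  Ground-truth values are
pre-rounded by the standard rounding convention so that in the
noiseless limit the unified chosen values recover the truth exactly.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import ComponentDefinition, ComponentRegistry, convert_value
from .ingest import SourceMapping
from .recipes import (
    ANY,
    Recipe,
    RecipeIngredient,
    RecipeResult,
    RetentionFactorEntry,
    RetentionFactorTable,
    YieldFactorEntry,
    YieldFactorTable,
)
from .unify import UnifiedFood, round_standard

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "DefectLabel",
    "build_component_menu",
    "generate_sources",
    "plant_qc_defects",
    "perturb_export",
    "RecipeFixture",
    "generate_recipes",
]

FOOD_GROUPS = (
    "Vegetables and vegetable products",
    "Fruit and fruit products",
    "Cereals and cereal products",
    "Meat and meat products",
    "Fish and seafood",
    "Milk and dairy products",
    "Legumes, nuts and oilseeds",
    "Fats and oils",
)
#: groups whose foods genuinely contain no fibre (logical zero)
_NO_FIBER_GROUPS = {"Meat and meat products", "Fish and seafood",
                    "Milk and dairy products", "Fats and oils"}
_PLANT_GROUPS = {"Vegetables and vegetable products", "Fruit and fruit products",
                 "Cereals and cereal products", "Legumes, nuts and oilseeds"}

COOKING_METHODS = ("raw", "boiled", "fried", "roasted")

# (tagname, display name, unit, class, typical scale in standard unit)
_MICRONUTRIENT_MENU = [
    ("CA", "calcium", "mg", "mineral", 50.0),
    ("FE", "iron", "mg", "mineral", 2.0),
    ("ZN", "zinc", "mg", "mineral", 1.5),
    ("MG", "magnesium", "mg", "mineral", 30.0),
    ("NA", "sodium", "mg", "mineral", 120.0),
    ("K", "potassium", "mg", "mineral", 300.0),
    ("P", "phosphorus", "mg", "mineral", 150.0),
    ("SE", "selenium", "µg", "mineral", 10.0),
    ("MN", "manganese", "mg", "mineral", 0.5),
    ("CU", "copper", "mg", "mineral", 0.2),
    ("VITC", "vitamin C", "mg", "vitamin", 20.0),
    ("THIA", "thiamin", "mg", "vitamin", 0.2),
    ("RIBF", "riboflavin", "mg", "vitamin", 0.2),
    ("NIA", "niacin", "mg", "vitamin", 2.0),
    ("VITB6A", "vitamin B6", "mg", "vitamin", 0.3),
    ("FOL", "folate", "µg", "vitamin", 40.0),
    ("VITB12", "vitamin B12", "µg", "vitamin", 1.0),
    ("VITD", "vitamin D", "µg", "vitamin", 2.0),
    ("VITE", "vitamin E", "mg", "vitamin", 1.5),
    ("VITA_RAE", "vitamin A (RAE)", "µg", "vitamin", 60.0),
]
_CORE_MENU = [
    ("WATER", "water", "g", "proximate"),
    ("PROT", "protein", "g", "proximate"),
    ("FAT", "total fat", "g", "proximate"),
    ("CHOAVL", "available carbohydrate", "g", "proximate"),
    ("CHOCDF", "carbohydrate, by difference", "g", "proximate"),
    ("FIBTG", "dietary fibre", "g", "proximate"),
    ("ASH", "ash", "g", "proximate"),
    ("ALC", "alcohol", "g", "proximate"),
    ("ENERC_KCAL", "energy", "kcal", "energy"),
    ("FASAT", "saturated fatty acids", "g", "fatty_acid"),
    ("FAMS", "monounsaturated fatty acids", "g", "fatty_acid"),
    ("FAPU", "polyunsaturated fatty acids", "g", "fatty_acid"),
    ("CHOLE", "cholesterol", "mg", "sterol"),
]
_POLYPHENOL_NAMES = (
    "CATECHIN", "EPICATECHIN", "QUERCETIN", "KAEMPFEROL", "GALLIC_ACID",
    "CHLOROGENIC_ACID", "CAFFEIC_ACID", "RESVERATROL", "NARINGENIN",
    "HESPERETIN", "CYANIDIN", "MALVIDIN", "LUTEOLIN", "APIGENIN",
)


def build_component_menu(n_components: int) -> ComponentRegistry:
    """Registry of the first ``n_components`` of the fixture menu.

    The menu mirrors a typical compilation: proximates and energy
    first, fatty-acid summaries and cholesterol, then micronutrients,
    then compiler-tagged polyphenol components as filler (real
    compilations are dominated by polyphenols in component count).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    defs = [ComponentDefinition(t, n, u, c) for t, n, u, c in _CORE_MENU]
    defs += [ComponentDefinition(t, n, u, c)
             for t, n, u, c, _ in _MICRONUTRIENT_MENU]
    i = 0
    while len(defs) < n_components:
        base = _POLYPHENOL_NAMES[i % len(_POLYPHENOL_NAMES)]
        suffix = "" if i < len(_POLYPHENOL_NAMES) else f"_{i // len(_POLYPHENOL_NAMES)}"
        defs.append(ComponentDefinition(
            f"PP_{base}{suffix}", base.replace("_", " ").lower(), "mg",
            "polyphenol", tagname_origin="compiler_assigned"))
        i += 1
    return ComponentRegistry(defs[:max(n_components, len(_CORE_MENU))])


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions of a generated multi-source fixture.

    Defaults describe the reference setting used throughout: seven
    sources, between-source CV 0.15, 5 % planted zeros and 5 % planted
    ×10 outliers, with 60 % of foods shared by every source.
    """

    n_sources: int = 7
    n_foods: int = 60
    n_components: int = 30
    overlap_fraction: float = 0.6
    noise_cv: float = 0.15
    zero_rate: float = 0.05
    outlier_rate: float = 0.05
    outlier_factor: float = 10.0
    unit_scramble: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sources, self.n_foods, self.n_components) < 1:
            raise ValueError("counts must be >= 1")
        for name in ("overlap_fraction", "noise_cv", "zero_rate", "outlier_rate"):
            v = getattr(self, name)
            if name == "noise_cv":
                if v < 0:
                    raise ValueError("noise_cv must be >= 0")
            elif not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class DefectLabel:
    kind: str                   # "zero" | "outlier"
    source_id: str
    food_id: str
    foodex2: str
    tagname: str


@dataclass
class FoodTruth:
    foodex2: str
    name: str
    food_group: str
    edible_portion: float
    #: tagname -> true value in the standard unit (None = logical zero)
    values: dict[str, Optional[float]] = field(default_factory=dict)


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    registry: ComponentRegistry
    tables: dict[str, pd.DataFrame]
    mappings: dict[str, SourceMapping]
    truth: dict[str, FoodTruth]                  # foodex2 -> truth
    defect_labels: list[DefectLabel]

    def ground_truth(self, foodex2: str, tagname: str) -> Optional[float]:
        t = self.truth[foodex2].values.get(tagname)
        return 0.0 if t is None else t

    def write(self, out_dir: str | Path) -> None:
        """Emit CSV sources, YAML mappings and JSON truth/labels."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.registry.to_file(out / "registry.csv")
        for sid, df in sorted(self.tables.items()):
            df.to_csv(out / f"{sid}.csv", index=False)
            self.mappings[sid].to_yaml(out / f"{sid}.mapping.yaml")
        truth = {code: {"name": t.name, "food_group": t.food_group,
                        "edible_portion": t.edible_portion, "values": t.values}
                 for code, t in sorted(self.truth.items())}
        (out / "truth.json").write_text(
            json.dumps(truth, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
        (out / "defect_labels.json").write_text(
            json.dumps([asdict(d) for d in self.defect_labels], indent=2) + "\n",
            encoding="utf-8")


def _truth_for_food(idx: int, rng: np.random.Generator,
                    registry: ComponentRegistry) -> FoodTruth:
    group = FOOD_GROUPS[int(rng.integers(len(FOOD_GROUPS)))]
    code = f"A{idx:04d}"
    truth = FoodTruth(
        foodex2=code,
        name=f"fixture food {idx:04d}",
        food_group=group,
        edible_portion=round(float(rng.uniform(0.6, 1.0)), 2),
    )
    tags = {d.tagname for d in registry}

    # proximates: proportions of 100 g that always sum inside the window
    water, prot, fat, cho, ash = (
        100.0 * rng.dirichlet([30.0, 4.0, 3.0, 8.0, 1.0]))
    if fat < 0.6:           # keep total fat clearly nonzero after rounding
        water -= 0.6 - fat
        fat = 0.6
    fiber = None if group in _NO_FIBER_GROUPS else float(rng.uniform(0.5, 3.0))
    vals: dict[str, Optional[float]] = {
        "WATER": round_standard(water, "proximate"),
        "PROT": round_standard(prot, "proximate"),
        "FAT": round_standard(fat, "proximate"),
        "CHOAVL": round_standard(cho, "proximate"),
        "FIBTG": None if fiber is None else round_standard(fiber, "proximate"),
        "ASH": round_standard(ash, "proximate"),
        "ALC": None,
    }
    vals["CHOCDF"] = round_standard(
        vals["CHOAVL"] + (vals["FIBTG"] or 0.0), "proximate")
    vals["ENERC_KCAL"] = round_standard(
        4.0 * vals["PROT"] + 9.0 * vals["FAT"] + 4.0 * vals["CHOAVL"], "energy")

    # fatty-acid detail consistent with total fat
    sat, mono, poly = rng.dirichlet([2.0, 2.0, 1.0]) * 0.92 * vals["FAT"]
    vals["FASAT"] = round_standard(float(sat), "fatty_acid")
    vals["FAMS"] = round_standard(float(mono), "fatty_acid")
    vals["FAPU"] = round_standard(float(poly), "fatty_acid")
    vals["CHOLE"] = (None if group in _PLANT_GROUPS
                     else round_standard(float(rng.uniform(5.0, 90.0)), "sterol"))

    for tag, _, _, cls, scale in _MICRONUTRIENT_MENU:
        if tag not in tags:
            continue
        vals[tag] = round_standard(
            float(scale * rng.lognormal(0.0, 0.6)), cls)
    for d in registry:
        if d.component_class == "polyphenol":
            if group in _PLANT_GROUPS:
                vals[d.tagname] = round_standard(
                    float(2.0 * rng.lognormal(0.0, 1.0)), "polyphenol")
            else:
                vals[d.tagname] = None
    truth.values = {t: vals[t] for t in sorted(vals) if t in tags}
    return truth


def generate_sources(spec: FixtureSpec) -> FixtureBundle:
    """Generate per-source tables, mappings, ground truth and defect labels.

    The first ``round(overlap_fraction · n_foods)`` foods appear in
    every source; the rest are singletons assigned round-robin.  Each
    source reports ``truth × lognormal`` values, with planted zeros and
    ×``outlier_factor`` outliers recorded exhaustively in
    ``defect_labels``.  Under ``unit_scramble``, odd-numbered sources
    report mg-standard components in g (the mapping declares the true
    unit, so harmonization must undo the shift).  Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    registry = build_component_menu(spec.n_components)
    tagnames = sorted(d.tagname for d in registry)

    truths = [_truth_for_food(i, rng, registry) for i in range(spec.n_foods)]
    n_shared = round(spec.overlap_fraction * spec.n_foods)

    source_ids = [f"src{i:02d}" for i in range(spec.n_sources)]
    membership: dict[str, list[FoodTruth]] = {sid: [] for sid in source_ids}
    for i, t in enumerate(truths):
        if i < n_shared:
            for sid in source_ids:
                membership[sid].append(t)
        else:
            membership[source_ids[(i - n_shared) % spec.n_sources]].append(t)

    sigma = float(np.sqrt(np.log1p(spec.noise_cv ** 2)))
    labels: list[DefectLabel] = []
    tables: dict[str, pd.DataFrame] = {}
    mappings: dict[str, SourceMapping] = {}

    for s_idx, sid in enumerate(source_ids):
        scramble = spec.unit_scramble and s_idx % 2 == 1
        column_map: dict[str, tuple[str, str]] = {}
        col_units: dict[str, str] = {}
        for tag in tagnames:
            std = registry.resolve(tag).standard_unit
            unit = std
            if scramble and std == "mg":
                unit = "g"          # source reports grams; mapping says so
            col = f"{sid}_{tag.lower()}"
            column_map[col] = (tag, unit)
            col_units[tag] = unit

        rows = []
        for t in membership[sid]:
            food_id = f"{sid.upper()}-{t.foodex2}"
            row: dict[str, object] = {
                "id": food_id,
                "name": t.name,
                "code": t.foodex2,
                "group": t.food_group,
                "ep": t.edible_portion,
                "class": "generic",
            }
            for tag in tagnames:
                tv = t.values.get(tag)
                std = registry.resolve(tag).standard_unit
                if tv is None:
                    # logical zero in truth: sources report a literal 0
                    row[f"{sid}_{tag.lower()}"] = 0
                    continue
                value = tv
                if sigma > 0:
                    value = float(tv * np.exp(sigma * rng.standard_normal()))
                u = rng.uniform()
                if u < spec.zero_rate:
                    row[f"{sid}_{tag.lower()}"] = 0
                    labels.append(DefectLabel("zero", sid, food_id, t.foodex2, tag))
                    continue
                if u < spec.zero_rate + spec.outlier_rate:
                    value *= spec.outlier_factor
                    labels.append(DefectLabel("outlier", sid, food_id, t.foodex2, tag))
                value = round(value, 6)
                if col_units[tag] != std:
                    value = convert_value(value, std, col_units[tag])
                row[f"{sid}_{tag.lower()}"] = value
            rows.append(row)

        tables[sid] = pd.DataFrame(
            rows, columns=["id", "name", "code", "group", "ep", "class",
                           *column_map])
        mappings[sid] = SourceMapping(
            source_id=sid,
            column_map=column_map,
            id_column="id",
            foodex2_column="code",
            name_column="name",
            english_name_column="name",
            group_column="group",
            edible_portion_column="ep",
            record_class_column="class",
            # one source codes its zeros as logical zeros so both
            # conventions are exercised; the rest emit plain zeros,
            # which the unifier must treat as missing
            zero_is_logical=(s_idx == 0),
        )
    return FixtureBundle(spec=spec, registry=registry, tables=tables,
                         mappings=mappings,
                         truth={t.foodex2: t for t in truths},
                         defect_labels=labels)


# ---------------------------------------------------------------------------
# QC defect planting
# ---------------------------------------------------------------------------

def _set_chosen(food: UnifiedFood, tag: str, value: float) -> None:
    uv = food.values[tag]
    uv.chosen = value
    uv.median = value
    uv.mean = value


def plant_qc_defects(
    foods: list[UnifiedFood],
    seed: int = 0,
    n_defects: Optional[int] = None,
) -> tuple[list[UnifiedFood], list[tuple[str, str]]]:
    """Corrupt deep copies of unified foods with labelled QC violations.

    Cycles through the four rule-based defect kinds (proximate-sum
    violation, fat = 0 with fatty-acid detail, fat without any
    fatty-acid/cholesterol detail, fibre in a fish-group food), each
    planted in a distinct food and adjusted so no *other* rule fires as
    a side effect.  Returns the corrupted list and labels
    ``(foodex2, check_id)`` — exhaustive and exclusive by construction.
    """
    rng = np.random.default_rng(seed)
    foods = copy.deepcopy(foods)
    if n_defects is None:
        n_defects = min(8, len(foods))
    if n_defects > len(foods):
        raise ValueError("cannot plant more defects than foods")
    order = rng.permutation(len(foods))
    kinds = ("proximate_sum", "fat_zero_with_components",
             "fat_without_components", "fiber_in_fish")
    labels: list[tuple[str, str]] = []
    for j in range(n_defects):
        food = foods[int(order[j])]
        kind = kinds[j % len(kinds)]
        code = str(food.foodex2)
        if kind == "proximate_sum":
            # push the sum to ~85 g, safely below the window
            current = sum(food.chosen_value(t) or 0.0 for t in
                          ("WATER", "PROT", "FAT", "CHOCDF", "ALC", "ASH"))
            water = food.chosen_value("WATER") or 0.0
            _set_chosen(food, "WATER", max(0.0, round(water - (current - 85.0), 1)))
        elif kind == "fat_zero_with_components":
            # keep the proximate sum in range by moving the fat into water
            fat = food.chosen_value("FAT") or 0.0
            _set_chosen(food, "WATER",
                        round((food.chosen_value("WATER") or 0.0) + fat, 1))
            _set_chosen(food, "FAT", 0.0)
        elif kind == "fat_without_components":
            fat = food.chosen_value("FAT") or 0.0
            new_fat = 5.0
            _set_chosen(food, "FAT", new_fat)
            _set_chosen(food, "WATER",
                        round(max(0.0, (food.chosen_value("WATER") or 0.0)
                                  - (new_fat - fat)), 1))
            for t in ("FASAT", "FAMS", "FAPU", "CHOLE"):
                food.values.pop(t, None)
        else:  # fiber_in_fish
            food.food_group = "Fish and seafood"
            if "FIBTG" in food.values:
                _set_chosen(food, "FIBTG", 1.2)
            else:
                from .unify import UnifiedValue
                food.values["FIBTG"] = UnifiedValue(
                    tagname="FIBTG", n_sources=1, mean=1.2, median=1.2,
                    sd=0.0, chosen=1.2)
        labels.append((code, kind))
    return foods, labels


def perturb_export(
    export: pd.DataFrame, seed: int = 0, delta: float = 0.001,
) -> tuple[pd.DataFrame, tuple[int, str]]:
    """Perturb one numeric cell of a flat export by ``delta``; returns
    the perturbed copy and the (row position, column) of the change."""
    rng = np.random.default_rng(seed)
    out = export.copy(deep=True)
    num_cols = [c for c in out.columns if out[c].dtype.kind == "f"]
    for _ in range(1000):
        r = int(rng.integers(len(out)))
        c = num_cols[int(rng.integers(len(num_cols)))]
        v = out.iloc[r][c]
        if pd.notna(v):
            out.iloc[r, out.columns.get_loc(c)] = v + delta
            return out, (r, c)
    raise RuntimeError("no numeric cell found to perturb")


# ---------------------------------------------------------------------------
# Recipe fixtures with closed-form expected results
# ---------------------------------------------------------------------------

@dataclass
class RecipeFixture:
    recipes: list[Recipe]
    expected: dict[str, RecipeResult]
    yf_table: YieldFactorTable
    rf_table: RetentionFactorTable


def _oracle_recipe(recipe: Recipe, db: dict[str, UnifiedFood],
                   yf_by_method: dict[str, float],
                   rf_rules: dict[tuple, float],
                   registry: ComponentRegistry) -> RecipeResult:
    # straight-line reference computation, independent of the engine:
    # explicit dict lookups in precedence order, plain accumulation
    yf = recipe.yf_override if recipe.yf_override is not None \
        else yf_by_method[recipe.cooking_method]
    totals: dict[str, float] = {}
    edible = 0.0
    for ing in recipe.ingredients:
        food = db[ing.food_ref]
        ep = ing.edible_portion_override if ing.edible_portion_override is not None \
            else food.edible_portion
        w = ing.raw_weight_g * ep
        edible += w
        for tag, uv in food.values.items():
            cls = registry.resolve(tag).component_class
            for key in (("tag", tag, food.food_group, recipe.cooking_method),
                        ("tag", tag, ANY, recipe.cooking_method),
                        ("cls", cls, food.food_group, recipe.cooking_method),
                        ("cls", cls, ANY, recipe.cooking_method)):
                if key in rf_rules:
                    rf = rf_rules[key]
                    break
            else:
                rf = 1.0
            totals[tag] = totals.get(tag, 0.0) + (w / 100.0) * uv.chosen * rf
    cooked = yf * edible
    return RecipeResult(
        recipe_id=recipe.recipe_id,
        total_cooked_weight=cooked,
        per_component_total=totals,
        per_100g={t: 100.0 * v / cooked for t, v in totals.items()},
        yf=yf,
    )


def generate_recipes(
    db: dict[str, UnifiedFood],
    n: int,
    seed: int,
    registry: ComponentRegistry,
) -> RecipeFixture:
    """Random recipes over ``db`` plus independently computed expected
    results (the closed-form oracle) and the YF/RF tables they used.

    Deterministic under ``seed``.
    """
    if not db:
        raise ValueError("unified database is empty")
    rng = np.random.default_rng(seed)
    codes = sorted(db)
    methods = [m for m in COOKING_METHODS if m != "raw"]

    yf_by_method = {m: round(float(rng.uniform(0.6, 1.25)), 3) for m in methods}
    yf_table = YieldFactorTable(
        [YieldFactorEntry(ANY, m, yf) for m, yf in sorted(yf_by_method.items())])

    groups = sorted({f.food_group for f in db.values()})
    tag_pool = sorted({t for f in db.values() for t in f.values})
    rf_rules: dict[tuple, float] = {}
    rf_entries: list[RetentionFactorEntry] = []
    for m in methods:
        for tag in rng.choice(tag_pool, size=min(8, len(tag_pool)), replace=False):
            g = str(rng.choice([ANY, *groups]))
            rf = round(float(rng.uniform(0.3, 1.3)), 3)
            key = ("tag", str(tag), g, m)
            if key not in rf_rules:
                rf_rules[key] = rf
                rf_entries.append(RetentionFactorEntry(
                    cooking_method=m, rf=rf, tagname=str(tag), food_group=g))
        for cls in ("vitamin", "mineral", "polyphenol"):
            g = str(rng.choice([ANY, *groups]))
            rf = round(float(rng.uniform(0.5, 1.1)), 3)
            key = ("cls", cls, g, m)
            rf_rules[key] = rf
            rf_entries.append(RetentionFactorEntry(
                cooking_method=m, rf=rf, component_class=cls, food_group=g))
    rf_table = RetentionFactorTable(rf_entries)

    recipes: list[Recipe] = []
    expected: dict[str, RecipeResult] = {}
    for i in range(n):
        k = int(rng.integers(1, min(6, len(codes)) + 1))
        chosen = rng.choice(codes, size=k, replace=False)
        ingredients = []
        for code in chosen:
            ep_override = (round(float(rng.uniform(0.5, 1.0)), 2)
                           if rng.uniform() < 0.3 else None)
            ingredients.append(RecipeIngredient(
                food_ref=str(code),
                raw_weight_g=round(float(rng.uniform(20.0, 300.0)), 1),
                edible_portion_override=ep_override))
        recipe = Recipe(
            recipe_id=f"R{i:04d}",
            name=f"fixture recipe {i:04d}",
            cooking_method=str(rng.choice(methods)),
            ingredients=ingredients,
            yf_override=(round(float(rng.uniform(0.7, 1.2)), 3)
                         if rng.uniform() < 0.25 else None),
        )
        recipes.append(recipe)
        expected[recipe.recipe_id] = _oracle_recipe(
            recipe, db, yf_by_method, rf_rules, registry)
    return RecipeFixture(recipes, expected, yf_table, rf_table)
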