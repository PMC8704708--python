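"""EuroFIR mixed-method recipe calculation.

The mixed method combines a recipe-level yield factor (YF, cooked
weight over raw edible weight, resolved per cooking method and food
group) with per-ingredient retention factors (RF, fraction of a
component retained — or gained — through cooking).  For a recipe with
ingredients i and component k:

    edible weight      w_i       = raw_i · EP_i
    raw amount         n_{i,k}   = (w_i / 100) · c_{i,k}
    retained amount    r_{i,k}   = n_{i,k} · RF(k, group_i, method)
    component total    T_k       = Σ_i r_{i,k}
    cooked weight      W         = YF · Σ_i w_i
    per 100 g          per100_k  = 100 · T_k / W

Results are expressed both per 100 g of cooked recipe and per total
recipe, with a full factor audit recording which EP, RF and YF entered
each amount.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from .core import ComponentRegistry
from .unify import UnifiedFood

__all__ = [
    "ANY",
    "YieldFactorEntry",
    "YieldFactorTable",
    "RetentionFactorEntry",
    "RetentionFactorTable",
    "RecipeIngredient",
    "Recipe",
    "RecipeResult",
    "FactorLookupError",
    "compute_recipe",
    "verify_recipe_model",
]

#: wildcard food group in factor tables
ANY = "ANY"


class FactorLookupError(LookupError):
    """No yield factor resolves for a recipe and none was overridden."""


@dataclass(frozen=True)
class YieldFactorEntry:
    food_group: str
    cooking_method: str
    yf: float

    def __post_init__(self) -> None:
        if not self.yf > 0:
            raise ValueError(f"yield factor must be > 0, got {self.yf}")


class YieldFactorTable:
    """YF lookup keyed by (food group, cooking method); a group-specific
    entry outranks the ``ANY`` wildcard."""

    def __init__(self, entries: Optional[list[YieldFactorEntry]] = None):
        self.entries = list(entries or [])

    def add(self, entry: YieldFactorEntry) -> None:
        self.entries.append(entry)

    def lookup(self, food_group: str, cooking_method: str) -> Optional[YieldFactorEntry]:
        specific = wildcard = None
        for e in self.entries:
            if e.cooking_method != cooking_method:
                continue
            if e.food_group == food_group and specific is None:
                specific = e
            elif e.food_group == ANY and wildcard is None:
                wildcard = e
        return specific or wildcard

    @classmethod
    def from_csv(cls, path: str | Path) -> "YieldFactorTable":
        with open(path, newline="", encoding="utf-8") as fh:
            return cls([YieldFactorEntry(r["food_group"], r["cooking_method"],
                                         float(r["yf"]))
                        for r in csv.DictReader(fh)])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=["food_group", "cooking_method", "yf"])
            w.writeheader()
            for e in self.entries:
                w.writerow(asdict(e))


@dataclass(frozen=True)
class RetentionFactorEntry:
    """RF rule; keyed by a tagname or a whole component class, a food
    group or ``ANY``, and a cooking method.  RF may exceed 1 (gains)."""

    cooking_method: str
    rf: float
    tagname: Optional[str] = None
    component_class: Optional[str] = None
    food_group: str = ANY

    def __post_init__(self) -> None:
        if self.rf < 0:
            raise ValueError(f"retention factor must be >= 0, got {self.rf}")
        if (self.tagname is None) == (self.component_class is None):
            raise ValueError("exactly one of tagname / component_class must be set")


@dataclass(frozen=True)
class RFMatch:
    rf: float
    rule: Optional[RetentionFactorEntry]   # None -> default 1.0


class RetentionFactorTable:
    """RF lookup with most-specific-wins precedence:

    (tagname, group, method) > (tagname, ANY, method)
    > (class, group, method) > (class, ANY, method) > default 1.0
    """

    def __init__(self, entries: Optional[list[RetentionFactorEntry]] = None):
        self.entries = list(entries or [])

    def add(self, entry: RetentionFactorEntry) -> None:
        self.entries.append(entry)

    def lookup(self, tagname: str, component_class: str,
               food_group: str, cooking_method: str) -> RFMatch:
        best: Optional[RetentionFactorEntry] = None
        best_rank = 5
        for e in self.entries:
            if e.cooking_method != cooking_method:
                continue
            if e.tagname is not None:
                if e.tagname != tagname:
                    continue
                rank = 1 if e.food_group == food_group else (2 if e.food_group == ANY else 5)
            else:
                if e.component_class != component_class:
                    continue
                rank = 3 if e.food_group == food_group else (4 if e.food_group == ANY else 5)
            if rank < best_rank:
                best, best_rank = e, rank
        if best is None:
            return RFMatch(1.0, None)
        return RFMatch(best.rf, best)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RetentionFactorTable":
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            for r in csv.DictReader(fh):
                entries.append(RetentionFactorEntry(
                    cooking_method=r["cooking_method"],
                    rf=float(r["rf"]),
                    tagname=r.get("tagname") or None,
                    component_class=r.get("component_class") or None,
                    food_group=r.get("food_group") or ANY,
                ))
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        cols = ["tagname", "component_class", "food_group", "cooking_method", "rf"]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            for e in self.entries:
                w.writerow({c: ("" if getattr(e, c) is None else getattr(e, c))
                            for c in cols})


# ---------------------------------------------------------------------------
# Recipes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecipeIngredient:
    food_ref: str                      # FoodEx2 code of a unified food
    raw_weight_g: float
    edible_portion_override: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.raw_weight_g > 0:
            raise ValueError(f"raw weight must be > 0, got {self.raw_weight_g}")
        ep = self.edible_portion_override
        if ep is not None and not 0.0 < ep <= 1.0:
            raise ValueError(f"edible portion override must be in (0, 1], got {ep}")


@dataclass
class Recipe:
    recipe_id: str
    name: str
    cooking_method: str
    ingredients: list[RecipeIngredient]
    yf_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.yf_override is not None and not self.yf_override > 0:
            raise ValueError("yf_override must be > 0")


@dataclass(frozen=True)
class FactorAuditEntry:
    ingredient: str
    tagname: str
    edible_portion: float
    rf: float
    rf_rule: Optional[str]
    yf: float


@dataclass
class RecipeResult:
    recipe_id: str
    total_cooked_weight: float
    per_component_total: dict[str, float]
    per_100g: dict[str, float]
    factor_audit: list[FactorAuditEntry] = field(default_factory=list)
    partial_components: set[str] = field(default_factory=set)
    yf: float = 1.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["partial_components"] = sorted(self.partial_components)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, ensure_ascii=False)


def _rule_label(rule: Optional[RetentionFactorEntry]) -> Optional[str]:
    if rule is None:
        return None
    key = rule.tagname if rule.tagname is not None else f"class:{rule.component_class}"
    return f"{key}/{rule.food_group}/{rule.cooking_method}"


def compute_recipe(
    recipe: Recipe,
    db: dict[str, UnifiedFood],
    yf_table: YieldFactorTable,
    rf_table: RetentionFactorTable,
    registry: ComponentRegistry,
    yf_food_group: str = ANY,
) -> RecipeResult:
    """Apply the mixed method to one recipe.

    ``db`` maps FoodEx2 codes to unified foods.  The yield factor is the
    recipe's override if given, else the table entry for
    ``(yf_food_group, cooking_method)`` (wildcard group by default).
    A component missing from some — but not all — ingredients
    contributes 0 for those ingredients and the component is marked
    partial; a component missing from every ingredient stays missing.

    Raises
    ------
    KeyError
        If an ingredient food reference does not resolve in ``db``.
    FactorLookupError
        If no yield factor resolves and none was overridden.
    """
    for ing in recipe.ingredients:
        if ing.food_ref not in db:
            raise KeyError(f"recipe {recipe.recipe_id}: unresolvable ingredient "
                           f"food reference {ing.food_ref!r}")
    if recipe.yf_override is not None:
        yf = recipe.yf_override
    else:
        entry = yf_table.lookup(yf_food_group, recipe.cooking_method)
        if entry is None:
            raise FactorLookupError(
                f"recipe {recipe.recipe_id}: no yield factor for "
                f"({yf_food_group!r}, {recipe.cooking_method!r}) and no override")
        yf = entry.yf

    audit: list[FactorAuditEntry] = []
    totals: dict[str, float] = {}
    present_count: dict[str, int] = {}
    edible_sum = 0.0

    for ing in recipe.ingredients:
        food = db[ing.food_ref]
        ep = (ing.edible_portion_override
              if ing.edible_portion_override is not None
              else food.edible_portion)
        w = ing.raw_weight_g * ep
        edible_sum += w
        for tag in sorted(food.values):
            c = food.chosen_value(tag)
            if c is None:
                continue
            cls = registry.resolve(tag).component_class
            match = rf_table.lookup(tag, cls, food.food_group, recipe.cooking_method)
            retained = (w / 100.0) * c * match.rf
            totals[tag] = totals.get(tag, 0.0) + retained
            present_count[tag] = present_count.get(tag, 0) + 1
            audit.append(FactorAuditEntry(
                ingredient=ing.food_ref, tagname=tag, edible_portion=ep,
                rf=match.rf, rf_rule=_rule_label(match.rule), yf=yf))

    cooked_weight = yf * edible_sum
    n_ing = len(recipe.ingredients)
    partial = {t for t, n in present_count.items() if n < n_ing}
    per_100g = {t: 100.0 * v / cooked_weight for t, v in totals.items()}
    return RecipeResult(
        recipe_id=recipe.recipe_id,
        total_cooked_weight=cooked_weight,
        per_component_total=totals,
        per_100g=per_100g,
        factor_audit=audit,
        partial_components=partial,
        yf=yf,
    )


def verify_recipe_model(
    recipes: list[Recipe],
    db: dict[str, UnifiedFood],
    yf_table: YieldFactorTable,
    rf_table: RetentionFactorTable,
    registry: ComponentRegistry,
    reference: dict[str, RecipeResult],
    yf_food_group: str = ANY,
) -> list[dict]:
    """Compare engine results against an independent reference result set.

    Returns one row per (recipe, component) with absolute and relative
    differences, plus a row for the cooked weight.  Identical factor
    selections imply zero difference.
    """
    rows: list[dict] = []
    for recipe in recipes:
        got = compute_recipe(recipe, db, yf_table, rf_table, registry, yf_food_group)
        ref = reference[recipe.recipe_id]

        def diff_row(component: str, a: float, b: float) -> dict:
            abs_diff = abs(a - b)
            rel = abs_diff / abs(b) if b != 0 else (0.0 if abs_diff == 0 else float("inf"))
            return {"recipe_id": recipe.recipe_id, "component": component,
                    "engine": a, "reference": b,
                    "abs_diff": abs_diff, "rel_diff": rel}

        rows.append(diff_row("__cooked_weight__", got.total_cooked_weight,
                             ref.total_cooked_weight))
        for tag in sorted(set(got.per_component_total) | set(ref.per_component_total)):
            rows.append(diff_row(tag,
                                 got.per_component_total.get(tag, 0.0),
                                 ref.per_component_total.get(tag, 0.0)))
    return rows
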