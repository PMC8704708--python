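"""Persist the unified database in an interrelated relational store.

A single-file SQLite database with eight tables (see ``schema.sql``):
sources, components, foods, component_values (carrying contributor
provenance), yield_factors, retention_factors, recipes and
recipe_ingredients.  Referential integrity is enforced by the engine;
values are stored as binary64 REALs so a flat export → store → flat
export round-trip is the identity, which the management-stage transfer
check verifies.  :func:`trace` walks a unified value back to the
original source records — source, original food id, original value and
original (pre-conversion) unit.
"""

from __future__ import annotations

import sqlite3
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .core import ComponentDefinition, ComponentRegistry, FoodEx2Code, SourceDatabase
from .recipes import (
    Recipe,
    RecipeIngredient,
    RetentionFactorEntry,
    RetentionFactorTable,
    YieldFactorEntry,
    YieldFactorTable,
)
from .unify import Contributor, UnifiedFood, UnifiedValue

__all__ = ["ddl", "write_store", "read_store", "trace", "export_flat", "StoreContents"]


def ddl() -> str:
    """The portable DDL of the eight-table schema."""
    return resources.files("fcdbkit").joinpath("schema.sql").read_text("utf-8")


def _connect(path: str | Path) -> sqlite3.Connection:
    conn = sqlite3.connect(path)
    conn.execute("PRAGMA foreign_keys = ON")
    return conn


def write_store(
    foods: list[UnifiedFood],
    path: str | Path,
    registry: Optional[ComponentRegistry] = None,
    sources: Optional[list[SourceDatabase]] = None,
    recipes: Optional[list[Recipe]] = None,
    yf_table: Optional[YieldFactorTable] = None,
    rf_table: Optional[RetentionFactorTable] = None,
) -> None:
    """Create (or overwrite) the relational store at ``path``.

    Components and sources referenced by the unified foods are
    auto-registered with minimal rows when not supplied explicitly, so
    the provenance foreign keys always resolve.
    """
    path = Path(path)
    if path.exists():
        path.unlink()
    conn = _connect(path)
    try:
        conn.executescript(ddl())
        source_rows = {s.source_id: s for s in sources or []}
        for food in foods:
            for uv in food.values.values():
                if not uv.contributors:
                    source_rows.setdefault("unknown", SourceDatabase("unknown"))
                for c in uv.contributors:
                    source_rows.setdefault(c.source_id, SourceDatabase(c.source_id))
        conn.executemany(
            "INSERT INTO sources VALUES (?,?,?,?,?)",
            [(s.source_id, s.name, s.country_or_org, s.version_date, s.notes)
             for s in sorted(source_rows.values(), key=lambda s: s.source_id)])

        comp_rows: dict[str, ComponentDefinition] = {}
        for d in registry or []:
            comp_rows[d.tagname] = d
        for food in foods:
            for tag in food.values:
                comp_rows.setdefault(
                    tag, ComponentDefinition(tag, "", "g", "other"))
        conn.executemany(
            "INSERT INTO components VALUES (?,?,?,?,?)",
            [(d.tagname, d.display_name, d.standard_unit, d.component_class,
              d.tagname_origin)
             for d in sorted(comp_rows.values(), key=lambda d: d.tagname)])

        for food in sorted(foods, key=lambda f: (f.foodex2.code, f.basis)):
            cur = conn.execute(
                "INSERT INTO foods (foodex2, basis, name, food_group, "
                "edible_portion, cooking_method, matched) VALUES (?,?,?,?,?,?,?)",
                (food.foodex2.code, food.basis, food.name, food.food_group,
                 food.edible_portion, food.cooking_method, int(food.matched)))
            food_key = cur.lastrowid
            for tag in sorted(food.values):
                uv = food.values[tag]
                flagged = {(c.source_id, c.original_food_id)
                           for c in uv.flagged_contributors}
                contributors = uv.contributors or [
                    # defensive: a value must trace to at least one record
                    Contributor("unknown", "unknown", uv.chosen)]
                for c in contributors:
                    conn.execute(
                        "INSERT INTO component_values (food_key, tagname, "
                        "n_sources, mean, median, sd, chosen, outlier_flag, "
                        "logical_zero, contributor_source, contributor_food_id, "
                        "contributor_value, contributor_flagged, original_value, "
                        "original_unit) VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
                        (food_key, tag, uv.n_sources, uv.mean, uv.median, uv.sd,
                         uv.chosen, int(uv.outlier_flag), int(uv.logical_zero),
                         c.source_id, c.original_food_id, c.value,
                         int((c.source_id, c.original_food_id) in flagged),
                         c.original_value, c.original_unit))

        if yf_table is not None:
            conn.executemany(
                "INSERT INTO yield_factors (food_group, cooking_method, yf) "
                "VALUES (?,?,?)",
                [(e.food_group, e.cooking_method, e.yf) for e in yf_table.entries])
        if rf_table is not None:
            conn.executemany(
                "INSERT INTO retention_factors (tagname, component_class, "
                "food_group, cooking_method, rf) VALUES (?,?,?,?,?)",
                [(e.tagname, e.component_class, e.food_group, e.cooking_method,
                  e.rf) for e in rf_table.entries])
        for r in recipes or []:
            conn.execute(
                "INSERT INTO recipes VALUES (?,?,?,?)",
                (r.recipe_id, r.name, r.cooking_method, r.yf_override))
            for ing in r.ingredients:
                conn.execute(
                    "INSERT INTO recipe_ingredients (recipe_id, foodex2, basis, "
                    "raw_weight_g, edible_portion_override) VALUES (?,?,?,?,?)",
                    (r.recipe_id, ing.food_ref, "per_100g",
                     ing.raw_weight_g, ing.edible_portion_override))
        conn.commit()
    finally:
        conn.close()


class StoreContents:
    """Materialized contents of a store, re-read from disk."""

    def __init__(self, foods, registry, sources, recipes, yf_table, rf_table):
        self.foods: list[UnifiedFood] = foods
        self.registry: ComponentRegistry = registry
        self.sources: list[SourceDatabase] = sources
        self.recipes: list[Recipe] = recipes
        self.yf_table: YieldFactorTable = yf_table
        self.rf_table: RetentionFactorTable = rf_table


def read_store(path: str | Path) -> StoreContents:
    """Re-read a store into domain objects, value-identically."""
    conn = _connect(path)
    try:
        sources = [SourceDatabase(*row) for row in conn.execute(
            "SELECT source_id, name, country_or_org, version_date, notes "
            "FROM sources ORDER BY source_id")]
        registry = ComponentRegistry([ComponentDefinition(*row) for row in conn.execute(
            "SELECT tagname, display_name, standard_unit, component_class, "
            "tagname_origin FROM components ORDER BY tagname")])

        foods: list[UnifiedFood] = []
        by_key: dict[int, UnifiedFood] = {}
        for (food_key, code, basis, name, group, ep, method, matched) in conn.execute(
                "SELECT food_key, foodex2, basis, name, food_group, "
                "edible_portion, cooking_method, matched FROM foods "
                "ORDER BY foodex2, basis"):
            food = UnifiedFood(foodex2=FoodEx2Code(code), name=name,
                               food_group=group, basis=basis,
                               matched=bool(matched), edible_portion=ep,
                               cooking_method=method)
            by_key[food_key] = food
            foods.append(food)
        for (food_key, tag, n, mean, median, sd, chosen, oflag, lzero,
             csrc, cfid, cval, cflag, oval, ounit) in conn.execute(
                "SELECT food_key, tagname, n_sources, mean, median, sd, chosen, "
                "outlier_flag, logical_zero, contributor_source, "
                "contributor_food_id, contributor_value, contributor_flagged, "
                "original_value, original_unit FROM component_values "
                "ORDER BY food_key, tagname, contributor_source, contributor_food_id"):
            food = by_key[food_key]
            uv = food.values.get(tag)
            if uv is None:
                uv = UnifiedValue(tagname=tag, n_sources=n, mean=mean,
                                  median=median, sd=sd, chosen=chosen,
                                  outlier_flag=bool(oflag),
                                  logical_zero=bool(lzero))
                food.values[tag] = uv
            c = Contributor(csrc, cfid, cval, oval, ounit)
            uv.contributors.append(c)
            if cflag:
                uv.flagged_contributors.append(c)

        yf_table = YieldFactorTable([YieldFactorEntry(*row) for row in conn.execute(
            "SELECT food_group, cooking_method, yf FROM yield_factors "
            "ORDER BY yf_key")])
        rf_table = RetentionFactorTable([
            RetentionFactorEntry(cooking_method=m, rf=rf, tagname=t,
                                 component_class=c, food_group=g)
            for (t, c, g, m, rf) in conn.execute(
                "SELECT tagname, component_class, food_group, cooking_method, rf "
                "FROM retention_factors ORDER BY rf_key")])
        recipes = []
        for (rid, name, method, yfo) in conn.execute(
                "SELECT recipe_id, name, cooking_method, yf_override "
                "FROM recipes ORDER BY recipe_id"):
            ingredients = [RecipeIngredient(fx, w, epo) for (fx, w, epo) in conn.execute(
                "SELECT foodex2, raw_weight_g, edible_portion_override "
                "FROM recipe_ingredients WHERE recipe_id = ? "
                "ORDER BY ingredient_key", (rid,))]
            recipes.append(Recipe(rid, name, method, ingredients, yfo))
        return StoreContents(foods, registry, sources, recipes, yf_table, rf_table)
    finally:
        conn.close()


def trace(path: str | Path, foodex2: str, tagname: str,
          basis: str = "per_100g") -> list[tuple[str, str, float, Optional[str]]]:
    """Provenance chain of one unified value.

    Returns ``(source name, original food id, original value, original
    unit)`` per contributor — the original value/unit as read from the
    source, falling back to the harmonized value when the source
    already used the standard unit.

    Raises
    ------
    KeyError
        If the (food, component) pair is not in the store.
    """
    conn = _connect(path)
    try:
        code = FoodEx2Code(foodex2).code
        rows = list(conn.execute(
            "SELECT s.name, s.source_id, cv.contributor_food_id, "
            "cv.original_value, cv.original_unit, cv.contributor_value, "
            "c.standard_unit "
            "FROM component_values cv "
            "JOIN foods f ON f.food_key = cv.food_key "
            "JOIN sources s ON s.source_id = cv.contributor_source "
            "JOIN components c ON c.tagname = cv.tagname "
            "WHERE f.foodex2 = ? AND f.basis = ? AND cv.tagname = ? "
            "ORDER BY cv.contributor_source, cv.contributor_food_id",
            (code, basis, tagname)))
        if not rows:
            raise KeyError(f"no stored value for food {code} component {tagname}")
        chain = []
        for (sname, sid, fid, oval, ounit, cval, std_unit) in rows:
            value = cval if oval is None else oval
            unit = ounit if ounit is not None else std_unit
            chain.append((sname or sid, fid, value, unit))
        return chain
    finally:
        conn.close()


def export_flat(foods: list[UnifiedFood]) -> pd.DataFrame:
    """Wide export: one row per (food, basis), one column per tagname's
    chosen value; missing components are NaN.  Deterministic ordering."""
    tagnames = sorted({t for f in foods for t in f.values})
    rows = []
    for f in sorted(foods, key=lambda f: (f.foodex2.code, f.basis)):
        row: dict[str, object] = {
            "foodex2": f.foodex2.code, "basis": f.basis, "name": f.name,
            "food_group": f.food_group, "edible_portion": f.edible_portion,
            "matched": int(f.matched),
        }
        for t in tagnames:
            row[t] = f.chosen_value(t)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["foodex2", "basis", "name", "food_group",
                                     "edible_portion", "matched", *tagnames])
    for t in tagnames:
        df[t] = df[t].astype(float)
    return df
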