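"""Read per-source food tables and emit harmonized records.

A :class:`SourceMapping` describes how one source table maps onto the
common scheme: which column holds the food identifier and FoodEx2 code,
which component columns exist and in what unit, and how zeros are to be
read.  :func:`ingest_source` applies the mapping, converts every value
to its tagname's standard unit on a per-100 g (or per-100 mL) basis and
returns :class:`~fcdbkit.core.SourceFoodRecord` objects plus an
ingestion log.  Rows are rejected to the log — never silently dropped.

:func:`apply_exclusion_filter` then partitions records into kept and
excluded: fortified foods, supplements, commercial brands and
recipes/prepared dishes are discarded from database construction, while
generic foods (including cooked and generic unbranded processed foods)
are kept.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .core import (
    ComponentRegistry,
    ComponentValue,
    FoodEx2Code,
    SourceFoodRecord,
    convert_value,
    canonical_unit,
)

__all__ = [
    "SourceMapping",
    "MappingError",
    "IngestLogEntry",
    "ingest_source",
    "apply_exclusion_filter",
    "EXCLUDED_CLASSES",
    "read_table",
]

#: record classes discarded from database construction
EXCLUDED_CLASSES = ("branded", "fortified", "supplement", "recipe_or_dish")
_KNOWN_CLASSES = set(EXCLUDED_CLASSES) | {"generic"}


class MappingError(ValueError):
    """Source mapping is inconsistent with the table or the registry."""


@dataclass
class SourceMapping:
    """Column mapping and conventions for one source table.

    ``column_map`` maps a source column name to ``(tagname,
    source_unit)``; every tagname must resolve in the component
    registry.  ``zero_is_logical`` controls how a literal 0 cell is
    coded (plain ``zero`` vs ``logical_zero``); ``decimal_comma``
    accepts ``3,5`` style numbers from sources that use the comma
    decimal separator.
    """

    source_id: str
    column_map: dict[str, tuple[str, str]]
    id_column: str
    foodex2_column: str
    name_column: Optional[str] = None
    english_name_column: Optional[str] = None
    group_column: Optional[str] = None
    cooking_method_column: Optional[str] = None
    edible_portion_column: Optional[str] = None
    record_class_column: Optional[str] = None
    basis: str = "per_100g"
    zero_is_logical: bool = False
    decimal_comma: bool = False

    def __post_init__(self) -> None:
        if self.basis not in ("per_100g", "per_100mL"):
            raise MappingError(f"unknown basis {self.basis!r}")
        self.column_map = {
            col: (tag, canonical_unit(unit))
            for col, (tag, unit) in (
                (c, tuple(tu)) for c, tu in self.column_map.items()
            )
        }

    def validate_against(self, registry: ComponentRegistry) -> None:
        unknown = [t for t, _ in self.column_map.values() if t not in registry]
        if unknown:
            raise MappingError(
                f"source {self.source_id}: tagnames not in registry: {sorted(set(unknown))}"
            )

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["column_map"] = {c: list(tu) for c, tu in self.column_map.items()}
        Path(path).write_text(yaml.safe_dump(d, allow_unicode=True, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SourceMapping":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**d)


@dataclass(frozen=True)
class IngestLogEntry:
    source_id: str
    original_food_id: str
    action: str          # "rejected" | "warning"
    reason: str
    detail: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), ensure_ascii=False)


def read_table(path: str | Path, decimal_comma: bool = False) -> pd.DataFrame:
    """Read a CSV/TSV source table with all cells as text."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                       decimal="," if decimal_comma else ".")


def _parse_number(text: str, decimal_comma: bool) -> float:
    if decimal_comma:
        text = text.replace(".", "").replace(",", ".") if "," in text else text
    return float(text)


def _cell(row, column: Optional[str]) -> str:
    if column is None:
        return ""
    v = row.get(column, "")
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return str(v).strip()


def ingest_source(
    table: pd.DataFrame,
    mapping: SourceMapping,
    registry: ComponentRegistry,
) -> tuple[list[SourceFoodRecord], list[IngestLogEntry]]:
    """Harmonize one source table into records in standard units.

    Every emitted record keeps the source's food identifier verbatim.
    Blank component cells become status ``missing``; literal zeros
    become ``zero`` (or ``logical_zero`` under the mapping's
    ``zero_is_logical`` convention); ``tr``/``trace`` cells become
    ``trace``.  Values are converted from the mapping's declared source
    unit to the tagname's standard unit.

    Rows with an unparseable FoodEx2 code, a negative value, an
    unparseable number or an out-of-range edible portion are rejected
    with a reason in the log.

    Raises
    ------
    MappingError
        If a mandatory mapped column is missing from the table or a
        mapped tagname does not resolve in the registry.
    """
    mapping.validate_against(registry)
    mandatory = [mapping.id_column, mapping.foodex2_column, *mapping.column_map]
    missing_cols = [c for c in mandatory if c not in table.columns]
    if missing_cols:
        raise MappingError(
            f"source {mapping.source_id}: table lacks mapped columns {missing_cols}"
        )

    records: list[SourceFoodRecord] = []
    log: list[IngestLogEntry] = []

    for _, row in table.iterrows():
        food_id = _cell(row, mapping.id_column)
        code_text = _cell(row, mapping.foodex2_column)
        try:
            code = FoodEx2Code(code_text)
        except ValueError:
            log.append(IngestLogEntry(mapping.source_id, food_id, "rejected",
                                      "invalid_code", code_text))
            continue

        ep_text = _cell(row, mapping.edible_portion_column)
        edible_portion = 1.0
        if ep_text:
            try:
                edible_portion = _parse_number(ep_text, mapping.decimal_comma)
            except ValueError:
                log.append(IngestLogEntry(mapping.source_id, food_id, "rejected",
                                          "invalid_edible_portion", ep_text))
                continue
            if not 0.0 < edible_portion <= 1.0:
                log.append(IngestLogEntry(mapping.source_id, food_id, "rejected",
                                          "invalid_edible_portion", ep_text))
                continue

        record_class = _cell(row, mapping.record_class_column).lower() or "generic"

        values: dict[str, ComponentValue] = {}
        row_error: Optional[IngestLogEntry] = None
        for col, (tag, src_unit) in mapping.column_map.items():
            text = _cell(row, col)
            std_unit = registry.resolve(tag).standard_unit
            if not text:
                values[tag] = ComponentValue(tag, None, None, "missing")
                continue
            if text.lower() in ("tr", "trace"):
                values[tag] = ComponentValue(tag, 0.0, std_unit, "trace",
                                             original_value=0.0, original_unit=src_unit)
                continue
            try:
                num = _parse_number(text, mapping.decimal_comma)
            except ValueError:
                row_error = IngestLogEntry(mapping.source_id, food_id, "rejected",
                                           "unparseable_value", f"{col}={text!r}")
                break
            if num < 0:
                row_error = IngestLogEntry(mapping.source_id, food_id, "rejected",
                                           "negative_value", f"{col}={text!r}")
                break
            if num == 0:
                status = "logical_zero" if mapping.zero_is_logical else "zero"
                values[tag] = ComponentValue(tag, 0.0, std_unit, status,
                                             original_value=0.0, original_unit=src_unit)
            else:
                values[tag] = ComponentValue(
                    tag, convert_value(num, src_unit, std_unit), std_unit, "measured",
                    original_value=num, original_unit=src_unit,
                )
        if row_error is not None:
            log.append(row_error)
            continue

        records.append(SourceFoodRecord(
            source_id=mapping.source_id,
            original_food_id=food_id,
            original_name=_cell(row, mapping.name_column),
            english_name=_cell(row, mapping.english_name_column),
            foodex2=code,
            food_group=_cell(row, mapping.group_column),
            cooking_method=_cell(row, mapping.cooking_method_column) or None,
            basis=mapping.basis,
            edible_portion=edible_portion,
            record_class=record_class,
            values=values,
        ))
    return records, log


def apply_exclusion_filter(
    records: list[SourceFoodRecord],
) -> tuple[list[SourceFoodRecord], list[tuple[SourceFoodRecord, str]], list[IngestLogEntry]]:
    """Partition records into (kept, excluded-with-reason, log).

    Branded, fortified, supplement and recipe/prepared-dish records are
    excluded with their class as the reason; generic records — cooked
    foods and generic unbranded processed foods included — are kept.
    An unknown record class defaults to kept and is logged.
    """
    kept: list[SourceFoodRecord] = []
    excluded: list[tuple[SourceFoodRecord, str]] = []
    log: list[IngestLogEntry] = []
    for rec in records:
        if rec.record_class in EXCLUDED_CLASSES:
            excluded.append((rec, rec.record_class))
        else:
            if rec.record_class not in _KNOWN_CLASSES:
                log.append(IngestLogEntry(rec.source_id, rec.original_food_id,
                                          "warning", "unknown_record_class",
                                          rec.record_class))
            kept.append(rec)
    return kept, excluded, log


def write_log(log: list[IngestLogEntry], path: str | Path) -> None:
    """Write an ingestion log as JSON lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for entry in log:
            fh.write(entry.to_json() + "\n")
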