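"""Domain types, controlled vocabularies and the unit registry.

Everything downstream of ingestion speaks the vocabulary defined here:
food components are identified by INFOODS-style *tagnames* (``PROT``,
``VITC``, ...), each tied to a standard unit and a component class;
foods are identified by FoodEx2 codes (a letter followed by four
alphanumerics, e.g. ``A00MH``); and every value is expressed per 100 g
(or 100 mL) of edible portion in the tagname's standard unit.

The unit set is deliberately closed: ``g``, ``mg``, ``µg`` for masses
and ``kcal``, ``kJ`` for energy.  IU and percentages are out of scope.
Mass conversion is a decimal-exponent shift performed on the value's
shortest decimal representation, so converting a value that was parsed
from text (up to 15 significant digits) and converting it back is
bit-exact — IEEE multiplication by 1000 is not, which matters when a
round-trip through the store must be the identity.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, asdict
from decimal import Decimal
from pathlib import Path
from typing import Iterator, Literal, Mapping, Optional

__all__ = [
    "MASS_UNITS",
    "ENERGY_UNITS",
    "KJ_PER_KCAL",
    "UnitError",
    "RegistrationConflictError",
    "canonical_unit",
    "convert_value",
    "ComponentDefinition",
    "ComponentRegistry",
    "FoodEx2Code",
    "SourceDatabase",
    "ComponentValue",
    "SourceFoodRecord",
    "PROXIMATE_TAGS",
    "FATTY_ACID_SUMMARY_TAGS",
]

# ---------------------------------------------------------------------------
# Units
# ---------------------------------------------------------------------------

#: decimal exponent of each mass unit relative to grams
MASS_UNITS: dict[str, int] = {"g": 0, "mg": -3, "µg": -6}
ENERGY_UNITS: frozenset[str] = frozenset({"kcal", "kJ"})
#: thermochemical calorie, fixed here so the choice is auditable
KJ_PER_KCAL: float = 4.184

_UNIT_ALIASES = {
    "g": "g",
    "mg": "mg",
    "µg": "µg",      # U+00B5 micro sign
    "μg": "µg",  # U+03BC greek mu
    "ug": "µg",
    "mcg": "µg",
    "kcal": "kcal",
    "kj": "kJ",
    "kJ": "kJ",
}


class UnitError(ValueError):
    """Unknown unit token or dimensionally incompatible conversion."""


class RegistrationConflictError(ValueError):
    """Tagname re-registered with a conflicting definition."""


def canonical_unit(unit: str) -> str:
    """Normalize a unit token to its canonical spelling.

    Raises
    ------
    UnitError
        If the token is not in the closed unit set.
    """
    token = unit.strip()
    canon = _UNIT_ALIASES.get(token) or _UNIT_ALIASES.get(token.lower())
    if canon is None:
        raise UnitError(f"unknown unit token {unit!r}; supported: g, mg, µg, kcal, kJ")
    return canon


def convert_value(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between units of the closed set.

    Mass-to-mass conversion shifts the decimal exponent of the value's
    shortest decimal representation, which is exact: ``0.12`` g becomes
    ``120.0`` mg, not ``120.00000000000001``.  Energy conversion uses
    1 kcal = 4.184 kJ.

    Raises
    ------
    UnitError
        For mass↔energy (or any dimensionally incompatible) pairs.
    """
    fu, tu = canonical_unit(from_unit), canonical_unit(to_unit)
    if fu in MASS_UNITS and tu in MASS_UNITS:
        shift = MASS_UNITS[fu] - MASS_UNITS[tu]
        if shift == 0:
            return float(value)
        return float(Decimal(str(float(value))).scaleb(shift))
    if fu in ENERGY_UNITS and tu in ENERGY_UNITS:
        if fu == tu:
            return float(value)
        return value * KJ_PER_KCAL if fu == "kcal" else value / KJ_PER_KCAL
    raise UnitError(f"cannot convert between {fu!r} and {tu!r}: incompatible dimensions")


# ---------------------------------------------------------------------------
# Component vocabulary
# ---------------------------------------------------------------------------

ComponentClass = Literal[
    "proximate", "energy", "mineral", "vitamin",
    "fatty_acid", "sterol", "polyphenol", "other",
]
_COMPONENT_CLASSES = {
    "proximate", "energy", "mineral", "vitamin",
    "fatty_acid", "sterol", "polyphenol", "other",
}
_TAGNAME_RE = re.compile(r"^[A-Z0-9_]+$")

#: proximates entering the 95–105 g completeness check, in summation order
PROXIMATE_TAGS = ("WATER", "PROT", "FAT", "CHOCDF", "ALC", "ASH")
#: fatty-acid summary tags used by the implausible-value screen
FATTY_ACID_SUMMARY_TAGS = ("FASAT", "FAMS", "FAPU")


@dataclass(frozen=True)
class ComponentDefinition:
    """One entry of the component vocabulary.

    Parameters
    ----------
    tagname
        Uppercase token (letters/digits/underscore), unique per registry.
    display_name
        Human-readable component name.
    standard_unit
        Unit every harmonized value of this component is expressed in,
        per 100 g (or 100 mL) of food.
    component_class
        Drives rounding rules and QC semantics.
    tagname_origin
        ``infoods_standard`` for FAO/INFOODS tagnames, or
        ``compiler_assigned`` for tags created by compilers (typical for
        individual polyphenols that have no standard tagname).
    """

    tagname: str
    display_name: str
    standard_unit: str
    component_class: str
    tagname_origin: str = "infoods_standard"

    def __post_init__(self) -> None:
        if not _TAGNAME_RE.match(self.tagname):
            raise ValueError(f"invalid tagname {self.tagname!r}")
        object.__setattr__(self, "standard_unit", canonical_unit(self.standard_unit))
        if self.component_class not in _COMPONENT_CLASSES:
            raise ValueError(f"unknown component class {self.component_class!r}")
        if self.component_class == "energy":
            if self.standard_unit not in ENERGY_UNITS:
                raise ValueError(
                    f"energy component {self.tagname} must use kcal or kJ, "
                    f"got {self.standard_unit}"
                )
        elif self.standard_unit in ENERGY_UNITS:
            raise ValueError(
                f"non-energy component {self.tagname} cannot use unit {self.standard_unit}"
            )
        if self.tagname_origin not in ("infoods_standard", "compiler_assigned"):
            raise ValueError(f"unknown tagname origin {self.tagname_origin!r}")


class ComponentRegistry:
    """Tagname → :class:`ComponentDefinition` lookup.

    Registration is idempotent for identical definitions and refuses
    conflicting redefinitions, so a registry assembled from several
    source-mapping files stays consistent.
    """

    def __init__(self, definitions: Optional[list[ComponentDefinition]] = None):
        self._defs: dict[str, ComponentDefinition] = {}
        for d in definitions or []:
            self.register(d)

    def register(self, defn: ComponentDefinition) -> "ComponentRegistry":
        existing = self._defs.get(defn.tagname)
        if existing is not None and existing != defn:
            raise RegistrationConflictError(
                f"tagname {defn.tagname} already registered with unit "
                f"{existing.standard_unit!r}, conflicting unit {defn.standard_unit!r}"
            )
        self._defs[defn.tagname] = defn
        return self

    def resolve(self, tagname: str) -> ComponentDefinition:
        try:
            return self._defs[tagname]
        except KeyError:
            raise KeyError(f"tagname {tagname!r} not registered") from None

    def __contains__(self, tagname: str) -> bool:
        return tagname in self._defs

    def __iter__(self) -> Iterator[ComponentDefinition]:
        return iter(self._defs.values())

    def __len__(self) -> int:
        return len(self._defs)

    # -- serialization ------------------------------------------------------

    _FIELDS = ("tagname", "display_name", "standard_unit", "component_class", "tagname_origin")

    def to_file(self, path: str | Path) -> None:
        """Write the registry as JSON or delimited text (by extension)."""
        path = Path(path)
        rows = [asdict(d) for d in sorted(self, key=lambda d: d.tagname)]
        if path.suffix == ".json":
            path.write_text(json.dumps(rows, indent=2, ensure_ascii=False) + "\n",
                            encoding="utf-8")
        else:
            delim = "\t" if path.suffix == ".tsv" else ","
            with open(path, "w", newline="", encoding="utf-8") as fh:
                w = csv.DictWriter(fh, fieldnames=self._FIELDS, delimiter=delim)
                w.writeheader()
                w.writerows(rows)

    @classmethod
    def from_file(cls, path: str | Path) -> "ComponentRegistry":
        path = Path(path)
        if path.suffix == ".json":
            rows = json.loads(path.read_text(encoding="utf-8"))
        else:
            delim = "\t" if path.suffix == ".tsv" else ","
            with open(path, newline="", encoding="utf-8") as fh:
                rows = list(csv.DictReader(fh, delimiter=delim))
        return cls([ComponentDefinition(**{k: r[k] for k in cls._FIELDS}) for r in rows])


# ---------------------------------------------------------------------------
# Food identity
# ---------------------------------------------------------------------------

_FOODEX2_RE = re.compile(r"^[A-Z][A-Z0-9]{4}$")


@dataclass(frozen=True)
class FoodEx2Code:
    """A FoodEx2 classification code, treated as an opaque validated token.

    Codes are a letter followed by four alphanumerics (``A00MH``);
    comparison is case-insensitive, implemented by storing the
    uppercased form.  The optional ``level`` records hierarchy depth
    (1–4) and ``group_path`` the ancestor group labels; neither takes
    part in equality.
    """

    code: str
    level: Optional[int] = field(default=None, compare=False)
    group_path: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "code", str(self.code).strip().upper())
        if not _FOODEX2_RE.match(self.code):
            raise ValueError(f"invalid FoodEx2 code {self.code!r}")
        if self.level is not None and not 1 <= self.level <= 4:
            raise ValueError(f"FoodEx2 level must be in 1..4, got {self.level}")
        object.__setattr__(self, "group_path", tuple(self.group_path))

    def __str__(self) -> str:
        return self.code


@dataclass(frozen=True)
class SourceDatabase:
    """Metadata of one source food composition table/database."""

    source_id: str
    name: str = ""
    country_or_org: str = ""
    version_date: str = ""
    notes: str = ""


# ---------------------------------------------------------------------------
# Values and records
# ---------------------------------------------------------------------------

ValueStatus = Literal["measured", "zero", "logical_zero", "trace", "missing"]
_STATUSES = {"measured", "zero", "logical_zero", "trace", "missing"}


@dataclass(frozen=True)
class ComponentValue:
    """One component value of one source food.

    ``status`` distinguishes a measured number from the three flavours
    of nothing an FCDB can contain: a bare ``zero`` (untrustworthy — may
    encode a missing value), a ``logical_zero`` (genuinely absent, e.g.
    fibre in oil), a ``trace``, and ``missing``.  The original value and
    unit as read from the source are kept alongside the harmonized ones
    for traceability.
    """

    tagname: str
    raw_value: Optional[float]
    raw_unit: Optional[str]
    status: str = "measured"
    original_value: Optional[float] = None
    original_unit: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"unknown value status {self.status!r}")
        if self.status == "missing":
            if self.raw_value is not None:
                raise ValueError("missing value must have no raw_value")
        elif self.status in ("zero", "logical_zero"):
            if self.raw_value not in (0, 0.0):
                raise ValueError(f"{self.status} value must carry raw_value 0")
        if self.raw_value is not None and self.raw_value < 0:
            raise ValueError(f"negative component value {self.raw_value} for {self.tagname}")

    @property
    def numeric(self) -> Optional[float]:
        """Value entering computations: 0 for zero/logical-zero/trace, None if missing."""
        if self.status == "missing":
            return None
        if self.status == "measured":
            return self.raw_value
        return 0.0


@dataclass
class SourceFoodRecord:
    """One harmonized food row from one source database.

    Original identifiers are kept verbatim — they are the traceability
    anchor back to the source FCDB and are never rewritten.
    """

    source_id: str
    original_food_id: str
    original_name: str
    foodex2: FoodEx2Code
    english_name: str = ""
    food_group: str = ""
    cooking_method: Optional[str] = None
    basis: str = "per_100g"
    edible_portion: float = 1.0
    record_class: str = "generic"
    values: dict[str, ComponentValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.basis not in ("per_100g", "per_100mL"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if not 0.0 < self.edible_portion <= 1.0:
            raise ValueError(
                f"edible portion must be in (0, 1], got {self.edible_portion}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.source_id, self.original_food_id)

    def component_value(self, tagname: str) -> Optional[float]:
        cv = self.values.get(tagname)
        return None if cv is None else cv.numeric


def record_to_dict(record: SourceFoodRecord) -> dict:
    d = asdict(record)
    d["foodex2"] = record.foodex2.code
    return d


def record_from_dict(d: Mapping) -> SourceFoodRecord:
    d = dict(d)
    d["foodex2"] = FoodEx2Code(d["foodex2"])
    d["values"] = {
        tag: ComponentValue(**cv) for tag, cv in d.get("values", {}).items()
    }
    return SourceFoodRecord(**d)
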