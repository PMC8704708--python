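"""Cross-source unification: match by FoodEx2 code, pool, take the median.

Harmonized records that share a FoodEx2 code (within the same basis)
describe the same food as seen by different source databases.  For each
component the non-zero values are pooled, summary statistics (mean,
median, sample SD) are computed, and the **median** is selected as the
consensus value — the median is robust to the occasional wild value a
single source contributes, where the mean is not.  Plain zeros are
treated as missing before pooling (a 0 in a source table too often
encodes an absent measurement); logical zeros are likewise removed from
the pool but reinstated as a consensus 0 when every contributing source
coded the component as a logical zero.

An outlier screen (robust z-score against 1.4826·MAD, plus an extreme
coefficient-of-variation flag) marks values for human review; flags
never alter chosen values.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

from .core import ComponentRegistry, ComponentValue, FoodEx2Code, SourceFoodRecord

__all__ = [
    "foods_to_json",
    "foods_from_json",
    "Contributor",
    "UnifiedValue",
    "UnifiedFood",
    "MatchReport",
    "OutlierConfig",
    "clean_zeros",
    "round_standard",
    "unify_component",
    "unify_database",
    "flag_outliers",
]

# component classes rounded to one decimal; everything else gets 3 sig figs
_ONE_DECIMAL_CLASSES = {"proximate", "energy"}


def round_standard(value: float, component_class: str) -> float:
    """Apply the compilation rounding convention (half-up, deterministic).

    Proximates and energy are rounded to one decimal place; minerals,
    vitamins, fatty acids, sterols, polyphenols and other components to
    three significant figures.
    """
    if value < 0:
        raise ValueError(f"round_standard expects non-negative values, got {value}")
    if value == 0:
        return 0.0
    d = Decimal(str(float(value)))
    if component_class in _ONE_DECIMAL_CLASSES:
        q = d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    else:
        q = d.quantize(Decimal(1).scaleb(d.adjusted() - 2), rounding=ROUND_HALF_UP)
    return float(q)


def clean_zeros(values: list[ComponentValue]) -> list[ComponentValue]:
    """Recode plain zeros as missing prior to pooling.

    ``zero`` → ``missing`` (a bare 0 is untrustworthy and would drag the
    pool down); ``logical_zero`` and ``trace`` values pass through
    unchanged — they are excluded from the pool by :func:`unify_database`
    but retained so a genuine zero can be reinstated afterwards.
    """
    out = []
    for cv in values:
        if cv.status == "zero":
            out.append(ComponentValue(cv.tagname, None, None, "missing",
                                      original_value=cv.original_value,
                                      original_unit=cv.original_unit))
        else:
            out.append(cv)
    return out


@dataclass(frozen=True)
class Contributor:
    """Provenance of one pooled value: who said it, and what they said
    originally (pre-conversion value and unit, for traceability)."""

    source_id: str
    original_food_id: str
    value: float
    original_value: Optional[float] = None
    original_unit: Optional[str] = None


@dataclass
class UnifiedValue:
    """Consensus value of one component of one unified food."""

    tagname: str
    n_sources: int
    mean: float
    median: float
    sd: float
    chosen: float
    contributors: list[Contributor] = field(default_factory=list)
    outlier_flag: bool = False
    flagged_contributors: list[Contributor] = field(default_factory=list)
    logical_zero: bool = False


@dataclass
class UnifiedFood:
    """Cross-source consensus food, keyed by (FoodEx2 code, basis)."""

    foodex2: FoodEx2Code
    name: str
    food_group: str
    basis: str = "per_100g"
    values: dict[str, UnifiedValue] = field(default_factory=dict)
    matched: bool = False
    edible_portion: float = 1.0
    cooking_method: Optional[str] = None

    def chosen_value(self, tagname: str) -> Optional[float]:
        uv = self.values.get(tagname)
        return None if uv is None else uv.chosen


@dataclass
class MatchReport:
    n_input_records: int = 0
    n_unified_foods: int = 0
    n_matched: int = 0
    n_singleton: int = 0
    n_values: int = 0
    n_outlier_values: int = 0
    n_logical_zero_values: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class OutlierConfig:
    """Screen thresholds; both are review triggers, not edit rules."""

    z_threshold: float = 3.5
    cv_threshold: float = 2.0


def _median(sorted_vals: list[float]) -> float:
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return sorted_vals[mid]
    return (sorted_vals[mid - 1] + sorted_vals[mid]) / 2.0


def unify_component(
    pool: list[tuple[str, str, float]] | list[Contributor],
    component_class: str = "other",
    originals: Optional[dict[tuple[str, str], tuple[float, str]]] = None,
) -> UnifiedValue:
    """Summarize one component's pooled values into a :class:`UnifiedValue`.

    The median is the standard sample median (midpoint of the two
    central order statistics for even n); mean and sample SD (n−1
    denominator, 0 when n = 1) are kept as diagnostics.  The chosen
    value is the median after standard rounding for the component class.

    Raises
    ------
    ValueError
        On an empty pool — no unified value exists for a component
        nobody measured.
    """
    if not pool:
        raise ValueError("cannot unify an empty pool")
    contributors = []
    for entry in pool:
        if isinstance(entry, Contributor):
            contributors.append(entry)
        else:
            sid, fid, val = entry
            ov, ou = (originals or {}).get((sid, fid), (None, None))
            contributors.append(Contributor(sid, fid, float(val), ov, ou))
    contributors.sort(key=lambda c: (c.source_id, c.original_food_id))
    vals = sorted(c.value for c in contributors)
    n = len(vals)
    mean = math.fsum(vals) / n
    median = _median(vals)
    if n > 1:
        sd = math.sqrt(math.fsum((v - mean) ** 2 for v in vals) / (n - 1))
    else:
        sd = 0.0
    return UnifiedValue(
        tagname="", n_sources=n, mean=mean, median=median, sd=sd,
        chosen=round_standard(median, component_class),
        contributors=contributors,
    )


def flag_outliers(food: UnifiedFood, config: OutlierConfig = OutlierConfig()) -> UnifiedFood:
    """Mark suspicious contributor values and over-dispersed components.

    A contributor is flagged when its robust z-score
    ``|v − median| / (1.4826 · MAD)`` exceeds the threshold (flags are
    assignable only when at least three sources contributed); when the
    coefficient of variation ``sd/mean`` exceeds the extreme-CV
    threshold the whole component is flagged for review.  Mutates and
    returns ``food``; chosen values are never altered.
    """
    for uv in food.values.values():
        uv.outlier_flag = False
        uv.flagged_contributors = []
        if uv.n_sources < 3:
            continue
        vals = [c.value for c in uv.contributors]
        med = _median(sorted(vals))
        abs_dev = sorted(abs(v - med) for v in vals)
        mad = _median(abs_dev)
        scale = 1.4826 * mad
        for c in uv.contributors:
            dev = abs(c.value - med)
            if dev == 0:
                continue
            z = dev / scale if scale > 0 else math.inf
            if z > config.z_threshold:
                uv.flagged_contributors.append(c)
        if uv.flagged_contributors:
            uv.outlier_flag = True
        if uv.mean > 0 and uv.sd / uv.mean > config.cv_threshold:
            uv.outlier_flag = True
    return food


def unify_database(
    records: list[SourceFoodRecord],
    registry: ComponentRegistry,
    outlier_config: Optional[OutlierConfig] = OutlierConfig(),
) -> tuple[list[UnifiedFood], MatchReport]:
    """Group harmonized records by (FoodEx2 code, basis) and unify.

    One :class:`UnifiedFood` is emitted per (code, basis), sorted by
    code for determinism.  Foods with at least two contributing sources
    are ``matched``; singletons pass through with their single source's
    values as chosen values (still rounded by the standard convention).
    The unified food's name and group come from the contributing record
    with the most non-missing components (ties broken by lexicographic
    source_id); its edible portion is the median of the contributing
    records' edible portions.
    """
    groups: dict[tuple[str, str], list[SourceFoodRecord]] = defaultdict(list)
    for rec in records:
        groups[(rec.foodex2.code, rec.basis)].append(rec)

    report = MatchReport(n_input_records=len(records))
    foods: list[UnifiedFood] = []

    for (code, basis) in sorted(groups):
        group = sorted(groups[(code, basis)],
                       key=lambda r: (r.source_id, r.original_food_id))
        n_distinct_sources = len({r.source_id for r in group})

        def richness(r: SourceFoodRecord) -> tuple[int, str]:
            n_present = sum(1 for cv in r.values.values() if cv.status != "missing")
            return (-n_present, r.source_id)

        best = min(group, key=richness)
        eps = sorted(r.edible_portion for r in group)

        food = UnifiedFood(
            foodex2=FoodEx2Code(code),
            name=best.english_name or best.original_name,
            food_group=best.food_group,
            basis=basis,
            matched=n_distinct_sources >= 2,
            edible_portion=_median(eps),
            cooking_method=best.cooking_method,
        )

        tagnames = sorted({t for r in group for t in r.values})
        for tag in tagnames:
            cls = registry.resolve(tag).component_class
            cvs = clean_zeros([r.values[tag] for r in group if tag in r.values])
            recs = [r for r in group if tag in r.values]
            pool: list[Contributor] = []
            soft_zero: list[Contributor] = []   # logical zeros / traces
            for r, cv in zip(recs, cvs):
                if cv.status == "measured":
                    pool.append(Contributor(r.source_id, r.original_food_id,
                                            cv.raw_value, cv.original_value,
                                            cv.original_unit))
                elif cv.status in ("logical_zero", "trace"):
                    soft_zero.append(Contributor(r.source_id, r.original_food_id,
                                                 0.0, cv.original_value,
                                                 cv.original_unit))
            if pool:
                uv = unify_component(pool, cls)
                uv.tagname = tag
                food.values[tag] = uv
                report.n_values += 1
            elif soft_zero:
                # every contributing source coded a genuine zero: reinstate it
                soft_zero.sort(key=lambda c: (c.source_id, c.original_food_id))
                food.values[tag] = UnifiedValue(
                    tagname=tag, n_sources=len(soft_zero), mean=0.0, median=0.0,
                    sd=0.0, chosen=0.0, contributors=soft_zero, logical_zero=True,
                )
                report.n_values += 1
                report.n_logical_zero_values += 1
            # all zero/missing -> component stays missing

        if outlier_config is not None:
            flag_outliers(food, outlier_config)
            report.n_outlier_values += sum(
                1 for uv in food.values.values() if uv.outlier_flag
            )
        foods.append(food)
        if food.matched:
            report.n_matched += 1
        else:
            report.n_singleton += 1

    report.n_unified_foods = len(foods)
    return foods, report


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def foods_to_json(foods: list[UnifiedFood]) -> str:
    """Serialize unified foods (with full provenance) as deterministic JSON."""
    out = []
    for f in sorted(foods, key=lambda f: (f.foodex2.code, f.basis)):
        d = {
            "foodex2": f.foodex2.code,
            "name": f.name,
            "food_group": f.food_group,
            "basis": f.basis,
            "matched": f.matched,
            "edible_portion": f.edible_portion,
            "cooking_method": f.cooking_method,
            "values": {},
        }
        for tag in sorted(f.values):
            uv = f.values[tag]
            d["values"][tag] = {
                "n_sources": uv.n_sources, "mean": uv.mean, "median": uv.median,
                "sd": uv.sd, "chosen": uv.chosen,
                "outlier_flag": uv.outlier_flag,
                "logical_zero": uv.logical_zero,
                "contributors": [asdict(c) for c in uv.contributors],
                "flagged_contributors": [asdict(c) for c in uv.flagged_contributors],
            }
        out.append(d)
    return json.dumps(out, indent=2, ensure_ascii=False, sort_keys=True)


def foods_from_json(text: str) -> list[UnifiedFood]:
    foods = []
    for d in json.loads(text):
        food = UnifiedFood(
            foodex2=FoodEx2Code(d["foodex2"]), name=d["name"],
            food_group=d["food_group"], basis=d["basis"], matched=d["matched"],
            edible_portion=d["edible_portion"],
            cooking_method=d.get("cooking_method"),
        )
        for tag, v in d["values"].items():
            food.values[tag] = UnifiedValue(
                tagname=tag, n_sources=v["n_sources"], mean=v["mean"],
                median=v["median"], sd=v["sd"], chosen=v["chosen"],
                outlier_flag=v["outlier_flag"], logical_zero=v["logical_zero"],
                contributors=[Contributor(**c) for c in v["contributors"]],
                flagged_contributors=[Contributor(**c)
                                      for c in v["flagged_contributors"]],
            )
        foods.append(food)
    return foods
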