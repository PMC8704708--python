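"""HACCP-style validation suite.

Data quality is controlled at staged checkpoints: harmonization (names,
grouping, FoodEx2 coding, tagname resolution), unification (proximate
completeness, implausible values, outliers), management (flat-file ↔
relational-store transfer) and recipes (model-recipe verification,
implemented in :mod:`fcdbkit.recipes`).  Checks are pure: they produce
findings for human review and never mutate the data — corrections are a
separate, traceability-driven step.

Severity policy: range and transfer violations are ``error``;
implausibility and outlier findings are ``warning`` (they are resolved
by manual review, not automatically).
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import pandas as pd

from .core import (
    ComponentRegistry,
    FATTY_ACID_SUMMARY_TAGS,
    PROXIMATE_TAGS,
    SourceFoodRecord,
    _FOODEX2_RE,
)
from .unify import UnifiedFood

__all__ = [
    "QCConfig",
    "QCFinding",
    "QCReport",
    "check_proximate_sum",
    "check_implausible",
    "check_transfer",
    "run_suite",
    "RULE_CHECK_IDS",
]

#: deterministic, rule-based check ids whose planted-defect recall and
#: precision are scored exactly (outlier warnings are legitimately
#: data-dependent and scored separately)
RULE_CHECK_IDS = (
    "proximate_sum",
    "fat_zero_with_components",
    "fat_without_components",
    "fiber_in_fish",
)

_STAGES = {"harmonization", "unification", "management", "recipes"}
_CHECK_STAGE = {
    "food_name": "harmonization",
    "food_group": "harmonization",
    "foodex2_code": "harmonization",
    "tagname_resolution": "harmonization",
    "proximate_sum": "unification",
    "fat_zero_with_components": "unification",
    "fat_without_components": "unification",
    "fiber_in_fish": "unification",
    "outlier": "unification",
    "transfer": "management",
    "recipe_model": "recipes",
}


@dataclass(frozen=True)
class QCConfig:
    """Tunable screen parameters and per-rule toggles."""

    proximate_low: float = 95.0
    proximate_high: float = 105.0
    fat_threshold_g: float = 1.0   # rule (b) fires above this much fat
    fish_groups: tuple[str, ...] = ("fish",)
    enable_fat_zero_with_components: bool = True
    enable_fat_without_components: bool = True
    enable_fiber_in_fish: bool = True
    enable_outlier_findings: bool = True

    def is_fish(self, food_group: str) -> bool:
        g = (food_group or "").lower()
        return any(label in g for label in self.fish_groups)


@dataclass(frozen=True)
class QCFinding:
    check_id: str
    severity: str               # "error" | "warning"
    foodex2: Optional[str]
    tagname: Optional[str]
    detail: str
    stage: str

    def __post_init__(self) -> None:
        if self.check_id not in _CHECK_STAGE:
            raise ValueError(f"unregistered check id {self.check_id!r}")
        if self.stage not in _STAGES or _CHECK_STAGE[self.check_id] != self.stage:
            raise ValueError(f"check {self.check_id} cannot occur at stage {self.stage!r}")
        if self.severity not in ("error", "warning"):
            raise ValueError(f"unknown severity {self.severity!r}")


@dataclass
class QCReport:
    findings: list[QCFinding] = field(default_factory=list)
    n_foods_checked: int = 0

    @property
    def summary(self) -> dict[str, int]:
        return dict(Counter(f.check_id for f in self.findings))

    @property
    def has_errors(self) -> bool:
        return any(f.severity == "error" for f in self.findings)

    def to_json(self) -> str:
        return json.dumps({
            "n_foods_checked": self.n_foods_checked,
            "summary": self.summary,
            "findings": [asdict(f) for f in self.findings],
        }, indent=2, ensure_ascii=False)

    def to_text(self) -> str:
        lines = [f"QC report: {len(self.findings)} finding(s) "
                 f"on {self.n_foods_checked} food(s)"]
        for cid, n in sorted(self.summary.items()):
            lines.append(f"  {cid}: {n}")
        for f in self.findings:
            lines.append(f"  [{f.severity}] {f.check_id} {f.foodex2 or '-'} "
                         f"{f.tagname or '-'}: {f.detail}")
        return "\n".join(lines)


def _value(food, tagname: str) -> Optional[float]:
    if isinstance(food, UnifiedFood):
        return food.chosen_value(tagname)
    return food.component_value(tagname)


def check_proximate_sum(food, config: QCConfig = QCConfig()) -> Optional[QCFinding]:
    """Water + protein + fat + total carbohydrate + alcohol + ash must
    land in the 95–105 g window per 100 g (closed interval).

    Missing terms contribute 0 but are named in the finding detail.
    Only meaningful on a per-100 g basis; per-100 mL foods are skipped.
    """
    if food.basis != "per_100g":
        return None
    total = 0.0
    missing = []
    for tag in PROXIMATE_TAGS:
        v = _value(food, tag)
        if v is None:
            missing.append(tag)
        else:
            total += v
    if config.proximate_low <= total <= config.proximate_high:
        return None
    detail = f"proximate sum {total:.6g} g outside [{config.proximate_low:g}, {config.proximate_high:g}]"
    if missing:
        detail += f"; missing terms treated as 0: {','.join(missing)}"
    return QCFinding("proximate_sum", "error", str(food.foodex2), None,
                     detail, "unification")


def check_implausible(
    food,
    config: QCConfig = QCConfig(),
    registry: Optional[ComponentRegistry] = None,
) -> list[QCFinding]:
    """Implausible-value screen (warnings for review, never edits).

    (a) total fat = 0 while an individual fatty acid or cholesterol is
    positive; (b) total fat above the threshold while fatty-acid
    summaries and cholesterol are all zero or missing (suspicious
    completeness); (c) positive fibre in a fish-group food.
    """
    findings: list[QCFinding] = []
    code = str(food.foodex2)
    fat = _value(food, "FAT")

    fa_tags = list(FATTY_ACID_SUMMARY_TAGS)
    if registry is not None:
        if isinstance(food, UnifiedFood):
            tags = food.values.keys()
        else:
            tags = food.values.keys()
        fa_tags += [t for t in tags
                    if t in registry and registry.resolve(t).component_class == "fatty_acid"
                    and t not in fa_tags]
    detail_tags = fa_tags + ["CHOLE"]

    if config.enable_fat_zero_with_components and fat == 0:
        positive = [t for t in detail_tags if (_value(food, t) or 0) > 0]
        if positive:
            findings.append(QCFinding(
                "fat_zero_with_components", "warning", code, "FAT",
                f"total fat is 0 but {','.join(positive)} > 0", "unification"))

    if (config.enable_fat_without_components and fat is not None
            and fat > config.fat_threshold_g):
        if all(not _value(food, t) for t in detail_tags):
            findings.append(QCFinding(
                "fat_without_components", "warning", code, "FAT",
                f"total fat {fat:.6g} g with no fatty-acid or cholesterol detail",
                "unification"))

    if config.enable_fiber_in_fish and config.is_fish(food.food_group):
        fib = _value(food, "FIBTG")
        if fib is not None and fib > 0:
            findings.append(QCFinding(
                "fiber_in_fish", "warning", code, "FIBTG",
                f"fibre {fib:.6g} g in fish-group food ({food.food_group})",
                "unification"))
    return findings


def _eq(a, b) -> bool:
    if isinstance(a, float) and isinstance(b, float) and math.isnan(a) and math.isnan(b):
        return True
    return a == b


def check_transfer(
    export_a: pd.DataFrame,
    export_b: pd.DataFrame,
    key_columns: Iterable[str] = ("foodex2", "basis"),
) -> Optional[QCFinding]:
    """Verify a flat export against its relational round-trip.

    Row counts, key sets and every cell must agree bit-exactly (NaN
    matches NaN).  Any discrepancy yields a single error finding that
    names the offending keys / cells.
    """
    key_columns = list(key_columns)
    problems: list[str] = []
    if len(export_a) != len(export_b):
        problems.append(f"row count {len(export_a)} vs {len(export_b)}")
    a = export_a.set_index(key_columns).sort_index()
    b = export_b.set_index(key_columns).sort_index()
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a):
        problems.append(f"keys only in first: {list(only_a)}")
    if len(only_b):
        problems.append(f"keys only in second: {list(only_b)}")
    cols_a, cols_b = set(a.columns), set(b.columns)
    if cols_a != cols_b:
        problems.append(f"column sets differ: {sorted(cols_a ^ cols_b)}")
    shared = a.index.intersection(b.index)
    for key in shared:
        ra, rb = a.loc[key], b.loc[key]
        for col in sorted(cols_a & cols_b):
            if not _eq(ra[col], rb[col]):
                problems.append(f"value mismatch at {key} {col}: {ra[col]!r} != {rb[col]!r}")
    if not problems:
        return None
    return QCFinding("transfer", "error", None, None,
                     "; ".join(problems), "management")


def run_suite(
    foods: list[UnifiedFood] | list[SourceFoodRecord],
    registry: Optional[ComponentRegistry] = None,
    config: QCConfig = QCConfig(),
    transfer_pair: Optional[tuple[pd.DataFrame, pd.DataFrame]] = None,
) -> QCReport:
    """Run the full check suite and return a deterministic report.

    Harmonization checks (name present, group present, FoodEx2 pattern,
    tagname resolution), the proximate-sum and implausible-value
    screens, outlier flags already attached by the unifier, and — when a
    ``transfer_pair`` of exports is supplied — the transfer check.
    """
    report = QCReport(n_foods_checked=len(foods))
    for food in sorted(foods, key=lambda f: (str(f.foodex2), f.basis)):
        code = str(food.foodex2)
        if not _FOODEX2_RE.match(code):   # defensive; constructors validate
            report.findings.append(QCFinding(
                "foodex2_code", "error", code, None,
                "malformed FoodEx2 code", "harmonization"))
        name = food.name if isinstance(food, UnifiedFood) else \
            (food.english_name or food.original_name)
        if not name:
            report.findings.append(QCFinding(
                "food_name", "warning", code, None, "food has no name",
                "harmonization"))
        if not food.food_group:
            report.findings.append(QCFinding(
                "food_group", "warning", code, None, "food has no group label",
                "harmonization"))
        if registry is not None:
            for tag in sorted(food.values):
                if tag not in registry:
                    report.findings.append(QCFinding(
                        "tagname_resolution", "error", code, tag,
                        "tagname does not resolve in the component registry",
                        "harmonization"))
        f = check_proximate_sum(food, config)
        if f is not None:
            report.findings.append(f)
        report.findings.extend(check_implausible(food, config, registry))
        if config.enable_outlier_findings and isinstance(food, UnifiedFood):
            for tag in sorted(food.values):
                uv = food.values[tag]
                if uv.outlier_flag:
                    report.findings.append(QCFinding(
                        "outlier", "warning", code, tag,
                        f"outlier screen: {len(uv.flagged_contributors)} flagged "
                        f"contributor(s), sd={uv.sd:.6g}", "unification"))
    if transfer_pair is not None:
        f = check_transfer(*transfer_pair)
        if f is not None:
            report.findings.append(f)
    return report
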