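"""Energy recalculation from macronutrients with Atwater factors.

Energy is recomputed as ``4·protein + 9·fat + 4·carbohydrate +
7·alcohol`` kcal per 100 g (general Atwater system), with an optional
2 kcal/g dietary-fibre term, and converted to kJ at 4.184 kJ/kcal.
Recalculated energy never silently overwrites a source energy value:
the result carries the original alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import KJ_PER_KCAL
from .unify import UnifiedFood
from .core import SourceFoodRecord

__all__ = ["AtwaterFactors", "EnergyResult", "recalc_energy"]


@dataclass(frozen=True)
class AtwaterFactors:
    """Caloric conversion factors, kcal per gram of macronutrient.

    Defaults are the general Atwater factors (protein 4, fat 9,
    carbohydrate 4, alcohol 7).  The fibre term defaults to 0 (off);
    :meth:`with_fiber` enables the conventional 2 kcal/g.
    ``carbohydrate_tagname`` selects which tagname feeds the formula —
    available carbohydrate (``CHOAVL``) by default, total carbohydrate
    by difference (``CHOCDF``) if preferred.
    """

    protein: float = 4.0
    fat: float = 9.0
    carbohydrate: float = 4.0
    alcohol: float = 7.0
    fiber: float = 0.0
    kj_per_kcal: float = KJ_PER_KCAL
    carbohydrate_tagname: str = "CHOAVL"

    def __post_init__(self) -> None:
        for name in ("protein", "fat", "carbohydrate", "alcohol", "fiber"):
            if getattr(self, name) < 0:
                raise ValueError(f"Atwater factor {name} must be >= 0")

    @classmethod
    def with_fiber(cls, **kw) -> "AtwaterFactors":
        kw.setdefault("fiber", 2.0)
        return cls(**kw)


@dataclass
class EnergyResult:
    kcal: float
    kj: float
    missing_terms: list[str] = field(default_factory=list)
    original_kcal: float | None = None
    original_kj: float | None = None


def _get(food, tagname: str) -> float | None:
    if isinstance(food, UnifiedFood):
        return food.chosen_value(tagname)
    if isinstance(food, SourceFoodRecord):
        return food.component_value(tagname)
    return food.get(tagname)  # plain mapping


def recalc_energy(food, factors: AtwaterFactors = AtwaterFactors()) -> EnergyResult:
    """Recalculate energy per 100 g for a unified food, a source record
    or a plain tagname→value mapping.

    Missing macronutrient terms contribute 0 and are listed in
    ``missing_terms``.  Any source energy values (``ENERC_KCAL`` /
    ``ENERC_KJ``) are carried along untouched.
    """
    terms = {
        "PROT": factors.protein,
        "FAT": factors.fat,
        factors.carbohydrate_tagname: factors.carbohydrate,
        "ALC": factors.alcohol,
    }
    if factors.fiber > 0:
        terms["FIBTG"] = factors.fiber
    kcal = 0.0
    missing = []
    for tag, factor in terms.items():
        v = _get(food, tag)
        if v is None:
            missing.append(tag)
        else:
            kcal += factor * v
    return EnergyResult(
        kcal=kcal,
        kj=kcal * factors.kj_per_kcal,
        missing_terms=missing,
        original_kcal=_get(food, "ENERC_KCAL"),
        original_kj=_get(food, "ENERC_KJ"),
    )
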