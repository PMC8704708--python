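"""Shared test utilities: pipeline driver and independent oracles."""

from __future__ import annotations

import math
import statistics
from collections import defaultdict
from decimal import Decimal
from fractions import Fraction

from fcdbkit.core import ComponentRegistry, SourceFoodRecord
from fcdbkit.fixtures import FixtureBundle
from fcdbkit.ingest import apply_exclusion_filter, ingest_source
from fcdbkit.unify import OutlierConfig, UnifiedFood, unify_database


def run_pipeline(bundle: FixtureBundle, outlier_config=OutlierConfig()):
    """Ingest every fixture source and unify; returns (foods, match report)."""
    records = []
    for sid in sorted(bundle.tables):
        recs, log = ingest_source(bundle.tables[sid], bundle.mappings[sid],
                                  bundle.registry)
        assert not any(e.action == "rejected" for e in log), log
        records.extend(recs)
    kept, _excluded, _log = apply_exclusion_filter(records)
    return unify_database(kept, bundle.registry, outlier_config)


# ---------------------------------------------------------------------------
# Brute-force unification oracle (independent of fcdbkit.unify)
# ---------------------------------------------------------------------------

def oracle_round(value: float, component_class: str) -> float:
    """Half-up rounding via exact rational arithmetic (independent of the
    Decimal-quantize implementation under test)."""
    if value == 0:
        return 0.0
    f = Fraction(Decimal(str(value)))
    if component_class in ("proximate", "energy"):
        ndigits = 1
    else:
        # exponent of the leading decimal digit
        exp = Decimal(str(value)).adjusted()
        ndigits = 2 - exp
    scale = Fraction(10) ** ndigits
    rounded = math.floor(f * scale + Fraction(1, 2))
    return float(Fraction(rounded, 1) / scale)


def oracle_unify(records: list[SourceFoodRecord], registry: ComponentRegistry):
    """Group-by-code + per-component median, computed the slow obvious way.

    Returns {(code, basis): {tagname: (n, mean, median, chosen)}} using
    statistics.mean/median and rational rounding.  Zeros are dropped as
    missing; logical zeros / traces yield a consensus 0 only when no
    source measured the component.
    """
    groups = defaultdict(list)
    for r in records:
        groups[(r.foodex2.code, r.basis)].append(r)
    out = {}
    for key, group in groups.items():
        per_tag = {}
        tags = set()
        for r in group:
            tags |= set(r.values)
        for tag in tags:
            cls = registry.resolve(tag).component_class
            measured = []
            soft = 0
            for r in group:
                cv = r.values.get(tag)
                if cv is None:
                    continue
                if cv.status == "measured":
                    measured.append(cv.raw_value)
                elif cv.status in ("logical_zero", "trace"):
                    soft += 1
                # "zero" and "missing" contribute nothing
            if measured:
                med = statistics.median(measured)
                per_tag[tag] = (len(measured), statistics.mean(measured), med,
                                oracle_round(med, cls))
            elif soft:
                per_tag[tag] = (soft, 0.0, 0.0, 0.0)
        out[key] = per_tag
    return out


def assert_matches_oracle(foods: list[UnifiedFood], oracle: dict) -> None:
    got_keys = {(f.foodex2.code, f.basis) for f in foods}
    assert got_keys == set(oracle)
    for food in foods:
        expected = oracle[(food.foodex2.code, food.basis)]
        assert set(food.values) == set(expected), food.foodex2.code
        for tag, uv in food.values.items():
            n, mean, median, chosen = expected[tag]
            assert uv.n_sources == n
            assert uv.median == median, (food.foodex2.code, tag)
            assert uv.chosen == chosen, (food.foodex2.code, tag)
            assert math.isclose(uv.mean, mean, rel_tol=1e-12)
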