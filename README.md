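# fcdbkit

Toolkit for constructing a **unified food composition database (FCDB)**
from heterogeneous source tables, and for computing recipe composition
from it.

National and international food composition tables disagree: they code
foods differently, report components in different units and under
different names, hide missing values behind zeros, and occasionally
contain wild outliers. Compilers building a cross-country FCDB — for
nutritional epidemiology, dietary assessment or personalized-nutrition
services — need to harmonize those sources to a common scheme, merge
what is genuinely the same food, and control data quality at every
step. `fcdbkit` implements that workflow end to end:

1. **Harmonization** — each source table is read with a mapping
   configuration; foods are identified by EFSA **FoodEx2** codes,
   components by FAO/INFOODS-style **tagnames** with fixed standard
   units (`g`, `mg`, `µg`, `kcal`, `kJ`), and all values are converted
   to the standard unit per 100 g (or 100 mL) of edible portion.
   Original source identifiers, values and units are preserved for
   traceability. Fortified foods, supplements, commercial brands and
   prepared dishes are excluded; generic foods (cooked included) are
   kept.
2. **Unification** — foods sharing a FoodEx2 code are matched across
   sources. Plain zeros are treated as missing (a 0 too often encodes
   an absent measurement), genuine "logical zeros" are reinstated when
   all sources agree. Per component the toolkit records n, mean,
   median and SD, and selects the **median** as the consensus value:

   *chosen(k) = round( median { v₁ₖ, …, v_nₖ } )*

   with half-up rounding to 1 decimal for proximates/energy and 3
   significant figures otherwise. A robust outlier screen
   (|v − median| / (1.4826·MAD) > 3.5, or CV > 2) marks values for
   review without ever editing them.
3. **Quality control** — a staged (HACCP-style) check suite:
   proximate completeness (water + protein + fat + carbohydrate +
   alcohol + ash within 95–105 g/100 g), implausible-value rules
   (fat = 0 with fatty acids present; fat without any fatty-acid or
   cholesterol detail; fibre in fish), outlier flags, and a bit-exact
   transfer check between the flat export and the relational store.
4. **Energy** — recalculated from macronutrients with Atwater factors:
   *E = 4·P + 9·F + 4·C + 7·A (+ 2·fibre)* kcal/100 g, kJ = kcal·4.184.
5. **Recipes** — the EuroFIR *mixed method*: per ingredient *i*,
   edible weight *wᵢ = rawᵢ·EPᵢ* and retained amount
   *(wᵢ/100)·cᵢₖ·RF(k, groupᵢ, method)*; summed over ingredients and
   divided by the cooked weight *W = YF·Σ wᵢ* (yield factor applied
   once at recipe level) to give per-100 g and per-total values with a
   full factor audit.
6. **Storage** — an eight-table SQLite schema (sources, components,
   foods, component_values with contributor provenance, yield and
   retention factors, recipes, recipe ingredients) whose round-trip is
   verified bit-exactly; `trace()` walks any unified value back to the
   original source rows, values and units.

Because real source FCDBs are licensed, the package ships a
first-class synthetic fixture generator (`fcdbkit.fixtures`) that
emulates the multi-source setting with known ground truth, planted
zeros/outliers and discordant units, so every stage is testable.

## Worked example

Four sources report raw spinach (`A00MH`); one selenium value is an
order of magnitude off:

```python
from fcdbkit import (ComponentDefinition, ComponentRegistry, ComponentValue,
                     FoodEx2Code, SourceFoodRecord, unify_database)

registry = ComponentRegistry([
    ComponentDefinition("PROT", "protein", "g", "proximate"),
    ComponentDefinition("SE", "selenium", "µg", "mineral"),
])

def record(source, fid, prot, se):
    return SourceFoodRecord(source, fid, "Spinach, raw", FoodEx2Code("A00MH"),
                            english_name="Spinach, raw", food_group="Vegetables",
                            values={"PROT": ComponentValue("PROT", prot, "g"),
                                    "SE": ComponentValue("SE", se, "µg")})

records = [record("spain", "ES-204", 2.9, 1.0),
           record("germany", "DE-G7110", 2.8, 0.7),
           record("uk", "UK-13-145", 2.8, 9.9),
           record("netherlands", "NL-562", 3.1, 0.6)]
foods, report = unify_database(records, registry)
for tag, uv in foods[0].values.items():
    print(f"{tag}: n={uv.n_sources} mean={uv.mean:.3f} median={uv.median} "
          f"sd={uv.sd:.3f} chosen={uv.chosen}")
```

prints

```
PROT: n=4 mean=2.900 median=2.8499999999999996 sd=0.141 chosen=2.8
SE: n=4 mean=3.050 median=0.85 sd=4.570 chosen=0.85
```

Protein is consistent across sources (the food is correctly matched);
for selenium the mean (3.05 µg) is dragged toward the 9.9 µg outlier
while the median keeps the consensus at 0.85 µg — the reason the
median is the chosen value. The chosen values are the rounded medians
(2.8 g protein, 0.85 µg selenium per 100 g).

The same workflow is available from the shell:

```bash
fcdb fixtures make --out demo --seed 5 --sources 3 --foods 12
fcdb ingest --source demo/src00.csv --mapping demo/src00.mapping.yaml \
            --registry demo/registry.csv --out src00.records.json
# ... ingest the other sources ...
fcdb unify --records src00.records.json --records src01.records.json \
           --records src02.records.json --registry demo/registry.csv --out unified/
fcdb export --db unified/unified.json --store fcdb.sqlite --registry demo/registry.csv
fcdb qc --db unified/unified.json --registry demo/registry.csv --store fcdb.sqlite
```

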