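-- Relational schema of the unified food composition store.
-- Eight interrelated tables; contributor provenance is denormalized into
-- component_values (one row per contributing source value), so every
-- unified value traces back to at least one original source record.

PRAGMA foreign_keys = ON;

CREATE TABLE sources (
    source_id       TEXT PRIMARY KEY,
    name            TEXT NOT NULL DEFAULT '',
    country_or_org  TEXT NOT NULL DEFAULT '',
    version_date    TEXT NOT NULL DEFAULT '',
    notes           TEXT NOT NULL DEFAULT ''
);

CREATE TABLE components (
    tagname         TEXT PRIMARY KEY,
    display_name    TEXT NOT NULL DEFAULT '',
    standard_unit   TEXT NOT NULL,
    component_class TEXT NOT NULL,
    tagname_origin  TEXT NOT NULL DEFAULT 'infoods_standard'
);

CREATE TABLE foods (
    food_key        INTEGER PRIMARY KEY,
    foodex2         TEXT NOT NULL,
    basis           TEXT NOT NULL DEFAULT 'per_100g',
    name            TEXT NOT NULL DEFAULT '',
    food_group      TEXT NOT NULL DEFAULT '',
    edible_portion  REAL NOT NULL DEFAULT 1.0,
    cooking_method  TEXT,
    matched         INTEGER NOT NULL DEFAULT 0,
    UNIQUE (foodex2, basis)
);

-- one row per (food, component, contributor); the per-component
-- statistics repeat across a component's contributor rows
CREATE TABLE component_values (
    value_key            INTEGER PRIMARY KEY,
    food_key             INTEGER NOT NULL REFERENCES foods(food_key),
    tagname              TEXT NOT NULL REFERENCES components(tagname),
    n_sources            INTEGER NOT NULL,
    mean                 REAL NOT NULL,
    median               REAL NOT NULL,
    sd                   REAL NOT NULL,
    chosen               REAL NOT NULL,
    outlier_flag         INTEGER NOT NULL DEFAULT 0,
    logical_zero         INTEGER NOT NULL DEFAULT 0,
    contributor_source   TEXT NOT NULL REFERENCES sources(source_id),
    contributor_food_id  TEXT NOT NULL,
    contributor_value    REAL NOT NULL,
    contributor_flagged  INTEGER NOT NULL DEFAULT 0,
    original_value       REAL,
    original_unit        TEXT
);

CREATE TABLE yield_factors (
    yf_key          INTEGER PRIMARY KEY,
    food_group      TEXT NOT NULL,
    cooking_method  TEXT NOT NULL,
    yf              REAL NOT NULL CHECK (yf > 0)
);

CREATE TABLE retention_factors (
    rf_key          INTEGER PRIMARY KEY,
    tagname         TEXT REFERENCES components(tagname),
    component_class TEXT,
    food_group      TEXT NOT NULL DEFAULT 'ANY',
    cooking_method  TEXT NOT NULL,
    rf              REAL NOT NULL CHECK (rf >= 0),
    CHECK ((tagname IS NULL) <> (component_class IS NULL))
);

CREATE TABLE recipes (
    recipe_id       TEXT PRIMARY KEY,
    name            TEXT NOT NULL DEFAULT '',
    cooking_method  TEXT NOT NULL,
    yf_override     REAL
);

CREATE TABLE recipe_ingredients (
    ingredient_key          INTEGER PRIMARY KEY,
    recipe_id               TEXT NOT NULL REFERENCES recipes(recipe_id),
    foodex2                 TEXT NOT NULL,
    basis                   TEXT NOT NULL DEFAULT 'per_100g',
    raw_weight_g            REAL NOT NULL CHECK (raw_weight_g > 0),
    edible_portion_override REAL,
    FOREIGN KEY (foodex2, basis) REFERENCES foods(foodex2, basis)
);
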