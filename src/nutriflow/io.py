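"""CSV schemas and world round-tripping.

Every table the pipeline reads or writes is a plain CSV with a declared
column set; validation is fail-fast and names the file and the missing or
unexpected columns.  Floats are written at 10 significant digits so that
reruns under an identical manifest are byte-identical.
"""

from __future__ import annotations

import os

import pandas as pd

from .nutrients import CONC_COLUMNS, PREV_COLUMNS
from .synth import World, WorldConfig

FLOAT_FORMAT = "%.10g"

SCHEMAS: dict[str, list[str]] = {
    "catch.csv": ["year", "fishing_nation", "source_zone", "taxon_id", "tonnes"],
    "trade.csv": ["year", "exporter", "importer", "taxon_id", "tonnes"],
    "taxa.csv": ["taxon_id", "rank", "species", "genus", "family", *CONC_COLUMNS],
    "foc.csv": ["nation", "prop_foc_2013", "prop_foc_2018"],
    "indicators.csv": [
        "nation", "population", "fish_protein_share", "gdp_pc", "stability",
        "health_exp", "net_food_importer", "production_change", "hdi",
        "inequality_coef", *PREV_COLUMNS, "energy_adequacy",
    ],
    "rni.csv": ["nutrient", "rni_per_day"],
    "ledger.csv": ["nation", "nutrient", "channel", "mass", "rni_equiv"],
    "balances.csv": [
        "nation", "nutrient", "ffb", "tb", "include_high_seas", "foc_adjusted",
    ],
}


class SchemaError(ValueError):
    pass


def validate_columns(df: pd.DataFrame, name: str) -> None:
    """Check a frame against its declared schema (exact column set)."""
    expected = SCHEMAS.get(name)
    if expected is None:
        return
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def read_csv(path: str) -> pd.DataFrame:
    name = os.path.basename(path)
    df = pd.read_csv(path)
    validate_columns(df, name)
    return df


def write_csv(df: pd.DataFrame, path: str) -> None:
    name = os.path.basename(path)
    validate_columns(df, name)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_world(directory: str, config: WorldConfig) -> World:
    """Load a world from the canonical CSV directory."""
    catch = read_csv(os.path.join(directory, "catch.csv"))
    trade = read_csv(os.path.join(directory, "trade.csv"))
    taxa = read_csv(os.path.join(directory, "taxa.csv")).fillna(
        {"species": "", "genus": "", "family": ""}
    )
    foc = read_csv(os.path.join(directory, "foc.csv"))
    indicators = read_csv(os.path.join(directory, "indicators.csv"))
    nations = indicators["nation"].tolist()
    return World(
        nations=nations, catch=catch, trade=trade, taxa=taxa, foc=foc,
        indicators=indicators, config=config,
    )
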