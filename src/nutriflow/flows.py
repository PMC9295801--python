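"""Nutrient flows between inadequate-intake categories.

Nations are binned by their prevalence of inadequate intake of a nutrient
into right-closed categories (V.Lo ≤ 5 < Lo ≤ 10 < Med ≤ 25 < Hi ≤ 50 <
V.Hi; ND when no prevalence data exist), and focal-year nutrient masses
are routed between categories: foreign-fishing flows from the source-EEZ
nation's category (or HS for high-seas catch) to the fleet nation's
category (or FOC for pool catch); trade flows from the exporter's to the
importer's category.  Flow matrices are produced for the four
micronutrients with national intake data: calcium, iron, zinc, vitamin A.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .accounting import NutrientLedger, per_capita_yield
from .nutrients import FLOW_NUTRIENTS, FOC_POOL, HIGH_SEAS

CATEGORIES = ("V.Lo", "Lo", "Med", "Hi", "V.Hi", "ND")
ALL_CATEGORIES = CATEGORIES + (FOC_POOL, HIGH_SEAS)

#: Right-closed upper bounds of the prevalence categories, in percent.
_BOUNDS = ((5.0, "V.Lo"), (10.0, "Lo"), (25.0, "Med"), (50.0, "Hi"))


def categorize_prevalence(p: float | None) -> str:
    """Intake category for a prevalence in percent; missing → "ND"."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "ND"
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"prevalence must be in [0, 100], got {p}")
    for bound, label in _BOUNDS:
        if p <= bound:
            return label
    return "V.Hi"


def nation_categories(indicators: pd.DataFrame, nutrient: str) -> pd.Series:
    """Per-nation intake category for one nutrient."""
    col = f"prev_{nutrient}"
    if col not in indicators.columns:
        raise KeyError(f"no intake-prevalence column for nutrient {nutrient!r}")
    prev = indicators.set_index("nation")[col]
    return prev.map(categorize_prevalence)


def _dependent_nations(indicators: pd.DataFrame, threshold: float) -> set[str]:
    share = indicators.set_index("nation")["fish_protein_share"]
    return set(share[share > threshold].index)


def aggregate_flows(
    ledger: NutrientLedger,
    indicators: pd.DataFrame,
    nutrient: str,
    channel: str,
    fish_dependence_filter: float | None = None,
) -> pd.DataFrame:
    """Category × category flow matrix of one nutrient's mass.

    ``channel`` is "foreign_fishing" or "trade".  With the fish-dependence
    filter set, only nations whose fish share of animal protein is
    strictly above the threshold are included (the HS and FOC
    pseudo-sources always are).  Rows are source categories, columns sink
    categories; cells are nutrient mass per year.
    """
    if nutrient not in FLOW_NUTRIENTS:
        raise ValueError(
            f"flow matrices exist only for {FLOW_NUTRIENTS}, got {nutrient!r}"
        )
    if channel not in ("foreign_fishing", "trade"):
        raise ValueError(f"unknown channel {channel!r}")

    cats = nation_categories(indicators, nutrient)
    included = (
        _dependent_nations(indicators, fish_dependence_filter)
        if fish_dependence_filter is not None
        else set(cats.index)
    )
    mass_col = f"mass_{nutrient}"

    if channel == "foreign_fishing":
        rec = ledger.catch_nutrients
        rec = rec[rec["source_zone"] != rec["origin_nation"]]
        src_ok = rec["source_zone"].isin(included) | (rec["source_zone"] == HIGH_SEAS)
        snk_ok = rec["fishing_nation"].isin(included) | (
            rec["fishing_nation"] == FOC_POOL
        )
        rec = rec[src_ok & snk_ok]
        source = rec["source_zone"].map(
            lambda z: HIGH_SEAS if z == HIGH_SEAS else cats.get(z, "ND")
        )
        sink = rec["fishing_nation"].map(
            lambda f: FOC_POOL if f == FOC_POOL else cats.get(f, "ND")
        )
    else:
        rec = ledger.trade_nutrients
        rec = rec[rec["exporter"].isin(included) & rec["importer"].isin(included)]
        source = rec["exporter"].map(cats)
        sink = rec["importer"].map(cats)

    mat = (
        pd.DataFrame({"source": source, "sink": sink, "mass": rec[mass_col]})
        .groupby(["source", "sink"])["mass"]
        .sum()
        .unstack(fill_value=0.0)
    )
    return mat.reindex(
        index=list(ALL_CATEGORIES), columns=list(ALL_CATEGORIES), fill_value=0.0
    )


def yield_by_category(
    ledger: NutrientLedger,
    indicators: pd.DataFrame,
    nutrient: str,
    role: str,
    fish_dependence_filter: float | None = None,
) -> pd.Series:
    """Median per-capita yield (% RNI per capita per day) per category.

    Roles: "source" — mass extracted from the nation's EEZ by foreign
    fleets; "sink" — mass the nation's fleet catches abroad (EEZs + high
    seas); "sink_eez_only" — the same excluding high-seas catch;
    "exporter" / "importer" — traded mass.  The median is unweighted over
    nations within a category; empty categories are reported as missing.
    """
    channel = {
        "source": "loss_ff",
        "sink": None,
        "sink_eez_only": "ff_eez",
        "exporter": "exported",
        "importer": "imported",
    }
    if role not in channel:
        raise ValueError(f"unknown role {role!r}")
    if role == "sink":
        mass = (
            ledger.channel("ff_eez", "mass") + ledger.channel("ff_hs", "mass")
        )[nutrient]
    else:
        mass = ledger.channel(channel[role], "mass")[nutrient]

    cats = nation_categories(indicators, nutrient)
    pop = indicators.set_index("nation")["population"]
    included = (
        _dependent_nations(indicators, fish_dependence_filter)
        if fish_dependence_filter is not None
        else set(cats.index)
    )
    rni = ledger.rni[nutrient]
    rows = {
        nat: per_capita_yield(mass.get(nat, 0.0), pop[nat], rni)
        for nat in cats.index
        if nat in included
    }
    ydf = pd.DataFrame({"cat": cats.loc[list(rows)], "y": pd.Series(rows)})
    med = ydf.groupby("cat")["y"].median()
    return med.reindex(list(CATEGORIES))


def log_transform(y: float | np.ndarray) -> float | np.ndarray:
    """Presentation transform log10(y + 1); requires y ≥ 0."""
    if np.any(np.asarray(y) < 0):
        raise ValueError("yield must be non-negative")
    return np.log10(np.asarray(y, dtype=float) + 1.0) if np.ndim(y) else math.log10(y + 1.0)


def export_sankey_table(flow_matrix: pd.DataFrame, drop_zeros: bool = True) -> pd.DataFrame:
    """Tidy (source_category, sink_category, mass) table from a flow matrix."""
    long = (
        flow_matrix.rename_axis(index="source_category", columns="sink_category")
        .stack()
        .rename("mass")
        .reset_index()
    )
    if drop_zeros:
        long = long[long["mass"] > 0]
    return long.reset_index(drop=True)
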