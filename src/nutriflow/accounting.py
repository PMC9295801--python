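"""Tonnage → nutrient mass → RNI-equivalent accounting.

Converts focal-year catch and trade records into per-nation nutrient
masses partitioned by supply channel, applies the flag-of-convenience
(FOC) reattribution, and expresses masses as RNI-equivalents: the number
of reproductive-age females whose annual recommended nutrient intake the
mass could theoretically cover.

Channels
--------
domestic
    A nation's own fleet fishing its own EEZ (FOC-retained share).
ff_eez / ff_hs
    The nation's fleet in other nations' EEZs / on the high seas
    (FOC-retained share); together these are FF in the foreign-fishing
    balance.
loss_ff
    Catch taken from the nation's EEZ by other nations' fleets.  Fleet
    nationality here is the originally reported flag: a FOC vessel flagged
    to the nation itself is not another country's fleet, so this channel
    does not change with the FOC toggle.
imported / exported
    Bilateral trade, by importer / exporter.
foc_pool
    Catch reattributed to the unattributed FOC pool (pseudo-nation "FOC"),
    never reassigned to beneficial-owner nations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .concentrations import ConcentrationTable, resolve_coarse
from .nutrients import FOC_POOL, HIGH_SEAS, NUTRIENTS, PORTIONS_PER_TONNE
from .synth import World

#: Daily recommended nutrient intakes for reproductive-age females used by
#: the synthetic world (native units per day).  These are package defaults
#: of realistic magnitude for exercising the accounting; any real analysis
#: supplies its own RNI table via configuration.
DEFAULT_RNI: dict[str, float] = {
    "protein": 46.0,     # g
    "calcium": 1000.0,   # mg
    "iron": 29.4,        # mg
    "zinc": 4.9,         # mg
    "selenium": 26.0,    # mcg
    "omega3": 1.1,       # g
    "vitamin_a": 500.0,  # mcg
}

MASS_COLUMNS = tuple(f"mass_{n}" for n in NUTRIENTS)


def nutrient_mass(tonnes: float, conc: float) -> float:
    """Nutrient mass in the concentration's native unit.

    One tonne is 10⁴ hundred-gram portions, so mass = tonnes × 10⁴ × conc.
    """
    if tonnes < 0 or conc < 0:
        raise ValueError("tonnes and concentration must be non-negative")
    return tonnes * PORTIONS_PER_TONNE * conc


def rni_equivalents(annual_mass: float, rni_per_day: float) -> float:
    """Persons whose annual RNI the mass covers (365-day year; fractional)."""
    if rni_per_day <= 0:
        raise ValueError("rni_per_day must be positive")
    if annual_mass < 0:
        raise ValueError("annual_mass must be non-negative")
    return annual_mass / (rni_per_day * 365.0)


def per_capita_yield(
    annual_mass: float, population: float, rni_per_day: float
) -> float:
    """Percent of the daily RNI supplied per capita per day."""
    if population <= 0:
        raise ValueError("population must be positive")
    if rni_per_day <= 0:
        raise ValueError("rni_per_day must be positive")
    return (annual_mass / 365.0) / population / rni_per_day * 100.0


def foc_proportions(foc: pd.DataFrame) -> pd.Series:
    """Effective FOC proportion per nation: mean of the 2013 and 2018 columns."""
    p = (foc["prop_foc_2013"] + foc["prop_foc_2018"]) / 2.0
    p.index = foc["nation"]
    if ((p < 0) | (p > 1)).any():
        bad = p[(p < 0) | (p > 1)].index.tolist()
        raise ValueError(f"FOC proportion outside [0, 1] for: {bad}")
    return p


def apply_foc(
    catch: pd.DataFrame, foc: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split each nation's catch into a retained share and the FOC pool.

    Each record's tonnage is multiplied by (1 − p) for the flag nation,
    with the p share moved to the unattributed pool (fishing_nation set to
    the FOC pseudo-nation; the original flag is kept in ``origin_nation``
    for audit).  Total tonnage is conserved exactly.  Nations missing from
    the registry are treated as p = 0 with a warning.
    """
    p = foc_proportions(foc)
    missing = sorted(set(catch["fishing_nation"]) - set(p.index))
    if missing:
        warnings.warn(
            f"nations missing from FOC registry treated as p=0: {missing}",
            stacklevel=2,
        )
    pr = catch["fishing_nation"].map(p).fillna(0.0).to_numpy()

    retained = catch.copy()
    retained["origin_nation"] = retained["fishing_nation"]
    retained["tonnes"] = catch["tonnes"].to_numpy() * (1.0 - pr)

    pool = catch.copy()
    pool["origin_nation"] = pool["fishing_nation"]
    pool["tonnes"] = catch["tonnes"].to_numpy() * pr
    pool["fishing_nation"] = FOC_POOL
    pool = pool[pool["tonnes"] > 0]
    retained = retained[retained["tonnes"] > 0]
    return retained.reset_index(drop=True), pool.reset_index(drop=True)


@dataclass
class NutrientLedger:
    """Per-nation × nutrient × channel nutrient masses and RNI-equivalents.

    ``df`` is the tidy ledger; ``catch_nutrients`` and ``trade_nutrients``
    keep the record-level masses (wide, one mass column per nutrient) that
    the flow-aggregation stage routes between intake categories.
    """

    df: pd.DataFrame
    catch_nutrients: pd.DataFrame
    trade_nutrients: pd.DataFrame
    rni: dict[str, float]
    foc_mode: bool
    nations: list[str] = field(default_factory=list)
    #: per-(coarse taxon, context) interpolation tier actually used
    tier_audit: pd.DataFrame = field(default_factory=pd.DataFrame)

    def channel(self, channel: str, value: str = "rni_equiv") -> pd.DataFrame:
        """Nation × nutrient matrix for one channel (zero-filled)."""
        sub = self.df[self.df["channel"] == channel]
        mat = sub.pivot_table(
            index="nation", columns="nutrient", values=value, aggfunc="sum"
        )
        return mat.reindex(index=self.nations, columns=list(NUTRIENTS)).fillna(0.0)


def _attach_masses(
    records: pd.DataFrame,
    fine_values: pd.DataFrame,
    taxa: pd.DataFrame,
    context_col: str | None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach mass_<nutrient> columns to tonnage records.

    ``fine_values`` holds the resolved species/genus/family-rank
    concentrations; coarse taxa get a context-aware four-tier resolution
    per distinct (taxon, context) pair.  Returns the mass-bearing records
    and a tier audit (taxon_id, context, tier).
    """
    out = records.reset_index(drop=True)
    cc = [f"conc_{n}" for n in NUTRIENTS]

    merged = out.merge(
        fine_values, left_on="taxon_id", right_index=True, how="left"
    )
    audit_rows = []
    unresolved = merged[cc[0]].isna()
    if unresolved.any() and context_col is not None:
        pairs = out.loc[unresolved, ["taxon_id", context_col]].drop_duplicates()
        for _, (tid, ctx) in pairs.iterrows():
            vec, tier = resolve_coarse(
                tid, ctx, records, taxa, resolved=fine_values, zone_col=context_col
            )
            sel = unresolved & (out["taxon_id"] == tid) & (out[context_col] == ctx)
            merged.loc[sel, cc] = vec[cc].to_numpy()
            audit_rows.append((tid, ctx, tier))
    if merged[cc[0]].isna().any():
        bad = sorted(merged.loc[merged[cc[0]].isna(), "taxon_id"].unique())
        raise KeyError(f"unresolvable taxa in records: {bad}")

    t = merged["tonnes"].to_numpy()
    for n in NUTRIENTS:
        merged[f"mass_{n}"] = t * PORTIONS_PER_TONNE * merged[f"conc_{n}"].to_numpy()
    audit = pd.DataFrame(audit_rows, columns=["taxon_id", "context", "tier"])
    return merged.drop(columns=cc), audit


def _validate_references(world: World) -> None:
    known_zones = set(world.nations) | {HIGH_SEAS}
    bad_fisher = set(world.catch["fishing_nation"]) - set(world.nations)
    bad_zone = set(world.catch["source_zone"]) - known_zones
    bad_trade = (
        set(world.trade["exporter"]) | set(world.trade["importer"])
    ) - set(world.nations)
    bad_taxa = (
        set(world.catch["taxon_id"]) | set(world.trade["taxon_id"])
    ) - set(world.taxa["taxon_id"])
    problems = {
        "fishing nations": bad_fisher,
        "source zones": bad_zone,
        "trade nations": bad_trade,
        "taxa": bad_taxa,
    }
    offenders = {k: sorted(v) for k, v in problems.items() if v}
    if offenders:
        raise ValueError(f"records reference unknown identifiers: {offenders}")


def build_ledger(
    world: World,
    conc: ConcentrationTable,
    rni: dict[str, float] | None = None,
    foc_mode: bool = True,
) -> NutrientLedger:
    """Build the focal-year per-nation nutrient ledger.

    Channels are mutually exclusive and jointly exhaustive of the
    focal-year records: every retained catch record lands in exactly one of
    {domestic, ff_eez, ff_hs}, every pool record in foc_pool, and every
    trade record contributes once to imported and once to exported.
    """
    _validate_references(world)
    rni = dict(DEFAULT_RNI if rni is None else rni)
    missing = [n for n in NUTRIENTS if n not in rni or rni[n] <= 0]
    if missing:
        raise ValueError(f"RNI missing or non-positive for: {missing}")

    focal = world.focal_year
    catch = world.catch[world.catch["year"] == focal].copy()
    trade = world.trade[world.trade["year"] == focal].copy()

    if foc_mode:
        retained, pool = apply_foc(catch, world.foc)
    else:
        retained = catch.copy()
        retained["origin_nation"] = retained["fishing_nation"]
        pool = retained.iloc[0:0].copy()

    # coarse taxa are resolved per record context (tier 2 uses the local
    # catch composition), so only fine-rank rows use the direct table
    fine_ids = set(
        world.taxa.loc[
            world.taxa["rank"].isin(["species", "genus", "family"]), "taxon_id"
        ]
    )
    fine_values = conc.values[conc.values.index.isin(fine_ids)]

    all_catch = pd.concat([retained, pool], ignore_index=True)
    catch_n, audit_c = _attach_masses(
        all_catch, fine_values, world.taxa, context_col="source_zone"
    )
    trade_n, audit_t = _attach_masses(
        trade, fine_values, world.taxa, context_col="exporter"
    )
    tier_audit = pd.concat(
        [audit_c.assign(record_type="catch"), audit_t.assign(record_type="trade")],
        ignore_index=True,
    )

    fisher = catch_n["fishing_nation"]
    zone = catch_n["source_zone"]
    origin = catch_n["origin_nation"]
    is_pool = fisher == FOC_POOL

    channel = np.select(
        [
            is_pool,
            (fisher == zone),
            (zone == HIGH_SEAS),
        ],
        ["foc_pool", "domestic", "ff_hs"],
        default="ff_eez",
    )
    catch_n = catch_n.assign(channel=channel)

    mass_cols = list(MASS_COLUMNS)
    parts = []

    own = catch_n[~is_pool.to_numpy()]
    g = own.groupby(["fishing_nation", "channel"])[mass_cols].sum()
    g.index.names = ["nation", "channel"]
    parts.append(g)

    # losses: all catch in a nation's EEZ by originally-foreign fleets
    loss = catch_n[(origin != zone) & (zone != HIGH_SEAS)]
    gl = loss.groupby("source_zone")[mass_cols].sum()
    gl.index.name = "nation"
    gl["channel"] = "loss_ff"
    parts.append(gl.set_index("channel", append=True))

    if is_pool.any():
        gp = catch_n[is_pool.to_numpy()].groupby("fishing_nation")[mass_cols].sum()
        gp.index.name = "nation"
        gp["channel"] = "foc_pool"
        parts.append(gp.set_index("channel", append=True))

    gi = trade_n.groupby("importer")[mass_cols].sum()
    gi.index.name = "nation"
    gi["channel"] = "imported"
    parts.append(gi.set_index("channel", append=True))
    ge = trade_n.groupby("exporter")[mass_cols].sum()
    ge.index.name = "nation"
    ge["channel"] = "exported"
    parts.append(ge.set_index("channel", append=True))

    wide = pd.concat(parts)
    tidy = (
        wide.reset_index()
        .melt(id_vars=["nation", "channel"], value_vars=mass_cols,
              var_name="nutrient", value_name="mass")
    )
    tidy["nutrient"] = tidy["nutrient"].str.removeprefix("mass_")
    denom = tidy["nutrient"].map(rni) * 365.0
    tidy["rni_equiv"] = tidy["mass"] / denom
    tidy = tidy[["nation", "nutrient", "channel", "mass", "rni_equiv"]]

    return NutrientLedger(
        df=tidy.reset_index(drop=True),
        catch_nutrients=catch_n,
        trade_nutrients=trade_n,
        rni=rni,
        foc_mode=foc_mode,
        nations=list(world.nations),
        tier_audit=tier_audit,
    )
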