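"""Per-taxon nutrient concentrations with taxonomic imputation.

Each catch or trade record needs a per-100 g concentration for all seven
nutrients.  Species-rank taxa carry their own values.  Genus- and
family-rank taxa with missing values are imputed as the unweighted
arithmetic mean over the species-rank members of the same genus or family.
Taxa reported below family resolution (e.g. "marine finfishes") are
resolved by a four-tier ladder:

1. a direct entry in the taxon table (after genus/family imputation);
2. the catch-tonnage-weighted mean concentration over resolvable taxa
   reported from the same zone (or, for trade records, by the same
   trading nation);
3. the tonnage-weighted mean over resolvable taxa globally;
4. the unweighted global mean over all species-rank rows.

The ladder is a reconstruction of the local-composition logic such
interpolations follow — the mix of what is actually being landed nearby is
the best guess for what an unidentified "finfish" ton contains — and the
tier actually used for every taxon is recorded in an audit table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nutrients import CONC_COLUMNS, NUTRIENTS


class UnknownTaxonError(KeyError):
    pass


@dataclass
class ConcentrationTable:
    """Fully resolved per-taxon concentrations plus a provenance audit.

    ``values``: DataFrame indexed by taxon_id with one column per nutrient
    concentration.  ``audit``: long table (taxon_id, nutrient, value,
    source_tier) where source_tier ∈ {"species", "genus_mean",
    "family_mean", "tier1" … "tier4"}.
    """

    values: pd.DataFrame
    audit: pd.DataFrame

    def lookup(self, taxon_id: str) -> pd.Series:
        try:
            return self.values.loc[taxon_id]
        except KeyError as exc:
            raise UnknownTaxonError(taxon_id) from exc


def assign_concentration(taxon_id: str, table: pd.DataFrame) -> pd.Series:
    """Concentration vector for one species/genus/family-rank taxon.

    Species rows return their own values; genus and family rows with
    missing values take the unweighted mean over species-rank members of
    the same genus or family.  Raises ``UnknownTaxonError`` for taxa absent
    from the table and ``ValueError`` for a genus/family with no species
    members and no values of its own (such taxa fall through to the
    coarse-resolution ladder).
    """
    rows = table.loc[table["taxon_id"] == taxon_id]
    if rows.empty:
        raise UnknownTaxonError(taxon_id)
    row = rows.iloc[0]
    conc = row[list(CONC_COLUMNS)].astype(float)
    if not conc.isna().any():
        return conc
    rank = row["rank"]
    if rank not in ("genus", "family"):
        raise ValueError(
            f"taxon {taxon_id!r} at rank {rank!r} has missing concentrations"
        )
    key = "genus" if rank == "genus" else "family"
    members = table[(table["rank"] == "species") & (table[key] == row[key])]
    if members.empty:
        raise ValueError(
            f"{rank} taxon {taxon_id!r} has no species-rank members to impute from"
        )
    imputed = members[list(CONC_COLUMNS)].astype(float).mean()
    return conc.fillna(imputed)


def _weighted_mean_conc(
    taxa_conc: pd.DataFrame, weights: pd.Series | None
) -> pd.Series:
    if weights is None:
        return taxa_conc.mean()
    w = weights.reindex(taxa_conc.index).fillna(0.0)
    if w.sum() <= 0:
        return taxa_conc.mean()
    return taxa_conc.mul(w, axis=0).sum() / w.sum()


def resolve_coarse(
    taxon_id: str,
    context_zone: str | None,
    catch: pd.DataFrame,
    table: pd.DataFrame,
    resolved: pd.DataFrame | None = None,
    zone_col: str = "source_zone",
) -> tuple[pd.Series, str]:
    """Resolve a coarsely reported taxon via the four-tier ladder.

    ``resolved`` is the table of already-resolved (species/genus/family)
    concentrations indexed by taxon_id; it is rebuilt if not supplied.
    Returns ``(concentration vector, tier label)`` with tier ∈
    {"tier1" … "tier4"}.
    """
    if table.empty:
        raise ValueError("taxon table is empty")
    if resolved is None:
        resolved = _resolve_fine(table)

    # tier 1: direct entry
    if taxon_id in resolved.index:
        return resolved.loc[taxon_id], "tier1"

    focal = catch[catch["taxon_id"].isin(resolved.index)]
    tonnage = None
    if context_zone is not None and zone_col in focal.columns:
        local = focal[focal[zone_col] == context_zone]
        if len(local):
            tonnage = local.groupby("taxon_id")["tonnes"].sum()
            conc = resolved.loc[tonnage.index]
            return _weighted_mean_conc(conc, tonnage), "tier2"
    if len(focal):
        tonnage = focal.groupby("taxon_id")["tonnes"].sum()
        conc = resolved.loc[tonnage.index]
        return _weighted_mean_conc(conc, tonnage), "tier3"

    species = table[table["rank"] == "species"]
    if species.empty:
        raise ValueError("no species-rank rows available for tier-4 fallback")
    return (
        species.set_index("taxon_id")[list(CONC_COLUMNS)].astype(float).mean(),
        "tier4",
    )


def _resolve_fine(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorised genus/family imputation for every non-coarse taxon."""
    t = table.copy()
    conc = t[list(CONC_COLUMNS)].astype(float)
    species = t["rank"] == "species"
    sp = t.loc[species]
    genus_means = sp.groupby("genus")[list(CONC_COLUMNS)].mean()
    family_means = sp.groupby("family")[list(CONC_COLUMNS)].mean()

    out = conc.copy()
    for level, means in (("genus", genus_means), ("family", family_means)):
        mask = (t["rank"] == level) & conc.isna().any(axis=1)
        if not mask.any():
            continue
        fill = t.loc[mask, level].map(
            lambda name, m=means: m.loc[name] if name in m.index else pd.Series(
                np.nan, index=list(CONC_COLUMNS)
            )
        )
        fill = pd.DataFrame(list(fill), index=t.index[mask])
        out.loc[mask] = out.loc[mask].fillna(fill)

    out.index = t["taxon_id"]
    complete = ~out.isna().any(axis=1)
    fine = t["rank"].isin(["species", "genus", "family"]).to_numpy()
    return out[complete.to_numpy() & fine]


def resolve_all(
    taxa: pd.DataFrame,
    catch: pd.DataFrame,
    focal_year: int | None = None,
) -> ConcentrationTable:
    """Resolve every taxon in the table to a complete concentration vector.

    Fine-rank taxa (species, genus, family) use their own or imputed
    values; everything else goes through the four-tier ladder with the
    focal-year catch composition as context.  Coarse taxa are resolved
    globally (tier 3/4) here; record-level zone context (tier 2) is applied
    where the accounting layer knows the source zone.
    """
    if focal_year is not None and "year" in catch.columns:
        catch = catch[catch["year"] == focal_year]
    resolved = _resolve_fine(taxa)
    audit_rows = []
    values = {}
    for tid in resolved.index:
        rank = taxa.loc[taxa["taxon_id"] == tid, "rank"].iloc[0]
        own = taxa.loc[taxa["taxon_id"] == tid, list(CONC_COLUMNS)].iloc[0]
        tier = "species" if rank == "species" else (
            f"{rank}_mean" if own.isna().any() else rank
        )
        values[tid] = resolved.loc[tid]
        audit_rows.extend(
            (tid, n, float(resolved.loc[tid, f"conc_{n}"]), tier) for n in NUTRIENTS
        )
    for tid in taxa.loc[~taxa["taxon_id"].isin(resolved.index), "taxon_id"]:
        vec, tier = resolve_coarse(tid, None, catch, taxa, resolved=resolved)
        values[tid] = vec
        audit_rows.extend((tid, n, float(vec[f"conc_{n}"]), tier) for n in NUTRIENTS)

    vals = pd.DataFrame(values).T
    vals.index.name = "taxon_id"
    audit = pd.DataFrame(
        audit_rows, columns=["taxon_id", "nutrient", "value", "source_tier"]
    )
    return ConcentrationTable(values=vals[list(CONC_COLUMNS)], audit=audit)
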