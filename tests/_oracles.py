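"""Independent brute-force oracles.

Everything here iterates raw records with plain Python loops and
arithmetic — no pandas group-bys, no reuse of the package's aggregation
code — so that ledger, balance, flow, and vulnerability results can be
checked against a second, structurally different computation.
"""

from __future__ import annotations

import math
import statistics
from collections import defaultdict

from nutriflow.nutrients import FOC_POOL, HIGH_SEAS, NUTRIENTS

PORTIONS = 1e4


def foc_props(world) -> dict[str, float]:
    out = {}
    for r in world.foc.itertuples():
        out[r.nation] = (r.prop_foc_2013 + r.prop_foc_2018) / 2.0
    return out


def fine_concentrations(taxa) -> dict[str, dict[str, float]]:
    """Species values plus genus/family means, computed independently."""
    species = [r for r in taxa.to_dict("records") if r["rank"] == "species"]
    out = {}
    for r in taxa.to_dict("records"):
        tid, rank = r["taxon_id"], r["rank"]
        if rank == "species":
            out[tid] = {n: r[f"conc_{n}"] for n in NUTRIENTS}
        elif rank in ("genus", "family"):
            members = [s for s in species if s[rank] == r[rank]]
            if not members:
                continue
            out[tid] = {
                n: sum(s[f"conc_{n}"] for s in members) / len(members)
                for n in NUTRIENTS
            }
    return out


def coarse_concentration(
    tid: str, context: str | None, records, zone_col: str, fine: dict
) -> dict[str, float]:
    """Four-tier ladder re-derived by hand from focal-year records."""
    if tid in fine:
        return fine[tid]
    # tier 2: tonnage-weighted mean over resolvable taxa in the context
    pools = [
        (records, True),   # local (context-filtered)
        (records, False),  # global
    ]
    for recs, local in pools:
        tot = defaultdict(float)
        for r in recs.to_dict("records"):
            if r["taxon_id"] not in fine:
                continue
            if local and context is not None and r[zone_col] != context:
                continue
            tot[r["taxon_id"]] += r["tonnes"]
        if tot:
            w = sum(tot.values())
            return {
                n: sum(fine[t][n] * v for t, v in tot.items()) / w for n in NUTRIENTS
            }
    vals = list(fine.values())
    return {n: sum(v[n] for v in vals) / len(vals) for n in NUTRIENTS}


def oracle_ledger(world, rni: dict[str, float], foc_mode: bool):
    """Per-(nation, nutrient, channel) masses by record-by-record summation.

    Returns (masses, catch_records) where catch_records are the FOC-split
    focal-year catch rows used, for reuse by the flow oracle.
    """
    focal = world.focal_year
    fine = fine_concentrations(world.taxa)
    p = foc_props(world)
    catch = world.catch[world.catch["year"] == focal]
    trade = world.trade[world.trade["year"] == focal]

    coarse_cache: dict[tuple[str, str, str], dict[str, float]] = {}

    def conc_for(tid, ctx, records, zone_col):
        if tid in fine:
            return fine[tid]
        key = (tid, ctx, zone_col)
        if key not in coarse_cache:
            coarse_cache[key] = coarse_concentration(tid, ctx, records, zone_col, fine)
        return coarse_cache[key]

    masses: dict[tuple[str, str, str], float] = defaultdict(float)
    split_rows = []
    for r in catch.to_dict("records"):
        nat, zone, tid, t = (
            r["fishing_nation"], r["source_zone"], r["taxon_id"], r["tonnes"],
        )
        prop = p.get(nat, 0.0) if foc_mode else 0.0
        conc = conc_for(tid, zone, catch, "source_zone")
        for fleet, tt in ((nat, t * (1 - prop)), (FOC_POOL, t * prop)):
            if tt <= 0:
                continue
            split_rows.append(
                {"fleet": fleet, "origin": nat, "zone": zone, "taxon": tid,
                 "tonnes": tt, "conc": conc}
            )
            for n in NUTRIENTS:
                m = tt * PORTIONS * conc[n]
                if fleet == FOC_POOL:
                    masses[(FOC_POOL, n, "foc_pool")] += m
                elif zone == fleet:
                    masses[(fleet, n, "domestic")] += m
                elif zone == HIGH_SEAS:
                    masses[(fleet, n, "ff_hs")] += m
                else:
                    masses[(fleet, n, "ff_eez")] += m
        # losses: extraction from the zone's EEZ by originally-foreign fleets
        if zone != HIGH_SEAS and zone != nat:
            conc2 = conc
            for n in NUTRIENTS:
                masses[(zone, n, "loss_ff")] += t * PORTIONS * conc2[n]

    for r in trade.to_dict("records"):
        conc = conc_for(r["taxon_id"], r["exporter"], trade, "exporter")
        for n in NUTRIENTS:
            m = r["tonnes"] * PORTIONS * conc[n]
            masses[(r["importer"], n, "imported")] += m
            masses[(r["exporter"], n, "exported")] += m
    return masses, split_rows


def oracle_rni(masses, rni):
    return {
        k: m / (rni[k[1]] * 365.0) for k, m in masses.items()
    }


def oracle_balances(masses, rni, include_high_seas: bool):
    """FFB and TB per (nation, nutrient) in RNI-equivalents."""
    nations = {k[0] for k in masses if k[0] != FOC_POOL}
    ffb, tb = {}, {}
    for i in nations:
        for n in NUTRIENTS:
            ff = masses.get((i, n, "ff_eez"), 0.0)
            if include_high_seas:
                ff += masses.get((i, n, "ff_hs"), 0.0)
            loss = masses.get((i, n, "loss_ff"), 0.0)
            imp = masses.get((i, n, "imported"), 0.0)
            exp = masses.get((i, n, "exported"), 0.0)
            d = rni[n] * 365.0
            ffb[(i, n)] = (ff - loss) / d
            tb[(i, n)] = (imp - exp) / d
    return ffb, tb


def oracle_flow_matrix(split_rows, trade, fine, categories, nutrient, channel,
                       included=None):
    """Category→category mass routing by explicit loops."""
    cells: dict[tuple[str, str], float] = defaultdict(float)
    if channel == "foreign_fishing":
        for r in split_rows:
            if r["zone"] == r["origin"]:
                continue
            src_nat, snk_nat = r["zone"], r["fleet"]
            if included is not None:
                if src_nat != HIGH_SEAS and src_nat not in included:
                    continue
                if snk_nat != FOC_POOL and snk_nat not in included:
                    continue
            src = HIGH_SEAS if src_nat == HIGH_SEAS else categories.get(src_nat, "ND")
            snk = FOC_POOL if snk_nat == FOC_POOL else categories.get(snk_nat, "ND")
            cells[(src, snk)] += r["tonnes"] * PORTIONS * r["conc"][nutrient]
    else:
        cache = {}
        for r in trade.to_dict("records"):
            if included is not None and (
                r["exporter"] not in included or r["importer"] not in included
            ):
                continue
            tid = r["taxon_id"]
            if tid in fine:
                conc = fine[tid]
            else:
                key = (tid, r["exporter"])
                if key not in cache:
                    cache[key] = coarse_concentration(
                        tid, r["exporter"], trade, "exporter", fine
                    )
                conc = cache[key]
            src = categories.get(r["exporter"], "ND")
            snk = categories.get(r["importer"], "ND")
            cells[(src, snk)] += r["tonnes"] * PORTIONS * conc[nutrient]
    return dict(cells)


def oracle_cv(values) -> float:
    m = sum(values) / len(values)
    if m == 0:
        return 0.0
    return statistics.stdev(values) / m


def oracle_shannon(masses) -> float:
    tot = sum(masses)
    if tot == 0:
        return 0.0
    return -sum(
        (m / tot) * math.log(m / tot) for m in masses if m > 0
    )


def oracle_spearman(x, y) -> float:
    """Rank-then-Pearson with midranks for ties."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den
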