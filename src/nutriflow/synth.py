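"""Synthetic world generation for the nutrient-distribution pipeline.

Real catch-reconstruction and seafood-trade databases are large, access
controlled, and unnecessary for validating the accounting logic.  This
module builds a closed, self-consistent world — nations, a high-seas zone,
a mixed-resolution taxonomy with per-100 g nutrient concentrations, a
40-year catch and trade history, and a national indicator table — whose
statistical shape mimics the real data (heavy-tailed tonnages, sparse
nation × taxon matrices, coarsely reported taxa, missing intake data) while
every conservation property holds exactly by construction.

Two entry points:

``generate_world(config)``
    A seeded, bit-reproducible world.

``generate_indicator_extremes(world)``
    The same world with two designated nations pushed to the boundary of
    the vulnerability framework: one attains the maximum of every exposure
    and sensitivity driver and the minimum of every adaptive-capacity
    driver, the other the reverse.  After min-max renormalization the pair
    must come out at vulnerability 1 and 0 exactly, which makes them a
    sharp end-to-end fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nutrients import CONC_COLUMNS, HIGH_SEAS, NUTRIENTS, PREV_COLUMNS


class ConfigError(ValueError):
    """Invalid world configuration; the message names the offending field."""


#: Log-scale location of each nutrient's concentration distribution across
#: species (per 100 g raw portion, native units).  Dispersions differ by
#: nutrient: protein is tightly conserved across finfish, calcium and
#: vitamin A vary over orders of magnitude.
_CONC_LOGNORM = {
    "protein": (np.log(19.0), 0.15),
    "calcium": (np.log(40.0), 1.0),
    "iron": (np.log(1.0), 0.8),
    "zinc": (np.log(0.8), 0.6),
    "selenium": (np.log(40.0), 0.6),
    "omega3": (np.log(0.5), 0.8),
    "vitamin_a": (np.log(30.0), 1.2),
}


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic world.

    Defaults give a mid-sized world: 40 nations, 120 finfish taxa, the
    1976–2015 period with 2015 as the focal analysis year, 70 % of catch
    records reported at species rank, and 10 % of global focal-year catch
    taken on the high seas by a third of nations.
    """

    n_nations: int = 40
    n_taxa: int = 120
    year_range: tuple[int, int] = (1976, 2015)
    focal_year: int = 2015
    frac_species_level: float = 0.7
    foc_heavy_nations: int = 4
    seed: int = 0
    # tonnage model: log-normal across (nation, taxon) cells, zeroed below
    # a sparsity threshold; the defaults leave roughly a fifth of cells
    # occupied with a heavy right tail, matching the sparse, skewed shape
    # of reported nation × taxon landings matrices
    tonnage_log_mu: float = np.log(10.0)
    tonnage_log_sigma: float = 2.0
    sparsity_threshold: float = 50.0
    foreign_scale: float = 0.3
    high_seas_share: float = 0.10
    hs_fishing_frac: float = 0.3
    # geometric random-walk step s.d. range; one value drawn per nation so
    # catch/trade volatility (and hence CV) differs across nations
    rw_sigma_range: tuple[float, float] = (0.05, 0.4)
    nd_frac: float = 0.10

    def validate(self) -> None:
        if self.n_nations < 3:
            raise ConfigError("n_nations must be >= 3")
        if self.n_taxa < 3:
            raise ConfigError("n_taxa must be >= 3")
        y0, y1 = self.year_range
        if y1 <= y0:
            raise ConfigError("year_range must span at least 2 years")
        if not (y0 <= self.focal_year <= y1):
            raise ConfigError("focal_year must lie within year_range")
        if not 0.0 <= self.frac_species_level <= 1.0:
            raise ConfigError("frac_species_level must be in [0, 1]")
        if not 0 <= self.foc_heavy_nations <= self.n_nations:
            raise ConfigError("foc_heavy_nations must be in [0, n_nations]")
        if not 0.0 <= self.high_seas_share < 1.0:
            raise ConfigError("high_seas_share must be in [0, 1)")
        if not 0.0 <= self.nd_frac < 1.0:
            raise ConfigError("nd_frac must be in [0, 1)")
        if self.sparsity_threshold < 0:
            raise ConfigError("sparsity_threshold must be >= 0")


@dataclass
class World:
    """A closed synthetic world of catch, trade, taxa, and indicators.

    ``catch`` rows: year, fishing_nation, source_zone, taxon_id, tonnes.
    ``trade`` rows: year, exporter, importer, taxon_id, tonnes — each row is
    one bilateral flow, so per-(year, taxon) export and import totals are
    identical by construction (closed trade matrix).
    """

    nations: list[str]
    catch: pd.DataFrame
    trade: pd.DataFrame
    taxa: pd.DataFrame
    foc: pd.DataFrame
    indicators: pd.DataFrame
    config: WorldConfig
    meta: dict = field(default_factory=dict)

    @property
    def focal_year(self) -> int:
        return self.config.focal_year

    def write_dir(self, path) -> None:
        """Write the canonical CSV schemas consumed by the pipeline."""
        import os

        os.makedirs(path, exist_ok=True)
        ff = "%.10g"
        self.catch.to_csv(os.path.join(path, "catch.csv"), index=False, float_format=ff)
        self.trade.to_csv(os.path.join(path, "trade.csv"), index=False, float_format=ff)
        self.taxa.to_csv(os.path.join(path, "taxa.csv"), index=False, float_format=ff)
        self.foc.to_csv(os.path.join(path, "foc.csv"), index=False, float_format=ff)
        self.indicators.to_csv(
            os.path.join(path, "indicators.csv"), index=False, float_format=ff
        )


def _make_taxa(rng: np.random.Generator, cfg: WorldConfig) -> pd.DataFrame:
    n = cfg.n_taxa
    n_sp = int(round(cfg.frac_species_level * n))
    n_rest = n - n_sp
    n_coarse = min(n_rest, max(1, int(round(0.1 * n_rest)))) if n_rest else 0
    n_gen = (n_rest - n_coarse) * 3 // 5
    n_fam_rank = n_rest - n_coarse - n_gen
    if n_sp == 0 and n_rest:
        # degenerate: no species-rank rows would leave nothing to impute
        # from; promote one row to species
        n_sp, n_coarse = 1, n_coarse - 1 if n_coarse else 0

    n_families = max(2, n_sp // 8) if n_sp else 2
    n_genera = max(n_families, n_sp // 3) if n_sp else n_families
    fam_names = [f"Fam{i:02d}" for i in range(n_families)]
    gen_fam = rng.integers(0, n_families, size=n_genera)
    gen_names = [f"Gen{i:03d}" for i in range(n_genera)]

    rows = []
    sp_gen = rng.integers(0, n_genera, size=n_sp)
    for i in range(n_sp):
        g = sp_gen[i]
        conc = {
            f"conc_{nut}": rng.lognormal(*_CONC_LOGNORM[nut]) for nut in NUTRIENTS
        }
        rows.append(
            {
                "taxon_id": f"T{i:04d}",
                "rank": "species",
                "species": f"Gen{g:03d} sp{i:04d}",
                "genus": gen_names[g],
                "family": fam_names[gen_fam[g]],
                **conc,
            }
        )
    used_genera = sorted(set(sp_gen.tolist())) or [0]
    used_families = sorted({int(gen_fam[g]) for g in used_genera})
    for j in range(n_gen):
        g = used_genera[int(rng.integers(0, len(used_genera)))]
        rows.append(
            {
                "taxon_id": f"T{n_sp + j:04d}",
                "rank": "genus",
                "species": "",
                "genus": gen_names[g],
                "family": fam_names[gen_fam[g]],
            }
        )
    for j in range(n_fam_rank):
        f = used_families[int(rng.integers(0, len(used_families)))]
        rows.append(
            {
                "taxon_id": f"T{n_sp + n_gen + j:04d}",
                "rank": "family",
                "species": "",
                "genus": "",
                "family": fam_names[f],
            }
        )
    for j in range(n_coarse):
        rows.append(
            {
                "taxon_id": f"T{n_sp + n_gen + n_fam_rank + j:04d}",
                "rank": "coarse",
                "species": "",
                "genus": "",
                "family": "",
            }
        )
    taxa = pd.DataFrame(rows)
    for c in CONC_COLUMNS:
        if c not in taxa.columns:
            taxa[c] = np.nan
    return taxa[["taxon_id", "rank", "species", "genus", "family", *CONC_COLUMNS]]


def _sparse_cells(
    rng: np.random.Generator,
    pairs: list[tuple[str, str]],
    taxa_ids: np.ndarray,
    mu: float,
    sigma: float,
    threshold: float,
) -> pd.DataFrame:
    """Log-normal tonnage over (channel pair × taxon) cells, zeroed below
    the sparsity threshold; returns only surviving cells."""
    n_pairs, n_tax = len(pairs), len(taxa_ids)
    vals = rng.lognormal(mu, sigma, size=(n_pairs, n_tax))
    vals[vals < threshold] = 0.0
    pi, ti = np.nonzero(vals)
    fishers = np.array([p[0] for p in pairs], dtype=object)
    zones = np.array([p[1] for p in pairs], dtype=object)
    return pd.DataFrame(
        {
            "fishing_nation": fishers[pi],
            "source_zone": zones[pi],
            "taxon_id": taxa_ids[ti],
            "base_tonnes": vals[pi, ti],
        }
    )


def _expand_series(
    rng: np.random.Generator,
    cells: pd.DataFrame,
    years: np.ndarray,
    focal_year: int,
    sigma_by_nation: dict[str, float],
    key_cols: tuple[str, str],
) -> pd.DataFrame:
    """Turn focal-year base cells into a full annual series via a geometric
    random walk per channel (unique key-column pair), anchored so the
    focal-year value equals the base tonnage."""
    chan = cells[list(key_cols)].drop_duplicates().reset_index(drop=True)
    n_chan, n_years = len(chan), len(years)
    sigmas = chan[key_cols[0]].map(sigma_by_nation).to_numpy(dtype=float)
    steps = rng.normal(0.0, 1.0, size=(n_chan, n_years)) * sigmas[:, None]
    walk = np.cumsum(steps, axis=1)
    focal_idx = int(np.where(years == focal_year)[0][0])
    walk -= walk[:, [focal_idx]]
    mult = np.exp(walk)
    chan = chan.assign(_chan=np.arange(n_chan))
    cells = cells.merge(chan, on=list(key_cols))
    ci = cells["_chan"].to_numpy()
    base = cells["base_tonnes"].to_numpy()
    tonnes = base[:, None] * mult[ci, :]
    n_cells = len(cells)
    data = {
        col: np.repeat(cells[col].to_numpy(), n_years)
        for col in cells.columns
        if col not in ("_chan", "base_tonnes")
    }
    data["year"] = np.tile(years, n_cells)
    data["tonnes"] = tonnes.ravel()
    return pd.DataFrame(data)


def _make_indicators(
    rng: np.random.Generator, nations: list[str], cfg: WorldConfig
) -> pd.DataFrame:
    n = len(nations)
    gdp = rng.lognormal(np.log(8000.0), 1.2, size=n)
    ind = pd.DataFrame(
        {
            "nation": nations,
            "population": rng.lognormal(np.log(5e6), 1.5, size=n),
            "fish_protein_share": 100.0 * rng.beta(1.5, 6.0, size=n),
            "gdp_pc": gdp,
            "stability": np.clip(rng.normal(0.0, 1.0, size=n), -2.5, 2.5),
            "health_exp": rng.uniform(2.0, 12.0, size=n),
            "net_food_importer": rng.integers(0, 2, size=n),
            "production_change": rng.uniform(-0.4, 0.15, size=n),
            "hdi": rng.uniform(0.35, 0.95, size=n),
            "inequality_coef": np.clip(
                55.0 - 5.0 * np.log(gdp) + rng.normal(0, 4, size=n), 2.0, 60.0
            ),
        }
    )
    for c in PREV_COLUMNS:
        ind[c] = 100.0 * rng.beta(1.2, 3.0, size=n)
    # dietary-energy adequacy, anticorrelated with micronutrient
    # inadequacy (used only by the redundancy-screen correlations)
    mean_prev = ind[list(PREV_COLUMNS)].mean(axis=1)
    ind["energy_adequacy"] = np.clip(
        120.0 - 0.8 * mean_prev + rng.normal(0, 4, size=n), 40.0, 135.0
    )
    # "ND" subset: no intake-prevalence data at all (exercises the ND
    # category downstream); indicator-complete otherwise
    n_nd = int(round(cfg.nd_frac * n))
    if n_nd:
        nd_idx = rng.choice(n, size=n_nd, replace=False)
        ind.loc[nd_idx, list(PREV_COLUMNS)] = np.nan
    return ind


def generate_world(config: WorldConfig) -> World:
    """Generate a seeded synthetic world; identical config ⇒ identical world."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nations = [f"N{i:03d}" for i in range(cfg.n_nations)]
    years = np.arange(cfg.year_range[0], cfg.year_range[1] + 1)

    taxa = _make_taxa(rng, cfg)
    taxa_ids = taxa["taxon_id"].to_numpy()

    sig_lo, sig_hi = cfg.rw_sigma_range
    sigma_by_nation = {
        nat: float(s)
        for nat, s in zip(nations, rng.uniform(sig_lo, sig_hi, size=cfg.n_nations))
    }

    # --- catch: domestic, foreign-EEZ, and high-seas channels -------------
    dom_pairs = [(nat, nat) for nat in nations]
    dom = _sparse_cells(
        rng, dom_pairs, taxa_ids, cfg.tonnage_log_mu, cfg.tonnage_log_sigma,
        cfg.sparsity_threshold,
    )

    f_pairs: list[tuple[str, str]] = []
    for i, nat in enumerate(nations):
        k = int(rng.poisson(2))
        if k == 0:
            continue
        others = [z for z in nations if z != nat]
        zones = rng.choice(len(others), size=min(k, len(others)), replace=False)
        f_pairs.extend((nat, others[z]) for z in zones)
    foreign = _sparse_cells(
        rng, f_pairs, taxa_ids,
        cfg.tonnage_log_mu + np.log(cfg.foreign_scale), cfg.tonnage_log_sigma,
        cfg.sparsity_threshold,
    ) if f_pairs else dom.iloc[0:0].copy()

    n_hs = max(1, int(round(cfg.hs_fishing_frac * cfg.n_nations)))
    hs_fishers = [nations[i] for i in rng.choice(cfg.n_nations, n_hs, replace=False)]
    hs = _sparse_cells(
        rng, [(nat, HIGH_SEAS) for nat in hs_fishers], taxa_ids,
        cfg.tonnage_log_mu + np.log(cfg.foreign_scale), cfg.tonnage_log_sigma,
        cfg.sparsity_threshold,
    )
    non_hs_total = dom["base_tonnes"].sum() + foreign["base_tonnes"].sum()
    if cfg.high_seas_share > 0 and len(hs) and hs["base_tonnes"].sum() > 0:
        target = cfg.high_seas_share / (1.0 - cfg.high_seas_share) * non_hs_total
        hs["base_tonnes"] *= target / hs["base_tonnes"].sum()
    else:
        hs = hs.iloc[0:0]

    cells = pd.concat([dom, foreign, hs], ignore_index=True)
    catch = _expand_series(
        rng, cells, years, cfg.focal_year, sigma_by_nation,
        ("fishing_nation", "source_zone"),
    )
    catch = catch[["year", "fishing_nation", "source_zone", "taxon_id", "tonnes"]]

    # --- trade: bilateral exporter→importer flows, closed by construction --
    t_rows = []
    for nat in nations:
        k = 1 + int(rng.poisson(5))
        others = [z for z in nations if z != nat]
        partners = rng.choice(len(others), size=min(k, len(others)), replace=False)
        for p in partners:
            m = 1 + int(rng.poisson(10))
            tx = rng.choice(len(taxa_ids), size=min(m, len(taxa_ids)), replace=False)
            for t in tx:
                t_rows.append((nat, others[p], taxa_ids[t]))
    t_cells = pd.DataFrame(t_rows, columns=["fishing_nation", "source_zone", "taxon_id"])
    t_cells["base_tonnes"] = rng.lognormal(
        cfg.tonnage_log_mu, cfg.tonnage_log_sigma, size=len(t_cells)
    )
    trade = _expand_series(
        rng, t_cells, years, cfg.focal_year, sigma_by_nation,
        ("fishing_nation", "source_zone"),
    ).rename(columns={"fishing_nation": "exporter", "source_zone": "importer"})
    trade = trade[["year", "exporter", "importer", "taxon_id", "tonnes"]]

    # --- flag-of-convenience registry -------------------------------------
    heavy_idx = set(
        rng.choice(cfg.n_nations, size=cfg.foc_heavy_nations, replace=False).tolist()
    )
    p13 = np.where(
        [i in heavy_idx for i in range(cfg.n_nations)],
        rng.uniform(0.4, 0.9, size=cfg.n_nations),
        rng.uniform(0.0, 0.08, size=cfg.n_nations),
    )
    p18 = np.clip(p13 + rng.normal(0.0, 0.05, size=cfg.n_nations), 0.0, 1.0)
    foc = pd.DataFrame({"nation": nations, "prop_foc_2013": p13, "prop_foc_2018": p18})

    indicators = _make_indicators(rng, nations, cfg)

    return World(
        nations=nations, catch=catch, trade=trade, taxa=taxa, foc=foc,
        indicators=indicators, config=cfg,
    )


def generate_indicator_extremes(world: World) -> World:
    """Push one nation to every worst-case driver and one to every best case.

    The "worst" nation is rebuilt so that its entire focal-year nutrient
    supply comes from a single foreign-fishing location and a single import
    partner (zero diversity), both with maximally spiky 40-year series
    (maximal coefficient of variation), with no domestic catch (domestic
    supply share zero), maximal fish dependence and inadequate-intake
    prevalence, and minimal wealth, stability, and health spending.  The
    "best" nation is purely domestic with a constant, uniform multi-species
    catch, zero fish dependence and prevalence, and maximal adaptive
    capacity.  Both have flag-of-convenience proportion 0.
    """
    if len(world.nations) < 2:
        raise ValueError("need at least 2 nations to designate extremes")
    worst, best = world.nations[0], world.nations[1]
    donor = world.nations[2] if len(world.nations) > 2 else best
    cfg = world.config
    years = np.arange(cfg.year_range[0], cfg.year_range[1] + 1)
    focal = cfg.focal_year

    catch = world.catch[world.catch["fishing_nation"] != worst]
    catch = catch[catch["fishing_nation"] != best]

    species_taxa = world.taxa.loc[world.taxa["rank"] == "species", "taxon_id"]
    spike_taxon = species_taxa.iloc[0]

    # worst: single foreign zone, all-but-one year negligible => CV ~ sqrt(n)
    spiky = np.where(years == focal, 1000.0, 1e-3)
    worst_rows = pd.DataFrame(
        {
            "year": years,
            "fishing_nation": worst,
            "source_zone": donor,
            "taxon_id": spike_taxon,
            "tonnes": spiky,
        }
    )
    # best: constant uniform catch over every species-rank taxon in its own
    # EEZ — maximal domestic species diversity, zero temporal variability
    n_sp = len(species_taxa)
    best_rows = pd.DataFrame(
        {
            "year": np.repeat(years, n_sp),
            "fishing_nation": best,
            "source_zone": best,
            "taxon_id": np.tile(species_taxa.to_numpy(), len(years)),
            "tonnes": 500.0 / n_sp,
        }
    )
    catch = pd.concat([catch, worst_rows, best_rows], ignore_index=True)

    trade = world.trade[
        ~world.trade["importer"].isin([worst, best])
        & ~world.trade["exporter"].isin([worst, best])
    ]
    worst_imp = pd.DataFrame(
        {
            "year": years,
            "exporter": donor,
            "importer": worst,
            "taxon_id": spike_taxon,
            "tonnes": spiky,
        }
    )
    trade = pd.concat([trade, worst_imp], ignore_index=True)

    ind = world.indicators.copy().set_index("nation")
    ind.loc[worst, list(PREV_COLUMNS)] = 100.0
    ind.loc[best, list(PREV_COLUMNS)] = 0.0
    ind.loc[worst, "fish_protein_share"] = 100.0
    ind.loc[best, "fish_protein_share"] = 0.0
    ind.loc[worst, "gdp_pc"] = 0.5 * ind["gdp_pc"].min()
    ind.loc[best, "gdp_pc"] = 2.0 * ind["gdp_pc"].max()
    ind.loc[worst, "stability"] = -3.0
    ind.loc[best, "stability"] = 3.0
    ind.loc[worst, "health_exp"] = 0.5
    ind.loc[best, "health_exp"] = 15.0
    ind.loc[worst, "net_food_importer"] = 1
    ind.loc[best, "net_food_importer"] = 0
    ind.loc[worst, "production_change"] = ind["production_change"].min() - 0.2
    ind.loc[best, "production_change"] = ind["production_change"].max() + 0.2
    ind = ind.reset_index()

    foc = world.foc.copy().set_index("nation")
    foc.loc[[worst, best], ["prop_foc_2013", "prop_foc_2018"]] = 0.0
    foc = foc.reset_index()

    return World(
        nations=list(world.nations),
        catch=catch.reset_index(drop=True),
        trade=trade.reset_index(drop=True),
        taxa=world.taxa.copy(),
        foc=foc,
        indicators=ind,
        config=replace(cfg),
        meta={**world.meta, "worst": worst, "best": best},
    )
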