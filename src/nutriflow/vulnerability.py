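"""Composite vulnerability of national fishery-derived nutrient supply.

The framework is

    Vulnerability = Exposure + Sensitivity − Adaptive capacity

with every sub-variable min-max normalized to [0, 1] across nations at
each stage, reversed where high raw values mean low exposure or high
adaptive capacity.

Exposure combines volatility (coefficient of variation of the 40-year
foreign-fishing and import tonnage series) and redundancy (Shannon
diversity of foreign-fishing locations and of import partners, computed
per nutrient on nutrient-mass shares and averaged over the seven
nutrients), each pair weighted by the share of the nation's
fishery-derived nutrient supply coming from foreign fishing (F_FF) and
imports (F_IMP).  The supply denominator is domestic + foreign-fished +
imported (exports excluded: losing exports would retain nutrients, not
remove them).  Sensitivity averages fish dependence (share of animal
protein from fish) and the mean prevalence of inadequate intake over 14
micronutrients (S_PIMII).  Adaptive capacity averages a socioeconomic
metric (GDP per capita and political stability), health expenditure, and
net-food-importer status (reversed: importing reduces capacity).

The climate extension adds a third weighted exposure component built from
the projected 2010–2050 change in domestic catch production (CpDC,
reversed: decline means exposure) and the species diversity of domestic
catch (DivDC, reversed), weighted by the domestic supply share F_DC.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .accounting import NutrientLedger
from .nutrients import FOC_POOL, HIGH_SEAS, NUTRIENTS, PREV_COLUMNS
from .synth import World

# ---------------------------------------------------------------------------
# primitive statistics


def coefficient_of_variation(series) -> float:
    """Sample (n−1) coefficient of variation; zero-mean series → 0.

    A nation with no catches in a channel has an all-zero series: the
    convention CV = 0 makes the absent channel contribute no exposure,
    consistent with its supply weight of zero.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 years to compute a CV")
    m = x.mean()
    if m == 0:
        return 0.0
    return float(x.std(ddof=1) / m)


def shannon_diversity(masses) -> float:
    """Shannon–Weaver index H = −Σ p ln p over positive mass shares, in nats."""
    x = np.asarray(masses, dtype=float)
    if (x < 0).any():
        raise ValueError("masses must be non-negative")
    total = x.sum()
    if total == 0:
        warnings.warn("all-zero mass vector; H = 0 by convention", stacklevel=2)
        return 0.0
    p = x[x > 0] / total
    p = p[p > 0]  # guard against underflow of extreme share ratios
    return float(-(p * np.log(p)).sum())


def minmax_normalize(values: pd.Series, reverse: bool = False) -> pd.Series:
    """Min-max scale to [0, 1] across nations; missing values stay missing.

    ``reverse`` returns 1 − scaled.  A constant vector normalizes to all
    zeros with a warning (degenerate convention).
    """
    v = pd.Series(values, dtype=float)
    if v.notna().sum() == 0:
        raise ValueError("cannot normalize an all-missing vector")
    lo, hi = v.min(), v.max()
    if hi == lo:
        warnings.warn("constant vector normalized to all zeros", stacklevel=2)
        out = v * 0.0
    else:
        out = (v - lo) / (hi - lo)
    return 1.0 - out if reverse else out


# ---------------------------------------------------------------------------
# sub-variable builders


def _annual_series(
    records: pd.DataFrame, by: str, years: np.ndarray, nations: list[str]
) -> pd.DataFrame:
    """Nation × year tonnage matrix, zero-filled for absent years."""
    g = records.groupby([by, "year"])["tonnes"].sum().unstack(fill_value=0.0)
    return g.reindex(index=nations, columns=years, fill_value=0.0).fillna(0.0)


def foreign_fishing_series(world: World, foc_adjusted: bool = True) -> pd.DataFrame:
    """Annual foreign-fishing tonnage per nation (other EEZs + high seas)."""
    c = world.catch
    ff = c[c["source_zone"] != c["fishing_nation"]].copy()
    if foc_adjusted:
        from .accounting import foc_proportions

        p = foc_proportions(world.foc)
        ff["tonnes"] = ff["tonnes"] * (
            1.0 - ff["fishing_nation"].map(p).fillna(0.0)
        )
    years = np.arange(world.config.year_range[0], world.config.year_range[1] + 1)
    return _annual_series(ff, "fishing_nation", years, world.nations)


def import_series(world: World) -> pd.DataFrame:
    """Annual imported tonnage per nation."""
    years = np.arange(world.config.year_range[0], world.config.year_range[1] + 1)
    return _annual_series(world.trade, "importer", years, world.nations)


def _mean_diversity(
    records: pd.DataFrame, owner_col: str, group_col: str, nations: list[str]
) -> pd.Series:
    """Shannon diversity over ``group_col`` per nutrient, averaged over the
    seven nutrients, for each nation in ``owner_col``.  Nations with no
    records score 0 (no portfolio, no redundancy)."""
    out = pd.Series(0.0, index=nations)
    if records.empty:
        return out
    for nat, sub in records.groupby(owner_col):
        if nat not in out.index:
            continue
        hs = []
        for n in NUTRIENTS:
            masses = sub.groupby(group_col)[f"mass_{n}"].sum()
            if masses.sum() > 0:
                hs.append(shannon_diversity(masses.to_numpy()))
            else:
                hs.append(0.0)
        out[nat] = float(np.mean(hs))
    return out


def diversity_foreign_fishing(ledger: NutrientLedger) -> pd.Series:
    """DivFF: location diversity of each nation's foreign-fishing nutrient catch."""
    c = ledger.catch_nutrients
    ff = c[
        (c["source_zone"] != c["fishing_nation"]) & (c["fishing_nation"] != FOC_POOL)
    ]
    return _mean_diversity(ff, "fishing_nation", "source_zone", ledger.nations)


def diversity_imports(ledger: NutrientLedger) -> pd.Series:
    """DivIMP: partner diversity of each nation's imported nutrient mass."""
    return _mean_diversity(
        ledger.trade_nutrients, "importer", "exporter", ledger.nations
    )


def diversity_domestic(ledger: NutrientLedger) -> pd.Series:
    """DivDC: species diversity of each nation's domestic nutrient catch."""
    c = ledger.catch_nutrients
    dom = c[(c["source_zone"] == c["fishing_nation"]) & (c["fishing_nation"] != FOC_POOL)]
    return _mean_diversity(dom, "fishing_nation", "taxon_id", ledger.nations)


def supply_weights(ledger: NutrientLedger) -> pd.DataFrame:
    """Supply shares (f_ff, f_imp, f_dc) of mean-across-nutrient RNI supply.

    Supply = domestic + foreign-fished + imported RNI-equivalents,
    averaged over the seven nutrients.  Shares sum to 1 for nations with
    positive supply and are all 0 otherwise.
    """
    dom = ledger.channel("domestic").mean(axis=1)
    ff = (ledger.channel("ff_eez") + ledger.channel("ff_hs")).mean(axis=1)
    imp = ledger.channel("imported").mean(axis=1)
    total = dom + ff + imp
    with np.errstate(invalid="ignore", divide="ignore"):
        out = pd.DataFrame(
            {
                "f_ff": np.where(total > 0, ff / total, 0.0),
                "f_imp": np.where(total > 0, imp / total, 0.0),
                "f_dc": np.where(total > 0, dom / total, 0.0),
            },
            index=total.index,
        )
    return out


# ---------------------------------------------------------------------------
# framework components


def exposure(
    cv_ff: pd.Series,
    div_ff: pd.Series,
    cv_imp: pd.Series,
    div_imp: pd.Series,
    weights: pd.DataFrame,
) -> pd.DataFrame:
    """Exposure component: E_FF, E_IMP, their weighted mean, normalized E."""
    e_ff = pd.concat(
        [minmax_normalize(cv_ff), minmax_normalize(div_ff, reverse=True)], axis=1
    ).mean(axis=1)
    e_imp = pd.concat(
        [minmax_normalize(cv_imp), minmax_normalize(div_imp, reverse=True)], axis=1
    ).mean(axis=1)
    raw = pd.concat(
        [weights["f_ff"] * e_ff, weights["f_imp"] * e_imp], axis=1
    ).mean(axis=1)
    return pd.DataFrame(
        {
            "e_ff": e_ff,
            "e_imp": e_imp,
            "exposure_raw": raw,
            "exposure": minmax_normalize(raw),
        }
    )


def sensitivity(indicators: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity: mean of normalized fish dependence and S_PIMII, renormalized."""
    ind = indicators.set_index("nation")
    prev_cols = [c for c in PREV_COLUMNS if c in ind.columns]
    if len(prev_cols) < len(PREV_COLUMNS):
        warnings.warn(
            f"S_PIMII computed over {len(prev_cols)} of "
            f"{len(PREV_COLUMNS)} micronutrients",
            stacklevel=2,
        )
    s_pimii = ind[prev_cols].mean(axis=1)
    s_fd = ind["fish_protein_share"]
    raw = pd.concat(
        [minmax_normalize(s_fd), minmax_normalize(s_pimii)], axis=1
    ).mean(axis=1)
    return pd.DataFrame(
        {
            "s_fd": s_fd,
            "s_pimii": s_pimii,
            "sensitivity_raw": raw,
            "sensitivity": minmax_normalize(raw),
        }
    )


def _importer_flag(values: pd.Series) -> pd.Series:
    """Binary net-food-importer status; a continuous food-trade balance is
    thresholded at 0 (negative balance ⇒ importer)."""
    v = pd.Series(values, dtype=float)
    if set(v.dropna().unique()) <= {0.0, 1.0}:
        return v
    return (v < 0).astype(float).where(v.notna())


def adaptive_capacity(indicators: pd.DataFrame) -> pd.DataFrame:
    """Adaptive capacity: socioeconomic status, health spending, importer status."""
    ind = indicators.set_index("nation")
    ac_se = pd.concat(
        [minmax_normalize(ind["gdp_pc"]), minmax_normalize(ind["stability"])], axis=1
    ).mean(axis=1)
    ac_he = minmax_normalize(ind["health_exp"])
    imp = _importer_flag(ind["net_food_importer"])
    # being a net importer reduces adaptive capacity: importer → 0
    ac_imp = 1.0 - imp
    raw = pd.concat([ac_se, ac_he, ac_imp], axis=1).mean(axis=1)
    return pd.DataFrame(
        {
            "ac_se": ac_se,
            "ac_he": ac_he,
            "ac_imp": ac_imp,
            "adaptive_capacity_raw": raw,
            "adaptive_capacity": minmax_normalize(raw),
        }
    )


def vulnerability(
    e: pd.Series, s: pd.Series, ac: pd.Series, renormalize: bool = True
) -> pd.DataFrame:
    """V = E + S − AC, raw in [−1, 2]; renormalized to [0, 1] across nations."""
    raw = e + s - ac
    out = pd.DataFrame({"v_raw": raw})
    out["vulnerability"] = minmax_normalize(raw) if renormalize else raw
    return out


def climate_exposure(
    production_change: pd.Series,
    div_dc: pd.Series,
    weights: pd.DataFrame,
    e_ff: pd.Series,
    e_imp: pd.Series,
) -> pd.DataFrame:
    """Climate-augmented exposure.

    E_CC core is the mean of reversed-normalized CpDC (a projected decline
    in domestic production means exposure) and reversed-normalized DivDC
    (a narrow domestic portfolio means exposure); the reported E_CC is the
    core weighted by the domestic supply share F_DC.  The augmented
    exposure renormalizes the mean of all three weighted components.
    """
    core = pd.concat(
        [
            minmax_normalize(production_change, reverse=True),
            minmax_normalize(div_dc, reverse=True),
        ],
        axis=1,
    ).mean(axis=1)
    e_cc = core * weights["f_dc"]
    raw = pd.concat(
        [
            weights["f_ff"] * e_ff,
            weights["f_imp"] * e_imp,
            weights["f_dc"] * core,
        ],
        axis=1,
    ).mean(axis=1)
    return pd.DataFrame(
        {
            "e_cc_core": core,
            "e_cc": e_cc,
            "exposure_climate_raw": raw,
            "exposure_climate": minmax_normalize(raw),
        }
    )


# ---------------------------------------------------------------------------
# orchestration


def compute_vulnerability_table(
    world: World, ledger: NutrientLedger, climate: bool = True
) -> pd.DataFrame:
    """Full vulnerability table: raw sub-variables, weights, components,
    V with and without the climate term, and a completeness flag."""
    ff_series = foreign_fishing_series(world, foc_adjusted=ledger.foc_mode)
    imp_series = import_series(world)
    cv_ff = ff_series.apply(lambda r: coefficient_of_variation(r.to_numpy()), axis=1)
    cv_imp = imp_series.apply(lambda r: coefficient_of_variation(r.to_numpy()), axis=1)
    div_ff = diversity_foreign_fishing(ledger)
    div_imp = diversity_imports(ledger)
    weights = supply_weights(ledger)

    exp = exposure(cv_ff, div_ff, cv_imp, div_imp, weights)
    sen = sensitivity(world.indicators)
    ac = adaptive_capacity(world.indicators)

    tbl = pd.concat(
        [
            pd.DataFrame(
                {"cv_ff": cv_ff, "div_ff": div_ff, "cv_imp": cv_imp,
                 "div_imp": div_imp}
            ),
            weights,
            exp,
            sen,
            ac,
        ],
        axis=1,
    )
    v = vulnerability(tbl["exposure"], tbl["sensitivity"], tbl["adaptive_capacity"])
    tbl = pd.concat([tbl, v], axis=1)

    if climate:
        ind = world.indicators.set_index("nation")
        div_dc = diversity_domestic(ledger)
        cexp = climate_exposure(
            ind["production_change"], div_dc, weights, tbl["e_ff"], tbl["e_imp"]
        )
        tbl = pd.concat([tbl, pd.DataFrame({"div_dc": div_dc}), cexp], axis=1)
        vc = vulnerability(
            tbl["exposure_climate"], tbl["sensitivity"], tbl["adaptive_capacity"]
        ).rename(
            columns={"v_raw": "v_raw_climate", "vulnerability": "vulnerability_climate"}
        )
        tbl = pd.concat([tbl, vc], axis=1)

    tbl["complete"] = tbl.notna().all(axis=1)
    tbl.index.name = "nation"
    return tbl.reset_index()


# ---------------------------------------------------------------------------
# correlation screens


def balance_correlations(
    balances: pd.DataFrame,
    indicators: pd.DataFrame,
    metrics: tuple[str, ...] = ("gdp_pc", "hdi", "inequality_coef"),
) -> pd.DataFrame:
    """Spearman ρ between each balance (type × nutrient) and each
    socioeconomic metric, pairwise-complete; fewer than 3 complete pairs
    reports a missing ρ with a warning."""
    ind = indicators.set_index("nation")
    rows = []
    for nutrient, sub in balances.groupby("nutrient", observed=True):
        sub = sub.set_index("nation")
        for btype in ("ffb", "tb"):
            for metric in metrics:
                x = sub[btype]
                y = ind[metric].reindex(x.index)
                ok = x.notna() & y.notna()
                if ok.sum() < 3:
                    warnings.warn(
                        f"<3 complete pairs for {btype}/{nutrient}/{metric}",
                        stacklevel=2,
                    )
                    rho, p = np.nan, np.nan
                else:
                    rho, p = stats.spearmanr(x[ok], y[ok])
                rows.append((btype, str(nutrient), metric, rho, p, int(ok.sum())))
    return pd.DataFrame(
        rows, columns=["balance", "nutrient", "metric", "rho", "p_value", "n"]
    )


def screen_correlations(indicators: pd.DataFrame) -> pd.DataFrame:
    """Redundancy screen between candidate framework drivers.

    Reports Spearman ρ between S_PIMII and dietary-energy adequacy, and
    between GDP per capita and the coefficient of human inequality — the
    pairs used to decide whether a candidate variable is redundant with an
    included one.
    """
    ind = indicators.set_index("nation")
    prev_cols = [c for c in PREV_COLUMNS if c in ind.columns]
    s_pimii = ind[prev_cols].mean(axis=1)
    pairs = []
    if "energy_adequacy" in ind.columns:
        pairs.append(("s_pimii", "energy_adequacy", s_pimii, ind["energy_adequacy"]))
    if "inequality_coef" in ind.columns:
        pairs.append(("gdp_pc", "inequality_coef", ind["gdp_pc"], ind["inequality_coef"]))
    rows = []
    for xname, yname, x, y in pairs:
        ok = x.notna() & y.notna()
        rho, p = (np.nan, np.nan) if ok.sum() < 3 else stats.spearmanr(x[ok], y[ok])
        rows.append((xname, yname, rho, p, int(ok.sum())))
    return pd.DataFrame(rows, columns=["x", "y", "rho", "p_value", "n"])
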