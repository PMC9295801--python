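"""Vulnerability framework: primitives, components, and the full index."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nutriflow as nf
from nutriflow.vulnerability import (
    adaptive_capacity,
    climate_exposure,
    diversity_domestic,
    diversity_foreign_fishing,
    diversity_imports,
    exposure,
    foreign_fishing_series,
    import_series,
    screen_correlations,
    sensitivity,
    vulnerability,
)

from _oracles import oracle_cv, oracle_ledger, oracle_shannon, oracle_spearman


class TestCoefficientOfVariation:
    def test_constant_series_is_zero(self):
        assert nf.coefficient_of_variation([10, 10, 10]) == 0.0

    def test_two_point_series(self):
        # sd([0, 20]) = 14.142 (n−1), mean = 10
        assert nf.coefficient_of_variation([0, 20]) == pytest.approx(
            math.sqrt(2), rel=1e-6
        )

    def test_all_zero_series_convention(self):
        assert nf.coefficient_of_variation([0, 0, 0]) == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            nf.coefficient_of_variation([1.0])


class TestShannonDiversity:
    def test_uniform_is_log_k(self):
        assert nf.shannon_diversity([1, 1, 1, 1]) == pytest.approx(math.log(4))

    def test_single_location_is_zero(self):
        assert nf.shannon_diversity([7.0]) == 0.0

    def test_direct_evaluation(self):
        h = nf.shannon_diversity([0.5, 0.25, 0.25])
        assert h == pytest.approx(1.03972, abs=1e-5)

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            assert nf.shannon_diversity([0.0, 0.0]) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        masses=st.lists(
            st.floats(min_value=0.0, max_value=1e6), min_size=1, max_size=12
        ).filter(lambda v: sum(v) > 0)
    )
    def test_bounded_by_log_k(self, masses):
        h = nf.shannon_diversity(masses)
        assert -1e-9 <= h <= math.log(len(masses)) + 1e-9


class TestMinmaxNormalize:
    def test_scaling(self):
        out = nf.minmax_normalize(pd.Series([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])

    def test_reversed(self):
        out = nf.minmax_normalize(pd.Series([2.0, 4.0, 6.0]), reverse=True)
        np.testing.assert_allclose(out, [1.0, 0.5, 0.0])

    def test_constant_vector_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = nf.minmax_normalize(pd.Series([5.0, 5.0, 5.0]))
        np.testing.assert_allclose(out, [0.0, 0.0, 0.0])

    def test_missing_stays_missing(self):
        out = nf.minmax_normalize(pd.Series([1.0, np.nan, 3.0]))
        assert np.isnan(out.iloc[1])
        np.testing.assert_allclose(out.dropna(), [0.0, 1.0])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            nf.minmax_normalize(pd.Series([np.nan, np.nan]))


class TestSupplyWeights:
    def test_shares_from_channels(self, small_ledger):
        w = nf.supply_weights(small_ledger)
        dom = small_ledger.channel("domestic").mean(axis=1)
        ff = (
            small_ledger.channel("ff_eez") + small_ledger.channel("ff_hs")
        ).mean(axis=1)
        imp = small_ledger.channel("imported").mean(axis=1)
        total = dom + ff + imp
        np.testing.assert_allclose(w["f_ff"], ff / total, rtol=1e-12)
        np.testing.assert_allclose(w["f_dc"], dom / total, rtol=1e-12)

    def test_weight_closure(self, small_ledger):
        w = nf.supply_weights(small_ledger)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, rtol=1e-12)
        assert ((w >= 0) & (w <= 1)).all().all()


class TestComponents:
    def _toy_indicators(self):
        from nutriflow.nutrients import PREV_COLUMNS

        ind = pd.DataFrame(
            {
                "nation": ["A", "B", "C"],
                "fish_protein_share": [60.0, 5.0, 20.0],
                "gdp_pc": [500.0, 60000.0, 9000.0],
                "stability": [-2.0, 2.0, 0.0],
                "health_exp": [1.0, 11.0, 6.0],
                "net_food_importer": [1, 0, 1],
            }
        )
        for i, c in enumerate(PREV_COLUMNS):
            ind[c] = [80.0, 2.0, 30.0]
        return ind

    def test_sensitivity_extremes(self):
        s = sensitivity(self._toy_indicators())
        assert s.loc["A", "sensitivity"] == 1.0
        assert s.loc["B", "sensitivity"] == 0.0

    def test_adaptive_capacity_extremes(self):
        ac = adaptive_capacity(self._toy_indicators())
        assert ac.loc["B", "adaptive_capacity"] == 1.0
        assert ac.loc["A", "adaptive_capacity"] == 0.0

    def test_importer_status_reversed(self):
        ac = adaptive_capacity(self._toy_indicators())
        assert ac.loc["B", "ac_imp"] == 1.0
        assert ac.loc["A", "ac_imp"] == 0.0

    def test_continuous_food_balance_thresholded(self):
        ind = self._toy_indicators()
        ind["net_food_importer"] = [-5.0, 3.0, -0.5]  # negative ⇒ importer
        ac = adaptive_capacity(ind)
        assert ac.loc["A", "ac_imp"] == 0.0
        assert ac.loc["B", "ac_imp"] == 1.0

    def test_exposure_weighted_extremes(self):
        idx = ["A", "B", "C"]
        cv_ff = pd.Series([5.0, 1.0, 0.0], index=idx)
        div_ff = pd.Series([0.0, 1.0, 2.0], index=idx)
        cv_imp = pd.Series([4.0, 0.5, 0.0], index=idx)
        div_imp = pd.Series([0.0, 0.5, 1.5], index=idx)
        weights = pd.DataFrame(
            {"f_ff": [0.5, 0.2, 0.0], "f_imp": [0.5, 0.2, 0.0],
             "f_dc": [0.0, 0.6, 1.0]},
            index=idx,
        )
        e = exposure(cv_ff, div_ff, cv_imp, div_imp, weights)
        assert e.loc["A", "e_ff"] == 1.0
        assert e.loc["A", "exposure"] == 1.0
        # no foreign supply at all ⇒ weighted components zero ⇒ minimal E
        assert e.loc["C", "exposure"] == 0.0

    def test_vulnerability_arithmetic(self):
        idx = ["A", "B", "C"]
        v = vulnerability(
            pd.Series([1.0, 0.0, 0.5], index=idx),
            pd.Series([1.0, 0.0, 0.5], index=idx),
            pd.Series([0.0, 1.0, 0.5], index=idx),
        )
        np.testing.assert_allclose(v["v_raw"], [2.0, -1.0, 0.5])
        np.testing.assert_allclose(v["vulnerability"], [1.0, 0.0, 0.5])

    def test_climate_exposure_weighting(self):
        idx = ["A", "B"]
        weights = pd.DataFrame(
            {"f_ff": [0.0, 0.5], "f_imp": [0.0, 0.5], "f_dc": [1.0, 0.0]},
            index=idx,
        )
        ce = climate_exposure(
            production_change=pd.Series([-0.5, 0.2], index=idx),
            div_dc=pd.Series([0.0, 2.0], index=idx),
            weights=weights,
            e_ff=pd.Series([0.0, 1.0], index=idx),
            e_imp=pd.Series([0.0, 1.0], index=idx),
        )
        # worst decline + single-species domestic catch + all-domestic supply
        assert ce.loc["A", "e_cc"] == 1.0
        # no domestic catch ⇒ E_CC = 0
        assert ce.loc["B", "e_cc"] == 0.0


class TestSubvariablesAgainstOracle:
    def test_cv_series_match(self, oracle_world):
        ff = foreign_fishing_series(oracle_world, foc_adjusted=False)
        imp = import_series(oracle_world)
        c = oracle_world.catch
        t = oracle_world.trade
        years = list(
            range(oracle_world.config.year_range[0],
                  oracle_world.config.year_range[1] + 1)
        )
        for nat in oracle_world.nations:
            rows = c[(c["fishing_nation"] == nat)
                     & (c["source_zone"] != nat)]
            series = [
                rows.loc[rows["year"] == y, "tonnes"].sum() for y in years
            ]
            assert nf.coefficient_of_variation(
                ff.loc[nat].to_numpy()
            ) == pytest.approx(oracle_cv(series), rel=1e-9, abs=1e-12)
            irows = t[t["importer"] == nat]
            iseries = [
                irows.loc[irows["year"] == y, "tonnes"].sum() for y in years
            ]
            assert nf.coefficient_of_variation(
                imp.loc[nat].to_numpy()
            ) == pytest.approx(oracle_cv(iseries), rel=1e-9, abs=1e-12)

    def test_diversities_match(self, oracle_world):
        conc = nf.resolve_all(
            oracle_world.taxa, oracle_world.catch,
            focal_year=oracle_world.focal_year,
        )
        ledger = nf.build_ledger(oracle_world, conc, foc_mode=True)
        _, split_rows = oracle_ledger(oracle_world, ledger.rni, True)
        div_ff = diversity_foreign_fishing(ledger)
        div_dc = diversity_domestic(ledger)
        from collections import defaultdict

        from nutriflow.nutrients import FOC_POOL, NUTRIENTS

        for nat in oracle_world.nations:
            hs_ff, hs_dc = [], []
            for n in NUTRIENTS:
                by_zone = defaultdict(float)
                by_taxon = defaultdict(float)
                for r in split_rows:
                    if r["fleet"] != nat or r["fleet"] == FOC_POOL:
                        continue
                    m = r["tonnes"] * 1e4 * r["conc"][n]
                    if r["zone"] != nat:
                        by_zone[r["zone"]] += m
                    else:
                        by_taxon[r["taxon"]] += m
                hs_ff.append(oracle_shannon(list(by_zone.values())))
                hs_dc.append(oracle_shannon(list(by_taxon.values())))
            assert div_ff[nat] == pytest.approx(np.mean(hs_ff), rel=1e-9, abs=1e-12)
            assert div_dc[nat] == pytest.approx(np.mean(hs_dc), rel=1e-9, abs=1e-12)

    def test_supply_weights_match(self, oracle_world):
        conc = nf.resolve_all(
            oracle_world.taxa, oracle_world.catch,
            focal_year=oracle_world.focal_year,
        )
        ledger = nf.build_ledger(oracle_world, conc, foc_mode=True)
        masses, _ = oracle_ledger(oracle_world, ledger.rni, True)
        from nutriflow.nutrients import NUTRIENTS

        w = nf.supply_weights(ledger)
        for nat in oracle_world.nations:
            dom = np.mean(
                [masses.get((nat, n, "domestic"), 0.0) / (ledger.rni[n] * 365)
                 for n in NUTRIENTS]
            )
            ff = np.mean(
                [(masses.get((nat, n, "ff_eez"), 0.0)
                  + masses.get((nat, n, "ff_hs"), 0.0)) / (ledger.rni[n] * 365)
                 for n in NUTRIENTS]
            )
            imp = np.mean(
                [masses.get((nat, n, "imported"), 0.0) / (ledger.rni[n] * 365)
                 for n in NUTRIENTS]
            )
            total = dom + ff + imp
            assert w.loc[nat, "f_dc"] == pytest.approx(dom / total, rel=1e-9)
            assert w.loc[nat, "f_ff"] == pytest.approx(ff / total, rel=1e-9)
            assert w.loc[nat, "f_imp"] == pytest.approx(imp / total, rel=1e-9)


class TestFullTable:
    def test_bounds(self, small_world, small_ledger):
        tbl = nf.compute_vulnerability_table(small_world, small_ledger)
        for col in ("exposure", "sensitivity", "adaptive_capacity",
                    "vulnerability", "exposure_climate",
                    "vulnerability_climate"):
            assert tbl[col].between(-1e-12, 1 + 1e-12).all()
        assert tbl["v_raw"].between(-1 - 1e-12, 2 + 1e-12).all()

    def test_extreme_fixture_recovery(self, extreme_world):
        conc = nf.resolve_all(
            extreme_world.taxa, extreme_world.catch,
            focal_year=extreme_world.focal_year,
        )
        ledger = nf.build_ledger(extreme_world, conc, foc_mode=True)
        tbl = nf.compute_vulnerability_table(extreme_world, ledger).set_index(
            "nation"
        )
        worst, best = extreme_world.meta["worst"], extreme_world.meta["best"]
        assert tbl.loc[worst, "vulnerability"] == pytest.approx(1.0)
        assert tbl.loc[best, "vulnerability"] == pytest.approx(0.0)
        assert tbl.loc[worst, "vulnerability_climate"] == pytest.approx(1.0)
        assert tbl.loc[best, "vulnerability_climate"] == pytest.approx(0.0)
        # zero domestic share ⇒ the climate term adds nothing for that nation
        assert tbl.loc[worst, "f_dc"] == 0.0
        assert tbl.loc[worst, "vulnerability_climate"] == pytest.approx(
            tbl.loc[worst, "vulnerability"]
        )


class TestCorrelations:
    def test_monotone_relationship_is_plus_one(self, small_ledger, small_world):
        bt = nf.balance_table(small_ledger)
        ind = small_world.indicators.copy()
        mean = bt[bt["nutrient"] == "mean"].set_index("nation")
        ind["gdp_pc"] = ind["nation"].map(mean["tb"].rank())
        out = nf.balance_correlations(bt, ind, metrics=("gdp_pc",))
        row = out[(out["balance"] == "tb") & (out["nutrient"] == "mean")]
        assert row["rho"].iloc[0] == pytest.approx(1.0)

    def test_reversed_relationship_is_minus_one(self, small_ledger, small_world):
        bt = nf.balance_table(small_ledger)
        ind = small_world.indicators.copy()
        mean = bt[bt["nutrient"] == "mean"].set_index("nation")
        ind["gdp_pc"] = -ind["nation"].map(mean["tb"].rank())
        out = nf.balance_correlations(bt, ind, metrics=("gdp_pc",))
        row = out[(out["balance"] == "tb") & (out["nutrient"] == "mean")]
        assert row["rho"].iloc[0] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 4.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 5.0]
        from scipy import stats

        rho, _ = stats.spearmanr(x, y)
        assert rho == pytest.approx(oracle_spearman(x, y), rel=1e-12)

    def test_screen_reports_both_pairs(self, small_world):
        out = screen_correlations(small_world.indicators)
        assert set(zip(out["x"], out["y"])) == {
            ("s_pimii", "energy_adequacy"),
            ("gdp_pc", "inequality_coef"),
        }
        assert out["rho"].notna().all()
        # adequacy is built to oppose inadequate intake
        assert out.loc[out["x"] == "s_pimii", "rho"].iloc[0] < 0
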