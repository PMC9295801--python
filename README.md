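# nutriflow

Accounting for who gets the nutrients in global marine fisheries.

Marine finfish are a dense, bioavailable source of protein, calcium, iron,
zinc, selenium, long-chain omega-3 fatty acids, and vitamin A. But fish are
rarely eaten where they are caught: foreign fleets harvest other nations'
exclusive economic zones (EEZs) and the high seas, and international trade
moves catch again after landing. `nutriflow` converts catch and trade
records into **nutrient masses** and **RNI-equivalents** — the number of
reproductive-age females whose daily recommended nutrient intake (RNI) a
mass could theoretically cover over a year — and asks, for every nation:
does the international distribution system deliver nutrients toward or away
from it, and how fragile is that supply?

It is written for food-systems and fisheries researchers who want a tested,
fully synthetic-data-driven reimplementation of this accounting: every
stage runs against a seeded generated world with known ground truth, so no
access to the large proprietary catch/trade databases is needed.

## The quantities

For nation *i* and nutrient *n*, all in RNI-equivalents:

- **Foreign-fishing balance** `FFB_in = FF_in − LossFF_in`, where `FF` is
  nation *i*'s fleet fishing other EEZs and (optionally) the high seas, and
  `LossFF` is extraction from *i*'s own EEZ by other fleets.
- **Trade balance** `TB_in = IMP_in − EXP_in`; positive means net importer.
- **Flag-of-convenience (FOC) adjustment**: each nation's catch is scaled
  by `1 − p`, with `p` its registered FOC vessel share (mean of the 2013
  and 2018 registry columns); the `p` share moves to an unattributed FOC
  pool, never to beneficial-owner nations.
- **Flow matrices** route focal-year masses of calcium, iron, zinc and
  vitamin A between national categories of inadequate-intake prevalence
  (V.Lo ≤ 5 % < Lo ≤ 10 % < Med ≤ 25 % < Hi ≤ 50 % < V.Hi, ND when no
  data), from source-EEZ category (or HS) to fleet category (or FOC), and
  exporter to importer.
- **Vulnerability** `V = E + S − AC`: exposure from supply volatility
  (40-year coefficients of variation) and portfolio redundancy (Shannon
  diversity of fishing locations and import partners), weighted by supply
  shares `F_FF`, `F_IMP`; sensitivity from fish dependence and the mean
  inadequate-intake prevalence over 14 micronutrients; adaptive capacity
  from GDP per capita, political stability, health expenditure, and
  net-food-importer status. Every variable is min-max normalized across
  nations at each stage. A climate variant adds a third exposure component
  from projected 2010–2050 domestic-production change and domestic catch
  diversity, weighted by the domestic share `F_DC`.

## Worked example

```python
import nutriflow as nf

cfg = nf.WorldConfig(n_nations=12, n_taxa=60, seed=7)
world = nf.generate_world(cfg)
conc = nf.resolve_all(world.taxa, world.catch, focal_year=world.focal_year)
ledger = nf.build_ledger(world, conc, foc_mode=True)

balances = nf.balance_table(ledger, include_high_seas=True)
mean = balances[balances["nutrient"] == "mean"].set_index("nation")
print(mean[["ffb", "tb"]].round(0).head(4))
```

```
            ffb       tb
nation
N000   -38252.0 -59697.0
N001     5150.0  -5110.0
N002    -3711.0  66344.0
N003   -25405.0  -6373.0
```

Nation `N000` loses the equivalent of ~38,000 women's annual RNIs (averaged
across the seven nutrients) to foreign fleets fishing its EEZ, and a
further ~60,000 through net exports. `nf.classify_nation(-25405, -6373)`
returns `("loss_both", "negative")` — the bottom-left quadrant of a
gain/loss scatter.

```python
vuln = nf.compute_vulnerability_table(world, ledger).set_index("nation")
print(vuln[["exposure", "sensitivity", "adaptive_capacity", "vulnerability"]]
      .round(3).head(4))
```

```
        exposure  sensitivity  adaptive_capacity  vulnerability
nation
N000       0.254        0.470              0.630          0.289
N001       0.210        0.703              1.000          0.168
N002       0.716        0.661              0.254          0.972
N003       0.162        0.437              0.750          0.126
```

`N002` is close to the top of the vulnerability scale: highly exposed
(volatile, concentrated foreign supply), sensitive, and with little
adaptive capacity.

The same run is available from a shell:

```sh
nutriflow run-all --seed 7 --out out/
nutriflow balances --seed 7 --no-high-seas --foc --out out/
```

`run-all` writes every table (ledger, balances, classification, flow and
yield tables, vulnerability, correlations) plus `manifest.json` with the
config hash and per-file digests; a rerun under the same manifest is
byte-identical.

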