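# Methods

This note documents the model choices behind `nutriflow`: the accounting
conventions, the vulnerability framework, the synthetic world that the
package is validated against, and the numerical edge-case rules. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Nutrient accounting

**Units.** Concentrations are per 100 g of raw fish in each nutrient's
native unit (protein and omega-3 in g, calcium/iron/zinc in mg,
selenium and vitamin A in mcg). One tonne contains 10⁴ hundred-gram
portions, so `mass = tonnes × 10⁴ × concentration`. No edible-portion
conversion is applied: conversion factors are inconsistent and missing for
most taxa, so all masses refer to whole reported landings, and comparisons
are only meaningful in relative terms.

**RNI-equivalents.** Masses are compared across nutrients as the number
of reproductive-age females whose recommended intake the mass covers:
`persons = annual_mass / (rni_per_day × 365)`. A 365-day year is used
throughout; this convention (rather than a per-day framing) is fixed here
because the two differ only by the constant 365 and cancel in every
balance and share. The RNI table is a configuration input; the defaults in
`nutriflow.accounting.DEFAULT_RNI` are realistic magnitudes (e.g. calcium
1000 mg/d, zinc 4.9 mg/d) used by the synthetic world, and any real
analysis should supply its own table.

**Channels.** Focal-year records partition into: domestic (own fleet, own
EEZ), `ff_eez` and `ff_hs` (own fleet abroad / high seas), `loss_ff`
(other fleets in the nation's EEZ), `imported`/`exported`, and `foc_pool`.

**Flag-of-convenience adjustment.** Each nation's catch is split
`(1 − p)` retained / `p` pooled, with `p` the mean of the 2013 and 2018
registry proportions. Pool catch belongs to the pseudo-nation `FOC` and is
never reassigned: beneficial ownership is unobservable. Two consequences
are deliberate:

- `LossFF` is computed from the *originally reported* flag. A FOC vessel
  flagged to nation *i* fishing *i*'s own EEZ is not another country's
  fleet, so the loss channel is invariant to the FOC toggle; only `FF`
  shrinks. This preserves the monotonicity `FFB(foc on) ≤ FFB(foc off)`
  wherever `p > 0` and foreign catch is positive.
- Conservation then takes the form: with FOC off, EEZ-only FFB sums to
  zero over nations; with FOC on, the system-wide deficit equals exactly
  the nutrient mass pooled from foreign-EEZ FOC catch (asserted at 1e-9
  relative tolerance in the tests).

**Balances and classification.** `FFB = FF − LossFF` (high seas included
or not by toggle), `TB = IMP − EXP`. "Averaged across nutrients" is the
unweighted arithmetic mean of the seven per-nutrient RNI balances. Sign
ties at exactly zero classify as gains; this tie rule is arbitrary,
documented, and isolated in `classify_nation`.

## Concentration imputation

Species-rank taxa carry their own seven concentrations. Genus- and
family-rank taxa take the unweighted arithmetic mean over species-rank
members of the same genus/family ("averages" without weights). Taxa
reported below family ("marine finfishes") resolve by a four-tier ladder:

1. direct table entry;
2. catch-tonnage-weighted mean over resolvable taxa reported from the
   same zone (same trading nation for trade records);
3. tonnage-weighted mean over resolvable taxa globally;
4. unweighted mean over all species-rank rows.

The ladder is this package's reconstruction of the local-composition
principle — what is actually being landed nearby is the best guess for an
unidentified ton of finfish — not a verbatim transcription of any external
rule set; the tier used per (taxon, context) is recorded in the ledger's
`tier_audit` so monotonicity (a lower tier is never skipped) is testable.

## Vulnerability framework

`V = E + S − AC`, all components min-max normalized across nations at
each aggregation stage, reversed where high raw values imply low exposure
or high capacity.

- **Exposure.** `E_FF = mean(norm CvFF, 1 − norm DivFF)`; likewise
  `E_IMP`. CV uses the sample (n−1) standard deviation over the 40-year
  tonnage series. Diversity is the Shannon–Weaver index `H = −Σ p ln p`
  computed per nutrient on nutrient-mass shares and averaged across the
  seven nutrients; the across-nutrient average is taken on raw `H`, then
  normalized, then reversed (the alternative order — reverse before
  averaging — differs only by an affine map and was fixed this way once).
  `E = norm(mean(F_FF·E_FF, F_IMP·E_IMP))`.
- **Supply weights.** `F_FF`, `F_IMP`, `F_DC` are shares of the
  mean-across-nutrients RNI supply `domestic + foreign-fished + imported`.
  Exports are excluded from the denominator: losing an export market
  retains nutrients domestically rather than removing them. The
  FOC-adjusted channels feed these weights.
- **Sensitivity.** `S = norm(mean(norm S_FD, norm S_PIMII))`; `S_PIMII` is
  the unweighted mean inadequate-intake prevalence over 14 micronutrients.
  If prevalence columns are missing the mean is over available columns
  with a warning.
- **Adaptive capacity.** `AC_SE = mean(norm GDPpc, norm stability)`;
  `AC = norm(mean(AC_SE, norm health_exp, importer reversed))`. Importer
  status is binary (importer → 0 capacity before averaging); a continuous
  food-trade-balance column is accepted and thresholded at zero.
- **Climate extension.** `E_CC core = mean(1 − norm CpDC, 1 − norm DivDC)`
  (a projected production decline and a narrow domestic portfolio both
  mean exposure); the reported `E_CC = core × F_DC`, and the augmented
  exposure renormalizes `mean(F_FF·E_FF, F_IMP·E_IMP, F_DC·core)` — the
  third component enters by the same unweighted-mean composition as the
  first two.
- **Final index.** `V_raw = E + S − AC ∈ [−1, 2]` is emitted alongside
  the min-max renormalized `V ∈ [0, 1]`; plots and thresholds (e.g. a 0.5
  reference) presume the unit scale, analyses of raw spread can use
  `v_raw`.

**A note on the climate/no-climate identity.** For a nation with
`F_DC = 0`, the three-component exposure mean is exactly ⅔ of the
two-component mean. After min-max normalization the two exposures (and
hence the two vulnerabilities) coincide for such a nation *provided* the
nations anchoring the normalization extremes also scale consistently —
which holds when the maximum-exposure nation has `F_DC = 0` and the
minimum has zero raw exposure in both variants. The extreme fixture
(below) is constructed to satisfy exactly this, making the identity an
exact test rather than an approximation.

**Missing data.** Parent metrics are means of available normalized
children; no cross-nation imputation is performed, and each nation carries
a completeness flag in the output table.

**Degenerate inputs.** CV of an all-zero (or zero-mean) series is 0 — an
absent channel contributes no exposure, consistent with its zero supply
weight. Shannon H of an all-zero vector is 0 with a warning. A constant
vector min-max normalizes to all zeros with a warning. All-missing vectors
are an error.

## The synthetic world

The generator emulates the *shape* of the real inputs, not their values:

- **Tonnage.** Log-normal across (nation, taxon) cells (default median
  10 t, log-sd 2), zeroed below a 50 t sparsity threshold — roughly a
  fifth of cells occupied, with a heavy right tail, matching the sparse
  skewed structure of reported landings matrices. Foreign-EEZ and
  high-seas channels use a 0.3× scale; the high-seas zone receives 10 % of
  global focal-year catch, fished by a third of nations.
- **Time series.** Each (fleet, zone) channel follows a geometric random
  walk over 1976–2015 anchored at the 2015 focal year, with per-nation
  step dispersion drawn from [0.05, 0.4] so CV varies across nations.
- **Trade.** Bilateral exporter→importer records; closure (every export is
  someone's import) holds identically because each record carries both
  parties. Partner counts and per-pair taxon counts are Poisson
  (means 5 and 10), sized so total traded volume is of the same order as
  foreign-fished volume.
- **Taxonomy.** A configurable fraction of taxa (default 70 %) is
  species-rank with complete concentrations; the rest are genus-, family-,
  and coarse-rank to exercise imputation and the tier ladder.
  Concentrations are log-normal per nutrient with nutrient-specific
  dispersions (protein tight, calcium and vitamin A spanning orders of
  magnitude).
- **Indicators.** Prevalences are Beta-distributed; 10 % of nations are an
  "ND" subset with no intake data. Dietary-energy adequacy is generated
  anticorrelated with mean micronutrient inadequacy, and the inequality
  coefficient anticorrelated with log GDP, so the redundancy screens
  (Spearman between S_PIMII and energy adequacy, GDP and inequality)
  detect the strong associations they exist to detect; their values on
  synthetic data are reported, not asserted.

**What it does not emulate** — and hence what passing tests do not show
about real data: true taxonomic composition and nutrient values,
processing/re-export chains (circular trade), illegal/unreported catch and
discards, transshipment, prices, aquaculture, and within-country
distribution. The generator validates the *accounting*, not the world's
empirical magnitudes.

**Extreme fixture.** `generate_indicator_extremes` rebuilds one nation at
every worst-case driver (single foreign-fishing location and import
partner with maximally spiky series — the one-spike series attains the
maximal CV √(n−1) possible for a nonnegative series — no domestic catch,
maximal fish dependence and prevalence, minimal wealth/stability/health
spending, net importer) and one at every best case (purely domestic,
constant uniform catch over all species, maximal capacity). After
renormalization these land at exactly V = 1 and V = 0, with and without
the climate term, giving a sharp end-to-end pipeline check.

## Problem sizes and tolerances

The default world is 40 nations × 120 taxa × 40 years; unit and property
tests use 6–12 nations, the brute-force-oracle comparisons 10 nations × 30
taxa, and the end-to-end scale check 150 nations × 400 taxa × 40 years
(~10⁶ catch records), which completes in well under five minutes on one
CPU. Conservation and oracle-equivalence assertions use 1e-9 relative
tolerance; closed-form identities use exact or near-machine tolerance.
Monotonicity properties are checked over 200 seeded random perturbations.

## Known limitations

- The four-tier ladder is a defensible default, not a canonical rule;
  swapping the tier order changes coarse-taxon masses (typically a small
  share of total catch).
- Median category yields are unweighted over nations; a
  population-weighted median would emphasize large nations and is not
  currently implemented.
- The vulnerability index inherits the usual caveats of equal-weight
  composite indicators: min-max normalization is sensitive to outliers,
  and the arithmetic-mean composition assumes substitutability between
  drivers.
- FOC-pool nutrients are reported but unattributable; any true-ownership
  reattribution would require vessel-level registries out of scope here.
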