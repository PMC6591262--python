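# Methods

This note records the models implemented in `meorkit`, their assumptions,
the defaults that matter, and what the synthetic-data generators do and do
not emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Redox stoichiometry

Donors are C/H/O species (optionally charged); the electrons released on
complete oxidation of carbon to CO₂ are counted by the degree-of-reduction
formula γ = 4·nC + nH − 2·nO − z. The charge convention credits an anionic
charge of −1 with one extra electron; this reproduces γ = 8 for acetate
(C₂H₃O₂⁻) and hence the 6.25 mM acetate per 10 mM nitrate coupling.
Acceptor couples are fixed at 2 e⁻/N (nitrate→nitrite), 3 e⁻/N
(nitrite→½N₂) and 5 e⁻/N (full couple); the full couple is the default
endpoint everywhere.

Balanced reactions are constructed on a 1-mol-donor basis with carbon ending
as CO₂ (not bicarbonate): the choice affects only the H⁺/H₂O bookkeeping,
never the electron counts or gas yields of N₂. H⁺ and H₂O may appear on
either side (H-poor cationic donors legitimately consume water).
Coefficients are exact `fractions.Fraction` values; rounding (half-up,
default 2 decimals) happens only at presentation. `verify_balance` recomputes
per-element and charge residuals and is used as the internal oracle: every
constructed reaction has all-zero residuals.

Biomass yield is deliberately excluded from the stoichiometric coefficients
(complete dissimilation). The electrons actually diverted into biomass or
exopolymer are inferred separately (`dosing.assimilated_fraction`) from
observed nitrate/nitrite conversions; for acetate-fed cultures in which
10 mM nitrate reaches nitrite but only 4 mM continues to N₂, that fraction
is 1 − 32/50 = 0.36, consistent with the observation that stoichiometric
acetate doses leave residual nitrite.

**Benzoate discrepancy.** Charge-balanced chemistry gives γ = 30 for
benzoate (C₇H₅O₂⁻), i.e. 1.67 mM per 10 mM nitrate. The published coupling
of 1.72 mM implies 29 e⁻/mol. The package implements the correct chemistry
and exposes `PAPER_COMPAT_ELECTRONS` as an explicit override table for
reproducing the published figure; it never silently substitutes it.
Nitrogen-containing donors are rejected in this version (none of the donors
of interest contain N).

## Two-phase dosing

Hydrophobic donors are dosed in an inert heptamethylnonane (HMN) carrier
phase; the donor is treated as fully bioavailable over the incubation (no
mass-transfer kinetics), which is the assumption implicit in dosing a
carrier at the stoichiometric concentration. Bookkeeping is mmol-based
(mM·mL/1000). The solubility registry holds ethylbenzene 1.5 mM and toluene
5.6 mM at 20 °C; other temperatures are flagged `unknown` rather than
extrapolated. Margins are reported, never forced to zero: the published
chemostat pre-growth doses sit ≈2–5 % above the exact requirement and the
package reports exactly that.

## Mechanism models

* **Gas drive**: ideal-gas molar volume RT/P with R = 0.082057 L·atm/(mol·K);
  no compressibility correction at 27.2 atm (the discrepancy is ~1 % and the
  reference figures are themselves ideal-gas values). The 1 atm/25 °C molar
  volume is reported unrounded (24.47 L, not 25). The CO₂-as-gas fraction
  defaults to 0 (at reservoir pH most CO₂ is bicarbonate) and is a plain
  argument.
* **Emulsification**: monodisperse spherical droplets of diameter d covered
  by a cell monolayer. Total droplet surface A = N·a/coverage (N adhered
  cells, a the per-cell footprint), droplet count n = A/(πd²), oil volume
  V = n·πd³/6 = (d/6)·N·a/coverage. Defaults a = 1.7 μm², cell volume
  3.1 μm³ are plausible rod-shaped-cell values consistent with a ≈1.6 cm³
  capacity per 17.5 cm³ aqueous volume at 1.3×10⁹ cells/cm³ and with a
  ≈0.4 % biomass volume fraction; the exact cell geometry behind those
  reference figures is not published, so the tests treat the capacity as a
  bracketed range ([1.4, 2.0] cm³ over footprints 1.5–2.1 μm²), not a golden
  number. Both parameters are explicit fields, never constants inside
  formulas.
* **Plugging**: from Q = A·k·ΔP/(μ·L) at fixed Q, μ, L, k, the effective
  area ratio is A₂/A₁ = ΔP₁/ΔP₂. No permeability estimation or transient
  analysis is attempted.

## Column accounting

Pore volume comes from the wet/dry mass difference over brine density. The
extract calibration is modelled as linear with an explicit intercept
(blank); slope and intercept are required configuration inputs because no
standard curve exists for this assay — each lab calibrates its own extract
absorbance. Tests use a documented synthetic curve (slope 2.0 per mL oil/mL
solvent, intercept 0.02). Oil volumes are floored at zero; %ROIP is treatment-stage oil over
ROIP. Negative-control pooling offers both the mean over individual control
columns and the mean of group means: from the printed duplicate-row means
the pooled control is 3.95 %, while the published pooled value is 4.1 %;
the unrounded per-column values were not published, so neither 4.1 % nor
the derived "net 12.0–13.9 %" range is used as a golden number. Aggregation
weights rows by replicate multiplicity; the weighted ROIP/PV mean over the
23 summarized columns is 0.49. Presentation rounding: %ROIP one decimal,
fractions two decimals, half-up.

## Dose–response regression

Ordinary least squares of %ROIP on OD₆₀₀ per nitrate condition, r² as the
squared Pearson correlation (identical to OLS R² with intercept). No
weighting, no errors-in-variables; fits with n < 8 carry a `small_sample`
flag. From the printed four-point tables the no-nitrate line recomputes to
slope 4.86 (the published 4.8 is a rounding artifact; intercept 6.1 and
r² 0.947 reproduce exactly) and the nitrate line to 11.2·OD + 8.3
(r² 0.995). The biomass-equivalence ratio depends on the chosen target
recovery (≈2.8–3.3 over the observed range), so the operation takes the
target as an explicit argument rather than asserting a single fold value.

## Kinetic simulator

No rate law is published for these cultures; the simulator is the package's
own minimal model: two-step denitrification with each step Monod in its
N-oxyanion, Monod in the shared organic donor, proportional to biomass, and
biomass growing at a fixed yield per mM donor oxidized (electron-weighted
donor consumption: 2 e⁻/N for the first step, 3 e⁻/N for the second, γ per
donor). Chemostat operation adds D·(S_in − S) inflow/outflow terms and −D·X
biomass washout with a piecewise-constant dilution schedule. An optional
nitrate-inhibition term on nitrite reduction exists and is off by default.

Integration is fixed-step RK4 with dt = 0.01 d (a stiff-solver dependency is
avoided; halving dt moves trajectories by < 0.01 %, audited in tests).
Nitrogen and donor electrons are conserved exactly by the rate equations;
the solver audit requires closure within 0.1 %.

The default calibration (`data/default_kinetics.yaml`, labelled
fitted-by-us) is: qmax₁ = 8, qmax₂ = 4 mM/(OD·d), K₁ = 0.2, K₂ = 0.5 mM,
K_donor = 0.01 mM, Y = 2.65 OD/mM donor, X₀ = 0.05, donor₀ = 1.24 mM
(ethylbenzene-equivalent, γ = 42). It reproduces the qualitative targets:
10 mM nitrate fully converted to nitrite between day 2 and 4, a nitrite
peak above 5 mM clearing below 0.5 mM by day 9, chemostat biomass near
OD₆₀₀ 3.1 at day 65 on a 10 mM nitrate / 1.2 mM donor feed, washout above
the maximum specific growth rate, and effluent breakthrough after each
dilution-rate step with the second breakthrough larger than the first.

**Known limitation.** With a feed that is only ~0.8 % above the exact
electron requirement, this model cannot reproduce multi-mM breakthrough
peaks that later decay to zero: once nitrate accumulates, the electron
budget allows a drawdown of only ≈0.02 mM/d, so responses to dilution steps
are monotone approaches to small residuals (< 0.2 mM under the default
calibration) rather than large decaying excursions. Real cultures showing
such peaks presumably store donor, adapt their community, or experience
donor mass-transfer dynamics — all outside this model. Tests therefore
assert the breakthrough *ordering* and sub-0.2 mM levels, not peak
magnitudes.

## Ecology

Shannon diversity uses natural log by default (the mothur convention; base
is an argument). Bray–Curtis is computed on relative abundances by default
because sequencing depth varies between samples; a raw-count mode exists.
UPGMA maintains unweighted average linkage via the Lance–Williams update,
merges at half the cluster distance, and breaks ties by the
lexicographically smallest leaf id in each cluster so dendrograms are
reproducible; trees serialize to Newick. UPGMA is implemented in-package
(deterministic tie-breaks are part of the contract) and is cross-checked in
tests against both a brute-force re-averaging agglomerator and SciPy's
average-linkage cophenetic distances. Rank aggregation routes unmapped OTUs
to an `unclassified` bucket with a warning and preserves unit column sums.

Published community numbers (Shannon indices, *Thauera*/*Pseudomonas*
fractions) derive from deposited sequence reads that this package does not
process; they parameterize generator scenarios only. Passing round-trip
tests show the metrics recover what the generator put in — they say nothing
about reproducing the sequencing-derived values.

## Synthetic-data generators

All generators take explicit integer seeds (`numpy.random.default_rng`) and
are bitwise reproducible. Noise is Gaussian truncated at zero, which slightly
biases means near zero — the dose-table noise (σ = 0.5 %ROIP on values ≥ 6)
is unaffected in practice. OTU tables are Dirichlet-multinomial around a
target genus profile (α = p/overdispersion; overdispersion 0 means plain
multinomial), with the two dominant genera split across two OTUs each so
rank aggregation is exercised. Column datasets distribute the waterflood and
treatment oil over exponentially declining effluent profiles and perturb
extract absorbances; their reduction by `meorkit.columns` recovers the
generating ROIP and %ROIP exactly in the noiseless case.

What the generators do **not** emulate: spatial structure inside columns,
donor partitioning kinetics between oil/HMN and water, community succession,
chimeras/sequencing error profiles, and pressure transients. Tests passing
on generated data validate the bookkeeping and statistics, not these field
phenomena.

## Problem sizes and numerical choices

Default simulations run 12 d (batch) and 70 d (chemostat) at dt = 0.01 d.
Statistical checks use 1000 seeded replicates for regression parameter
recovery (n = 50 points each), 30 replicates for noisy column round trips,
and depth 10⁶ draws for the law-of-large-numbers OTU check; these sizes give
stable verdicts for the properties asserted. Equality tests on currency-like
outputs (coupling coefficients, printed regression numbers) are exact at
printed precision; floating-point comparisons elsewhere use explicit
relative tolerances stated in each test.
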