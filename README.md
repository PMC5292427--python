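# sporeflux

Quantification toolkit for dormant **thermophilic endospores** in cold
marine sediment and seawater. Cold seabeds accumulate endospores of
thermophilic *Firmicutes* that cannot grow in situ; they arrive by
passive dispersal through the water column and are buried. Because the
spores are inert until incubated at growth-permissive temperature
(~50 °C), their abundance must be inferred from what happens when they
are induced to germinate. This package implements the three independent
enumeration assays used for that inference, the burial-decay analysis,
and the deposition budget that ties the standing stock in the sediment
back to the supply of spores from the overlying water — plus seeded
generators that simulate every input table, so the full pipeline is
testable without laboratory data.

It is aimed at geomicrobiologists working with pasteurized incubation
assays (slurry time courses, dilution-to-extinction MPN series, DPA
measurements) and anyone modelling microbial dispersal budgets.

## The quantitative core

**Growth-kinetics enumeration.** After a lag of duration *t*<sub>lag</sub>
(germination + outgrowth), volatile fatty acid (VFA) carbon accumulates
as the germinated population grows exponentially:

    C(t) = C0 · e^{k (t − t_on)}

with *C0* anchored at the pre-onset baseline mean. The fit is a
single-parameter least squares of ln C on (t − t_on) with the intercept
fixed at ln C0. Differentiating at the window start gives the initial
production rate r_on = k·C0; dividing by the cell-specific rate *q*
(calibrated as rate / FISH cell count) enumerates the germinated
population, and the slurry mixing ratio converts to per-mL-sediment:

    N_slurry = r_on / q,   N_sediment = N_slurry · (sediment+medium)/sediment

The doubling time is 60·ln2/k minutes.

**MPN enumeration.** A tube receiving volume *v* of sample at density
*D* grows with Poisson probability p = 1 − e^{−Dv}; the positive
pattern across replicated dilution levels has binomial likelihood
L(D) = Π C(nᵢ,xᵢ) pᵢ^{xᵢ} (1−pᵢ)^{nᵢ−xᵢ}, maximized over D, with 95%
intervals from the profile likelihood (drop of χ²₁(0.95)/2 = 1.92).
Tubes are scored positive on acetate strictly above 0.60 mM; H₂ above
1000 ppm is an advisory "growth suspected" flag only.

**DPA enumeration.** Dissolved dipicolinic acid, released on
germination, is quantified by standard addition (OLS of signal on
spike; concentration = |x-intercept|) and converted to spore
equivalents via a per-spore DPA content (default 2.24 × 10⁻¹⁶ mol).

**Burial decay and deposition budget.** Abundance vs sediment age is
fit as first-order decay, N(age) = N₀e^{−λ·age}, half-life ln2/λ. The
deposition flux is F = N_total · ω · 10⁴ spores m⁻² yr⁻¹ (ω =
sedimentation rate, cm/yr), optionally corrected by λT/(1 − e^{−λT})
for decay over an accumulation horizon T; dividing by the annual water
throughput (depth · 10⁶ · 365/τ mL m⁻² yr⁻¹) gives the spore load each
mL of inflowing seawater must deliver.

## Worked example

```sh
python analysis/01_simulate_datasets.py --seed 1
python analysis/02_growth_enumeration.py
python analysis/03_mpn_enumeration.py
python analysis/04_dpa_enumeration.py
python analysis/05_burial_budget.py
```

which prints (seed 1):

```
VFA production begins at 3.50 h; the germinated population then doubles every 22.1 min.
Initial rate 1.28 mM C/h over a cell-specific rate of 731 fmol C/cell/h enumerates 1.7e+06 cells/mL slurry (5.2e+06 per mL sediment).
Simulated tube table: 4.3e+04 spores/mL (95% CI 9.8e+03-1.6e+05).
Reference patterns: surface 3/1/0 -> 4.3e+04/mL, deep 3/0/0 -> 23/mL.
Dissolved DPA 525 nM (r^2 = 0.9667) corresponds to 2.3e+06 germinated spores/mL.
Culturable spores halve every 346 yr during burial (r^2 = 0.967).
Deposition flux 5.41e+09 spores/m^2/yr (6e+09 after correcting for a century of decay); each mL of inflowing seawater must carry 11.9 spores.
Thermophilic endospores are 60% of the total endospore community.
```

Reading the numbers: the simulated slurry contains 2 × 10⁶ germinated
endospores per mL (the 5% measurement noise pulls this particular
realization to 1.7 × 10⁶); the 1:2 slurry triples densities to the
per-mL-sediment scale. The MPN estimate (4.3 × 10⁴/mL) sits far below
the kinetics-based estimate, as expected for a cultivation assay that
undercounts particle-attached or weakly active cells. The half-life of
~350 yr and the 0.09 cm/yr sedimentation rate turn the surface standing
stock into a deposition flux of ~6 × 10⁹ spores m⁻² yr⁻¹, which a
15-m-deep basin flushed every 12 days can supply at ~12 spores per mL
of inflowing water.

The same stages are exposed as a CLI (`sporeflux simulate | kinetics |
mpn | dpa | decay | budget | quantify`); `sporeflux quantify` runs every
stage whose inputs are given and writes a single key-value report.

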