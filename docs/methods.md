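# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical choices that matter.

## Growth-kinetics enumeration

Model: after pasteurization kills vegetative cells, the surviving
endospores germinate, pass through an outgrowth phase of length
t_lag, and then divide. Each cell produces VFA-carbon at a constant
cell-specific rate q (mol C cell⁻¹ h⁻¹), so with N₀ cells/mL at the end
of outgrowth,

    C(t) = C_bg + (q N₀/μ)(e^{μ(t − t_lag)} − 1),   t ≥ t_lag,

where μ is the specific growth rate and C_bg the pre-onset baseline.
The fitted quantity is a pure exponential anchored at the baseline mean
C0: a one-parameter OLS of ln C on (t − t_on) with intercept fixed at
ln C0. This anchoring honors the assay logic — the baseline is measured,
not fitted — and makes the derived initial rate r_on = k·C0 exact at the
window start. A free-intercept variant (`free_intercept=True`) is
available when the baseline is unreliable.

The anchored fit and the mechanistic curve agree exactly when
C_bg = qN₀/μ, which is the generator's default baseline (0.677 mM C for
the default scenario); the −1 term then cancels and noiseless round
trips recover (μ, N₀) to machine precision. For baselines off that
value the anchored fit is biased; the bias stays within 10% for ±10%
baseline perturbations when the fit window spans μ·Δt ≳ 3, and this is
what the round-trip tests assert.

Onset detection: first sample whose VFA-carbon exceeds baseline mean +
3 SD, reported as the *preceding* sample time (the true onset lies
between the two). The SD is floored at 5% of the baseline mean so the
rule also works on noiseless data. Three baseline samples minimum.

Units: concentrations are mM throughout; conversions to mol/mL happen
only in `sporeflux.units`. Carbon weighting uses a fixed registry
(formate 1 … isovalerate 5); unknown species are rejected by name.
Duplicate time points are rejected rather than averaged — they usually
indicate a data-handling error, not replicate measurements.

## MPN estimation

Likelihood: binomial per dilution level with Poisson seeding
probability pᵢ = 1 − e^{−D vᵢ}. The MLE is found by bounded search on
log D followed by a root solve of the score equation, giving ~1e-12
relative precision (and consequently exact volume-scale equivariance to
solver precision). Degenerate patterns short-circuit: all-negative
gives density 0 with a one-sided 95% upper bound (log-likelihood drop
χ²₁(0.90)/2 = 1.353 from D = 0); all-positive gives an infinite
estimate with the analogous one-sided lower bound.

Confidence intervals: two-sided 95% from the profile likelihood
(drop 1.92). The choice is pragmatic — it needs no table, handles
arbitrary designs, and calibrates well: simulated triplicate ten-fold
series at 10³ spores/mL give 95.3% empirical coverage over 1000
replicates. Cochran's classical log₁₀-normal interval
(SE = 0.58/√n per ten-fold step) is available via `ci_method="cochran"`
for comparison with tabulated assays.

Volume accounting is explicit: the estimator takes per-tube volumes of
*original sample*, never dilution labels. For a 1 mL inoculum into 9 mL
medium, the 10⁻ⁿ tube holds 10^{1−n} mL. The mapping from a lab's
dilution labels to volumes is left to the user because label
conventions vary and silently assuming one is how order-of-magnitude
errors happen. `informative_triplet` extracts the classical three-level
sub-design for table comparisons but is never applied automatically.

Scoring: acetate strictly above 0.60 mM (negative controls can show up
to ~0.57 mM without growth); H₂ above 1000 ppm flags "growth suspected"
only, since headspace H₂ is the incubation-termination signal, not the
scoring signal. Report rounding: below 100/mL to the nearest integer,
otherwise two significant figures.

## DPA quantification

Standard addition with unweighted OLS (no weighting scheme is imposed
because signal-noise structure varies by instrument); the sample
concentration is the x-intercept magnitude, intercept/slope. Negative
fitted concentrations — expected for true blanks under noise — are
clamped to zero with a warning rather than raised, since "no dissolved
DPA before pasteurization" is a meaningful result. The per-spore DPA
content (default 2.24 × 10⁻¹⁶ mol) is a configurable literature value;
it varies by species, so results scale with it. Note the x-intercept
extrapolation amplifies signal noise: at 2% CV a nine-level series
recovers a 582 nM sample with ~3% median error, but single series can
err by ~10%.

## Burial decay and deposition budget

Decay is fit log-linearly (OLS of ln N on age), matching the straight
line such data trace on a log axis, and unweighted because per-point
MPN confidence intervals are asymmetric and often unavailable.
Non-detects are excluded from the fit (they carry an upper bound, not a
value) but should be retained in reports.

Flux: F = (N_tfe + N_srb) · ω · 10⁴ spores m⁻² yr⁻¹. The decay
correction λT/(1 − e^{−λT}) reconstructs the constant deposition rate
that would leave the observed standing stock after T years of
first-order loss; for λ = ln2/350 yr⁻¹ and T = 100 yr the factor is
1.102. Corrected and uncorrected fluxes are always reported side by
side because the correction is a modelling choice, not a measurement.
Seawater supply divides the (uncorrected) flux by the annual water
throughput per m² of seafloor, depth · 10⁶ · (365/τ) mL; years are 365
days (the 365.25 difference is < 0.1%).

Default budget constants describe a shallow depositional basin:
ω = 0.09 cm/yr, 15 m mean depth, 12-day residence time, 10⁴/mL
sulfate-reducing endospores, 100-yr horizon.

## Synthetic data: what it emulates, what it does not

The generators produce tables with the statistical structure the
estimators assume: lag-then-exponential VFA-carbon partitioned across
species (acetate-dominant split 0.80/0.08/0.05/0.04/0.03), FISH counts
tracking the growing population, two-phase DPA release (an
instantaneous pasteurization fraction f_past = 0.7, then single-
exponential saturation with τ = 0.15 h — qualitatively matching release
within minutes of heating and a plateau by ~30 min), Poisson-seeded
tube tables, and log-normally scattered decay profiles with a *linear*
age model (age = depth/ω), a deliberate stand-in for a radiocarbon
age-depth model.

Default scenario ("Aarhus surface"): N₀ = 2 × 10⁶ cells/mL slurry,
q = 640 fmol C cell⁻¹ h⁻¹, t_lag = 3.5 h, μ = ln2/(22 min), 5%
measurement CV; DPA pool 582.4 nM (the spore-equivalent of
2.6 × 10⁶ spores/mL at 2.24 × 10⁻¹⁶ mol/spore — back-computed, since
no absolute DPA magnitudes are tabulated anywhere to anchor it
directly); MPN design of seven ten-fold levels from 1 mL in triplicate;
profile N₀ = 4.3 × 10⁴/mL, half-life 350 yr, σ(log₁₀) = 0.3 over eight
depths to 370 cm. Headspace H₂ is emitted as a fixed yield
(800 ppm per mM C) on the VFA-carbon excess — plumbing for the
advisory flag, not a gas-partitioning model.

Noise is multiplicative Gaussian truncated at zero; no error model is
imposed beyond that. What passing tests therefore do *not* show:
robustness to instrument drift, non-stationary baselines, community
succession effects on q (the cell-specific rate is treated as constant
while real incubations shift taxonomic composition within hours),
particle attachment or cultivation bias in MPN (which is why MPN and
kinetics-based estimates legitimately disagree by ~100×), or age-model
error in the decay fit.

## Problem sizes

Defaults throughout were sized for tight, informative statistics:
recovery medians use 50 replicate simulations, CI coverage uses 1000
simulated experiments, oracle cross-checks use 200 random designs
against a 2000-point likelihood grid. The full suite runs in ~10 s.

## Known limitations

* The anchored exponential fit assumes the baseline is flat and the
  exponential dominates in the fit window; fitting too late (production
  levelling off) biases k low. Choose windows by inspecting the onset.
* The MPN estimator has no correction for false-positive tubes
  (observed at low frequency in blank controls); thresholds are the
  only guard.
* `germination_fraction` compares bulk DPA amounts; it cannot separate
  thermophile germination from DPA released by heat-killed
  non-thermophilic spores during pasteurization.
* The decay model assumes no in-situ production of spores and a single
  community-wide λ; species-specific survival makes the fitted
  half-life an average.
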