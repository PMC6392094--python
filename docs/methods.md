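# Methods

## Scientific setting

`picoflux` implements the analysis chain of a non-stationary ¹³C-bicarbonate
labeling study in a marine picocyanobacterium grown under nitrogen-limited
(ammonium-fed chemostat) versus nitrogen-replete (batch) conditions. The
measured objects are LC-MS isotopologue ion-count vectors per metabolite,
cell-density series, ¹⁴C scintillation counts, and glucose-standard
absorbances. The package turns these into isotopic-enrichment summaries,
turnover-rate fits, per-cell pool sizes, carbon fixation and exudate
partitioning, glycogen concentrations, and a chemostat growth model — plus a
synthetic-data generator that makes every stage testable against known ground
truth.

## Enrichment analysis

For a metabolite with `c` carbons and ion counts `IC(M+i)`, `i = 0..c`:

- **MDV** (mass distribution vector): `MDV_i = IC(M+i) / TIC`, with
  `TIC = Σ_i IC(M+i)`.
- **FC** (fractional contribution): `FC = RLC / RTC` with
  `RLC = Σ_i i·IC(M+i)` and `RTC = c·TIC`. FC is identically the MDV-weighted
  mean label fraction `Σ_i MDV_i·(i/c)`; both code paths exist and are
  cross-checked in tests to 1e-12.
- **Per-cell pools**: `relative_abundance = TIC / cell_density`.

A `TIC = 0` sample raises a typed "undefined enrichment" error and is
reported as *not detected*, never as zero — small pools and absent pools are
scientifically different.

**Natural abundance.** Reported MDV/FC values are *uncorrected* for the
~1.07 % ¹³C background by default, matching common practice for
qualitative flux reading; the background is visible as partial labeling at
t = 0. Optional correction solves `C·x = counts`, where
`C[j,i] = Binom(c−i, j−i)·p^(j−i)·(1−p)^(c−j)` is the lower-triangular
binomial convolution over the unlabeled positions. Negative solutions
(possible for observations outside the convolution's image, e.g. counting
noise) are clipped to zero and the result rescaled to the original TIC;
constrained least squares would differ negligibly at c ≤ 7 and is less
transparent. Correction is carbon-only: the tracer is ¹³C-bicarbonate, and
adduct/heteroatom corrections belong upstream.

**Replicate structure.** MDVs are averaged across technical replicates
within each biological replicate; FC is summarized as mean ± sample SD
(n−1) across biological replicates. Both the per-biological-replicate and
the pooled technical-replicate views are exposed, since either convention
appears in published error bars. A single biological replicate yields a
flagged, undefined SD.

## Synthetic labeling experiments

The generator emulates the study design: substrate label fraction
`p_sub = 0.5` (0.6 mM ¹³C spike on 0.6 mM ambient DIC), sampling at
0/30/60/90 min, 3 technical × 2 biological replicates, natural abundance
0.0107, multiplicative lognormal ion-count noise with CV 5 %, and a cell
density of 4.5×10⁷ cells/ml (the chemostat plateau). The paper of record
for this design reports no measured ion-count noise model; the 5 % CV and
the lognormal form (positive, heteroscedastic, like ion counts) are this
package's defaults, stated here rather than inferred.

Per metabolite (pool size `P`, turnover `k`, precursor rise `k_pre`):

1. precursor atom enrichment `e(t) = p_sub(1 − e^{−k_pre t})`;
2. molecules made at time `s` have carbons labeled i.i.d. with probability
   `e(s)` → isotopologue distribution `Binom(c, e(s))`;
3. pool turnover is first-order, so
   `MDV(t) = e^{−kt}·δ₀ + ∫₀ᵗ k e^{−k(t−s)} Binom(c, e(s)) ds`;
4. natural abundance is convolved onto the remaining unlabeled positions;
5. expected counts are `MDV(t) · P · cell_density`, then multiplied by
   mean-1 lognormal noise per isotopologue entry.

The integral is evaluated with fixed Δt = 0.1 min using *exact survival
weights* per step (`e^{−k(t−s_{j+1})} − e^{−k(t−s_j)}`) and midpoint
enrichment, which conserves probability mass exactly and is second-order
accurate; the discretization error (~1e-8 in FC) is far below measurement
noise. Tests validate it against an independent Δt = 0.01 min Riemann
integration to 1e-3 and against the closed form
`FC(t) = p_sub[(1−e^{−kt}) − k(e^{−k_pre t} − e^{−kt})/(k − k_pre)]`.
Time-zero samples come from the unspiked model (pure natural abundance).
Label positions are exchangeable within a metabolite: no positional
isotopomer (atom-transition) network, no chromatography/peak-shape/m-z
simulation.

Randomness uses one master seed with deterministic, order-independent
substreams per (condition, biological, technical, metabolite, timepoint), so
identical seeds give bit-identical tables and conditions are independent.

**Condition pairs.** Nitrogen limitation is encoded as "large slow-moving
pools": pool sizes × factor, turnover rates ÷ factor (default 3), which
preserves the flux proxy `k·P`. The factor models the observed contrast
direction, not a measured value.

## Kinetics

With four time points, the minimal identifiable model for an FC series is
the mono-exponential rise `FC(t) = b + (A − b)(1 − e^{−kt})`, `0 ≤ A ≤ 1`,
`k ≥ 0`. The baseline `b` defaults to the observed t = 0 FC (uncorrected
natural abundance); fixing `b = 0` is available for corrected data. Fitting
is bounded least squares with two starts for `k` (log-linear transform of
the first rise interval, and 10× it) to escape the A↔k ridge of saturating
curves; ties break to lower RSS, then lower `k`. Degenerate inputs are
flagged rather than forced: flat series return `k = 0` with the plateau at
the mean, and series already ≥95 % saturated at the first positive time
carry a `rate_lower_bound` flag because only a lower bound on `k` is
identified.

**Apparent versus true turnover.** When the precursor equilibrates at a
finite rate, the true FC curve is bi-exponential and the fitted
mono-exponential rate systematically *underestimates* pool turnover
(by ~20–75 % across this package's default panel, measured noise-free).
Parameter-recovery benchmarks therefore use the instantly-equilibrated
precursor regime (`precursor_rise = inf`), where the generator's FC is
exactly mono-exponential and `k` is identifiable from FC alone: recovery is
then exact (≤1e-6 relative) without noise, with median |k̂−k|/k ≈ 2 % at
the experimental design (4 time points, 5 % CV, 3×2 replicates). Condition
*contrasts* are unaffected by the shared bias and use the full cascade
model.

The flux proxy is `k × pool size` (relative units/min): a pool can label
slowly because flux is small or because the pool is large, and the proxy
separates these. Condition comparisons classify each metabolite by sign
pattern (slower + larger = "large-slow", faster + smaller = "small-fast",
else "mixed"); unconverged fits propagate flags and stay unclassified. No
absolute fluxes (mol·cell⁻¹·h⁻¹) are attempted — this needs network flux
balancing, which is out of scope.

## Physiology

- **¹⁴C fixation**: `rate = [(mean(light) − mean(dark))/spike] · DIC · V /
  duration / cells`, in mol C·cell⁻¹·h⁻¹. Spike activity (default 10 µCi =
  2.22×10⁷ DPM) and DIC (default 1.2 mM: 0.6 ambient + 0.6 added) are
  explicit inputs — scintillation conversion constants and quench correction
  are instrument-specific and left parametric. Dark > light gives a flagged
  negative rate, never clipped, to keep error propagation honest. Triplicate
  SE propagates through the linear map.
- **Partitioning**: `particulate = POC/TOC`, `exudate = 1 − particulate`;
  they sum to 1 exactly; noise can push the fraction above 1, which is
  flagged, not clipped.
- **Glycogen**: OLS line through the six glucose standards
  (250/100/75/50/25/10 mg/ml), inverse prediction for the sample,
  extrapolation outside the standard range flagged.
- **Growth**: µ is the OLS slope of ln(density) vs time; doublings/day =
  µ/ln 2 (one doubling/day ⇔ µ = 0.693/day).
- **Chemostat**: Monod model `dX/dt = (µ(S) − D)X`,
  `dS/dt = D(S_in − S) − µ(S)Xq′`, with fixed per-cell N quota (no Droop
  variable quota, no diel light forcing — dilution is continuous as with a
  peristaltic pump). Defaults: D = 0.09/day (9 %/day volume replacement),
  S_in = 16 µmol/L NH₄Cl, q = 5 fg N/cell. µmax = 0.5/day and Ks = 0.1 µmol/L
  are assumptions (not measured) chosen so D < µmax with substrate strongly
  limiting. The quota conversion makes `X·q′` carry µmol N/L for X in
  cells/ml: `q′ = q·10⁻¹⁵·10³·10⁶/14.007`. Analytic steady state
  `S* = KsD/(µmax−D)`, `X* = (S_in−S*)/q′ ≈ 4.48×10⁷ cells/ml` — the
  observed plateau. Integration is LSODA with rtol 1e-8 over 60 days; the
  trajectory matches the analytic steady state to ≤0.1 % and realized
  µ(S) = D to <0.1 %. D ≥ µmax reports washout and no steady state.
- **Welch's t test**: unequal-variance statistic with Welch–Satterthwaite
  df, two-sided p; implemented directly (three lines of arithmetic) and
  cross-checked against `scipy.stats.ttest_ind(equal_var=False)` in tests,
  with a 10⁴-replicate null simulation confirming 5 % type-I calibration.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* of the study's
experiments: binomial label incorporation through first-order turnover,
natural abundance at t = 0, replicate hierarchy, multiplicative noise,
pool/turnover contrasts between conditions. It does not reproduce real-data
features such as peak-integration artifacts, adduct and fragment overlap,
metabolite-specific extraction efficiency, biological replicate variance
beyond the configured noise, or diel physiology. Passing tests therefore
demonstrate correctness of the computations and identifiability under the
stated design — not that any specific biological result would replicate.

## Numerical choices and edge cases

- Synthesis integral Δt = 0.1 min (exact-mass survival weights); oracle
  comparisons at Δt ≤ 0.01 min.
- NA deconvolution: triangular solve, clip at 0, rescale to TIC.
- Curve fits: `scipy.optimize.least_squares` with bounds, multi-start on k.
- Chemostat: LSODA, rtol 1e-8, atol (1e-2 cells/ml, 1e-10 µmol/L).
- Floats are written with 17 significant digits and read back with
  round-trip parsing, so every writer/reader pair is bit-exact.
- Problem sizes in tests and the acceptance script (200–500 Monte-Carlo
  series, 10 condition pairs, 10⁴ Welch replicates, 60-day chemostat
  horizon) were chosen to put Monte-Carlo error well inside the asserted
  margins while keeping a full run in tens of seconds.

## Known limitations

- The mono-exponential apparent rate is a lower bound on true turnover when
  precursor equilibration is slow (see above); use the cascade forward model
  `predict_mdv_progression` when MDV-level detail matters.
- Four time points cannot support richer kinetic models; no attempt is made
  to fit `k_pre` from FC data.
- Chemostat Monod parameters and the N quota are documented assumptions;
  the steady-state density scales as `(S_in − S*)/q`, so quota errors map
  linearly onto density.
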