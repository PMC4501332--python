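# Methods

## Isotopomer model

A sterol's detected fragment ion ([M+H−H₂O]⁺, so oxygen-free) produces an
isotopomer envelope indexed by nominal mass shift. Two independent processes
generate shifts, and their distributions convolve:

- **Natural abundance.** Each element contributes a binomial number of heavy
  isotopes; an isotope with mass increment *s* (¹⁸O: +2) stretches its
  binomial onto the shift axis by *s*. The spectrum is the exact polynomial
  convolution across elements — no sampling, no Gaussian approximation.
  Two abundance presets ship: `FULL_NATURAL_ABUNDANCES` (¹³C 1.1%, ²H
  0.015%, ¹⁸O 0.205%) and `CARBON_ONLY_ABUNDANCES` (¹³C only). The
  carbon-only preset is the package default throughout the pipeline: for
  dehydrated sterol fragments the non-carbon terms shift the M+0 fraction by
  under 0.5% (e.g. 71.3% vs 71.8% for a C₃₀H₄₉ fragment), and the
  carbon-only numbers are the ones the assay's reference values round to.
  The discrepancy is documented rather than hidden; the table is a plain
  parameter.
- **Deuterium incorporation.** A molecule synthesized at water enrichment
  *p* acquires deuterium at *N* effective sites: Binomial(N, p). N is an
  *effective* parameter (hydrogens from NADPH, acetyl-CoA and water
  exchange with different efficiencies); it is estimated, not derived from
  structure.

Truncation is applied once, after all convolutions, on an internal window
extended `window + 4 + N` shifts, so edge loss before renormalization is
below 1e−6 for realistic parameters. Windowed fractions are then
renormalized over the measurable shifts.

**Isobaric masking.** Cholesterol saturates m/z 369 (lathosterol,
zymostenol: unmeasurable) and contaminates m/z 367 above M+1 (desmosterol,
7-dehydrocholesterol, zymosterol: quantified from M+0 and M+1 only).
Masking is a property of the sterol registry; every stage — forward model,
calibration, deconvolution, synthetic generation — normalizes over the same
measurable-shift set, which is what makes the linear deconvolution exact on
model data.

## Deconvolution and kinetics

g = (M0ₘ − M0ₙ)/(M0ₜ − M0ₙ) per replicate, per time point. Noisy g values
outside [0, 1] are flagged but **not clipped**; clipping before fitting
would bias g∞ and k downward. Replicates enter the kinetic fit jointly
(ordinary least squares over all points) rather than being averaged first.

The fit g(t) = g∞(1 − e^(−kt)) uses bounded trust-region least squares with
g∞ ∈ [0, 1.05] (small calibration slack above 1) and k ∈ [0, 10]/hr.
Initialization is deterministic: g∞ ← max(g), k from the earliest
informative point via the closed-form single-point inversion. Series whose
g never exceeds 0.02 are reported as zero turnover (k = 0) instead of being
fitted. Standard errors come from the Gauss–Newton covariance at the
solution.

Concentrations are quantified per sample as
(analyte area / IS area) × IS amount × response factor / normalizer, with
response factors defaulting to 1 relative to d₆-sitosterol (20 ng spike),
then averaged across samples — total envelope intensity is conserved under
labeling, so every sample is usable. Rates are k × concentration, reported
per hour internally and per day (×24) in reports.

## Calibration

- **M0ₙ** is the mean windowed M+0 of the t = 0 (unlabeled) samples; the
  deviation from the natural-abundance prediction is reported as a sanity
  check. If no unlabeled samples exist, the theoretical value is used and a
  warning recorded.
- **Asymptotic M0ₜ observations** default to the replicate mean at the last
  time point (valid when labeling ran long enough to turn the pool over — 
  the design assumption of the experiment). A `plateau` mode extrapolates
  the fitted exponential plateau of M0(t) instead, for series that have not
  saturated.
- **N at known p** (cell mode): the model M+0 is strictly decreasing in N,
  so the least-squares N is the root of model(N) − observed over continuous
  N (gamma-function binomial), found by bisection and rounded to the nearest
  integer (ties up). Out-of-range observations return the nearest boundary
  with a warning.
- **Joint (N, p)** (mouse mode): one global p, one N per sterol shared
  across tissues, minimizing the RMS misfit of all asymptotic M+0 values.
  The objective is ridged: because the envelope depends on (N, p) mainly
  through the mean label content N·p, shifting every N and rescaling p
  produces near-equivalent fits ("aliases"), and a naive alternating scheme
  stalls at whatever basin its starting p lies in. The implementation
  therefore scans the N-profiled RMS on a fine p grid (step 2.5e−4),
  refines every competitive local basin by bounded 1-D minimization, keeps
  the best, and then runs the alternating polish (integer-grid N per
  sterol, ties to the smallest N; bounded scalar p), whose RMS is
  non-increasing to convergence (ΔRMS < 1e−10, ≤ 100 iterations).
  Identifiability requires two assumptions, both surfaced as parameters:
  N is restricted to the plausible site-count band 18–30 (literature and
  this assay agree on ~20–28; wider bands re-admit aliases at implausible N
  that noise cannot reject), and a single sterol/observation cannot pin
  both parameters (returned with a `degenerate` flag). Observation weights
  are equal across tissues and sterols.

## Pathway statistics

Fractional Bloch utilization = rate(desmosterol) / [rate(desmosterol) +
rate(7-DHC)] is the canonical statistic; the lanosterol-denominated ratio is
secondary and intentionally diverges where flux exits the pathway upstream
(in the testes-like scenario, two-thirds of t-MAS leaves before zymosterol,
so the alt ratio reads ~1/3 while the terminal split reads 0.97). Flux-drop
diagnostics compare each adjacent measurable pair along both branches and
flag ratios below 0.67 (configurable); the dihydrolanosterol branch off
lanosterol is always reported as off-pathway when present. When one
terminal rate is unmeasurable the utilization is returned as undefined with
a reason, never imputed. The utilization-vs-ln(lanosterol rate) table
carries a descriptive least-squares slope and residual ranks for outlier
inspection — no significance test is attached, since none is defined for
this design.

## Synthetic data generator

The generator is the forward model run in reverse, with explicit
`SimulationTruth`: global p, per-sterol (N, k, g∞, concentration), sampling
times (cell grid 0–24 h, 9 points; mouse grid 0–168 h, 14 points), 3
replicates, 2% multiplicative log-normal peak noise (unit mean; the assay
publishes no noise model, log-normal keeps intensities positive),
isobaric-masking censoring (masked peaks are absent, as the analysis must
treat them), and internal-standard rows scaled so quantitation recovers the
true concentration. Noise substreams are keyed by (seed, sterol, time,
replicate), so extending a scenario never perturbs existing streams; a
fixed seed reproduces files byte-for-byte. Note that two scenarios sharing
a seed share noise draws for the same (sterol, time, replicate) — use
distinct seeds per tissue when merging tables.

Per-sterol spectra are mixed as g·(windowed labeled) + (1−g)·(windowed
natural), each normalized over the sterol's measurable shifts. This is the
regime in which the linear M0 deconvolution is exact; real spectra are
mixtures of *unwindowed* envelopes, so real data carry a small additional
window-capture bias that the generator deliberately does not emulate —
passing tests certify the analysis chain, not the windowing approximation.
Other features of real data the generator omits: chromatographic
interference beyond the masking rules, retention-time drift, detector
saturation shapes, between-animal biological variance (noise_cv is a free
parameter, not an estimate of the study's variance), and time-varying body
water enrichment (p is constant, matching the bolus-plus-drinking-water
approximation).

Tissue presets specify each sterol's synthesis rate (ng/normalizer/day) and
pool concentration, deriving k = rate/(24·conc); rate ratios — the pathway
architecture — are therefore exact by construction: testes 0.97 terminal
Bloch share with a two-thirds t-MAS diversion, liver 0.50 with a
dihydrolanosterol branch at 7.5% of lanosterol, preputial 0.08, adrenal
≈0.97 with no flux drop, skin 0.15 with measurable dihydro-t-MAS, brain
slow and MK–R-dominated, plus two cell-line presets on the 24-h grid.
Concentrations are set so every rate constant turns the pool over within
the labeling window (k·t_max ≳ 3), the regime the asymptote-based
calibration assumes and the experiment was designed for. Absolute
magnitudes are scenario choices, not measurements.

## Numerical and design notes

- Printed reference values the model reproduces exactly: 30-carbon natural
  envelope 72/24/4% (M+0/1/2), 27-carbon natural M+0 = 0.74, fully-labeled
  lanosterol model (N = 22, p = 0.05) windowed M+0 = 25% and M+1 = 37%,
  windowed asymptotic M+0 at (C27, N = 24, p = 0.05) = 0.23.
- Per-peak deconvolution requires |labeled − natural| ≥ 0.02 for that peak
  (identifiability floor; prevents division blow-up), else the caller falls
  back to M+0.
- The windowed-M+0 model table used in calibration exploits the lower-
  triangular structure of truncated convolution (peak s needs only terms
  0…s of each factor), making the p-profile scan exact and vectorizable.
- Exit codes of the CLI: 0 success, 1 runtime failure, 2 config/validation
  failure. All tolerances, windows, bounds and abundance tables are
  function parameters or config keys, not hard-coded constants.
- Problem sizes in the test suite: parameter-recovery checks use 200 seeded
  replicates (joint calibration and kinetics) and single-tissue end-to-end
  runs at 3 replicates; the brute-force convolution oracle enumerates
  molecules up to 6 atoms + 6 sites.

## Known limitations

- Single-pool assumption: a sterol pool partially sequestered from the
  biosynthetic route (two sub-pools with different turnover) would bias g
  downward; multi-pool models are out of scope.
- No compartmental precursor–product coupling between sterols; each is
  fitted independently.
- Joint (N, p) estimation is identified only through the integer-lattice
  constraint on N within its plausibility band; at high noise the adjacent
  alias (all N ± 1, p rescaled ~4%) is occasionally selected even so.
- The crossover-point readout from tracer experiments is descriptive; no
  statistical test is defined.
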