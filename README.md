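# sterolflux

Flux analysis of cholesterol biosynthesis from heavy-water (D₂O) labeling
LC-MS/MS data.

Cholesterol is completed from lanosterol through two interleaved routes: the
**Bloch pathway**, in which the side-chain Δ24 double bond is reduced last
(…→ desmosterol → cholesterol), and the **Kandutsch–Russell (K–R)** route via
saturated side-chain intermediates (…→ 7-dehydrocholesterol → cholesterol).
Which route a tissue uses — and how much flux each carries — can be read out
by labeling the water pool with D₂O and watching deuterium appear in each
biosynthetic intermediate's isotopomer envelope. `sterolflux` implements the
full analysis chain for that experiment, plus a synthetic data generator so
every stage is testable without instrument data.

## The model

For each sterol, the fragment-ion isotopomer spectrum over the acquisition
window M+0…M+3 is a mixture of two reference states:

- **unlabeled** molecules, whose envelope is set by natural isotope
  abundance (binomial per element, ~1.1% ¹³C dominating — for a 30-carbon
  fragment ion M+0/M+1/M+2 ≈ 72/24/4%);
- **fully labeled** molecules, whose envelope is the natural envelope
  convolved with Binomial(N, p) deuterium incorporation, where *p* is the
  D₂O enrichment of the water pool (~0.05) and *N* ≈ 20–28 is the effective
  number of incorporation sites per molecule.

Writing M0ₘ, M0ₙ, M0ₜ for the measured, natural and fully-labeled M+0
fractions over the window, the fraction of the pool synthesized since
labeling began is the linear deconvolution (MIDA / isotopomer spectral
analysis):

    M0ₘ = g·M0ₜ + (1 − g)·M0ₙ      ⇒      g = (M0ₘ − M0ₙ) / (M0ₜ − M0ₙ)

The time course g(t) = g∞(1 − e^(−kt)) yields the first-order rate constant
k; multiplying by the pool concentration (quantified against a d₆-sitosterol
internal standard) gives the absolute synthesis rate. Fractional Bloch
utilization of a tissue is

    rate(desmosterol) / [rate(desmosterol) + rate(7-dehydrocholesterol)]

and ratios of adjacent intermediates' rates localize points where flux
leaves the pathway.

Calibration of the label model: M0ₙ comes from unlabeled samples, N by
regression of the observed asymptotic M+0 against the forward model at known
p (cell culture, p set by the medium), or — when p is unknown (mice) — by
jointly regressing a global p and per-sterol N against the asymptotic M+0
values across all tissues, minimizing the root-mean-square misfit.

## Worked example

```python
from sterolflux import (FragmentFormula, natural_spectrum,
                        CARBON_ONLY_ABUNDANCES, tissue_preset,
                        simulate_timecourse, run_pipeline, default_registry)
from sterolflux.isotopes import labeled_spectrum

c30 = FragmentFormula(30, 49, 0)              # lanosterol fragment ion, m/z 409
nat = natural_spectrum(c30, CARBON_ONLY_ABUNDANCES, max_shift=3)
print('natural  M+0..M+3:', [round(f, 3) for f in nat.fractions])
lab = labeled_spectrum(c30, n_sites=22, p=0.05, window=3)
print('labeled  M+0..M+3:', [round(f, 3) for f in lab.fractions])

reg = default_registry()
truth = tissue_preset('testes', seed=1, noise_cv=0.02)   # known ground truth
table = simulate_timecourse(truth, reg)                  # synthetic peak table
res = run_pipeline(table, reg, mode='mouse', p='estimate')
rep = res.reports[0]
print(f'bloch_fraction = {rep.bloch_fraction:.3f} '
      f'(truth {truth.bloch_fraction_truth():.2f})')
print(res.fits[['sterol', 'k_per_hr', 'conc', 'rate_per_day']]
      .round(3).to_string(index=False))
```

prints

```
natural  M+0..M+3: [0.718, 0.239, 0.039, 0.004]
labeled  M+0..M+3: [0.245, 0.366, 0.265, 0.124]
bloch_fraction = 0.969 (truth 0.97)
              sterol  k_per_hr   conc  rate_per_day
7-dehydrocholesterol     0.051  0.249         0.305
  dehydrodesmosterol     0.083  4.996         9.928
         desmosterol     0.050  8.021         9.704
              ff-MAS     0.155  7.969        29.706
          lanosterol     0.127  9.994        30.347
               t-MAS     0.103 11.962        29.566
          zymosterol     0.069  5.975         9.845
```

Read: in this testes-like scenario the unlabeled 30-carbon envelope has 72%
M+0, dropping to 25% once the pool is fully labeled; the fitted rate
constants and internal-standard concentrations reproduce the generating
values (e.g. lanosterol 30 ng/mg/day), the terminal-branch split puts 97% of
flux through desmosterol, and the ~3× drop from t-MAS to zymosterol flags
the diversion of methylated intermediates out of the pathway.

The same pipeline is scriptable from the shell:

```
sterolflux simulate --preset testes --seed 1 --out runs/testes
sterolflux fit --table runs/testes/peaks.csv --mode mouse --p estimate --out runs/testes-fit
sterolflux report --fits runs/testes-fit --out runs/testes-report
```

## Layout

| module | contents |
| --- | --- |
| `sterolflux.isotopes` | natural-abundance and label-incorporation spectra, convolution, windowing |
| `sterolflux.registry` | sterol definitions: fragment formulas, m/z, pathway roles, isobaric masking |
| `sterolflux.isa` | M+0 fractions and the linear g deconvolution |
| `sterolflux.calibration` | M0ₙ, N regression, joint (N, p) estimation |
| `sterolflux.kinetics` | first-order fits, internal-standard quantitation, synthesis rates |
| `sterolflux.pathway` | Bloch/MK–R utilization statistics, flux-drop diagnostics, tracer summaries |
| `sterolflux.simulate` | synthetic peak tables and tracer experiments with explicit ground truth |
| `sterolflux.pipeline`, `sterolflux.cli` | end-to-end wiring and the `sterolflux` command |

See `docs/methods.md` for the modeling assumptions, numerical choices and
known limitations.
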