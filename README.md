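# tracernmr

Simulation and quantitative analysis of stable-isotope tracer NMR
experiments: splitting-enhanced ¹H,¹³C-HSQC multiplets, quantitative
¹²C/¹³C spectral filters, and ¹⁵N co-tracing — for metabolomics
researchers who need per-atom ¹³C/¹⁵N isotopomer fractions and absolute
percent incorporation from single samples, and want every analysis step
testable against synthetic data with known ground truth.

## What it computes

**Splitting-enhanced multiplets.** In the ¹³C dimension of an HSQC, a
spin echo whose delays grow in integer multiples *k* of the dwell time
makes every C–C (and optionally C–N) scalar coupling appear at

&nbsp;&nbsp;&nbsp;&nbsp;J_app = (1 + k) · J

while chemical shifts are untouched. Under the weak-coupling
approximation a site's trace is a sum over isotopomers of
`f · exp(i2πΩt) · Π_j cos(πJ_j(1+k)t) · exp(−R₂t)`, Fourier transformed
to absorptive Lorentzian multiplets. Enhancement trades acquisition
length for apparent splitting: sampling 1/(1+k) as many points keeps the
multiplet equally well resolved.

**Quantitative filter.** Paired 1D ¹H spectra (all protons vs ¹³C-bound
protons, identical intensity scale) give absolute per-peak incorporation
from one sample:

&nbsp;&nbsp;&nbsp;&nbsp;%¹³C = 100 · (∫filtered / sin²(2πδJ_CH)) / ∫all

with the sin² term correcting the filter's J-dependent transmission
(worst case 7.2% loss over J_CH ∈ [120, 165] Hz at the standard
δ = 1/(4·145 Hz) tuning).

**Isotopomer fitting.** Observed multiplets are deconvolved by
non-negative least squares against simulated unit-fraction bases built
with the observation's own acquisition parameters; a brute-force simplex
grid search serves as an independent oracle in the tests.

## Worked example

`examples/fit_isotopomers.py` generates a noisy alanine C3 methyl
multiplet with an eight-fold splitting enhancement (ground truth 12.1%
[3-¹³C] / 87.9% [2,3-¹³C]) and fits it:

```
alanine C3 multiplet, 8x splitting enhancement, noise seed 2025
     species   fitted %   sigma   truth %
     [3-13C]      12.08    0.04      12.1
   [2,3-13C]      87.92    0.04      87.9
residual rms: 1.105e-04
```

The two percentages are the positional labelling fractions of the alanine
pool: [2,3-¹³C] alanine descends from labelled glucose through
glycolysis, while [3-¹³C] reflects label scrambling; the σ column is the
1-σ uncertainty propagated from the fit residual. The other example
scripts cover enhanced-multiplet simulation (`simulate_enhanced_multiplet.py`),
single-sample percent-incorporation with the filter correction
(`quantify_incorporation.py`), and the seven-component long-range
¹H,¹⁵N-HSQC of a mixed-origin alanine pool (`nitrogen_tracing.py`).

A `tracernmr` command-line tool wraps the same functionality
(`simulate`, `fit`, `filter-quant`, `fixtures` subcommands; see
`tracernmr --help`).

## Layout

```
src/tracernmr/
  spin_systems.py   metabolite templates, isotopomers, mixtures, JSON io
  spectra.py        Spectrum1D/2D containers, native JSON+CSV format
  simulate.py       FID/spectrum simulation, species filters, peak counting
  quant_filter.py   paired-spectrum percent-incorporation analysis
  fitting.py        NNLS deconvolution, grid oracle, enhancement series
  synthetic.py      fixture library and noisy-data generators
  cli.py            command-line interface
docs/methods.md     model, assumptions, parameter choices, limitations
examples/           one narrative script per capability
```
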