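# Methods

## The measurement problem

Stable-isotope tracer studies feed a ¹³C- (and/or ¹⁵N-) enriched nutrient
to a biological system and read the label's fate out of the NMR spectra of
extracted metabolites. Two quantities matter per carbon atom: the absolute
fraction of molecules carrying ¹³C at that position, and the *positional*
labelling pattern of its neighbours (the isotopomer distribution), which
is encoded in the fine structure of the ¹³C multiplet through one-bond
C–C couplings. This package simulates both observables under a controlled
model and fits them back, so that every analysis routine can be validated
on data with known ground truth.

## Multiplet model

The indirect (¹³C or ¹⁵N) dimension of an HSQC experiment is modelled as a
free-induction decay sampled at the dwell time `dw = 1/spectral_width`,
acquired after a spin echo that refocuses the heteronuclear ¹H couplings
and the chemical shift but lets selected homonuclear/heteronuclear
couplings evolve further. Under the **weak-coupling approximation** each
active coupling contributes an independent cosine modulation, so one
site's signal for a mixture is

    s(t) = Σ_m f_m · exp(i 2π Ω t) · Π_j cos(π J_j E t) · exp(−R₂ t)

where `f_m` is the isotopomer fraction, `Ω` the observed carbon's offset
from the carrier, the product runs over coupled sites that are
isotopically active (¹³C, ¹⁵N) in species *m*, and `R₂` sets the
Lorentzian linewidth (FWHM = R₂/π). Only species with ¹³C at the observed
site contribute — the one-bond coherence transfer is itself the ¹²C
filter — and proton-less carbons (carboxyls, quaternaries) never give a
direct cross peak.

The enhancement multiplier `E = 1 + k` arises because the extra echo
delays are restricted to integer multiples `k` of the dwell time: the
coupling then evolves `1 + k` periods per t₁ increment while the shift
evolves one, so every affected splitting *appears* at `(1+k)·J` with the
line positions `Ω ± Σ(± E·J/2)`. C–C and C–N couplings carry independent
multipliers (`k_cc`, `k_cn`), matching the option of applying the ¹⁵N
π pulse with or without the ¹³C one. Three consequences the test-suite
verifies: the multiplet integral is invariant under `k` (the t=0 amplitude
does not change), the singlet of an uncoupled species is untouched, and a
long-range coupling smaller than the linewidth becomes resolved once
`E·J` clears roughly twice the FWHM.

Spectra are produced by halving the first FID point, zero filling,
discrete Fourier transform, and taking the real (absorptive) part; a
`dispersive_fraction` parameter blends in the imaginary part to emulate
the predictable lineshape perturbation of echo/anti-echo quadrature
detection (default 0; when used it must be applied to observation and
fitting basis alike). The 2D long-range ¹H,¹⁵N spectrum is the outer
product of the F1 multiplet interferogram and the F2 proton line (split by
¹J_CH when the proton's carbon is ¹³C); no t₂ relaxation model is applied.

Deliberately out of the model: strong-coupling (second-order) effects,
relaxation during transfer periods, pulse imperfections, non-uniform
sampling, and spectral folding (aliasing is warned about, not folded).

## Quantitative spectral filter

Absolute per-peak ¹³C incorporation comes from two 1D ¹H spectra of the
*same* sample on one intensity scale: all protons, and ¹³C-bound protons
only. The filtered signal is transmitted with `sin²(2πδJ_CH)`, δ being
the filter's echo delay; with the usual tuning δ = 1/(4·145 Hz) the factor
is exactly 1 at 145 Hz and falls to 92.8% at 120 Hz — a worst case of
7.2% over the aliphatic ¹J_CH range [120, 165] Hz, removed analytically
when the peak's actual J is supplied. The proportionality constant of the
transmission is taken as exactly 1 at the tuned coupling, which is what
makes the 7.2% worst case come out. Integration is a plain trapezoidal
sum over a user window (wide enough to include the ¹³C satellites at
±J/2); 1-σ uncertainties propagate the baseline RMS of a signal-free
window as `σ_I = RMS × Δf × √n`. The reported percentage includes the
~1.07% natural-abundance background; an optional flag subtracts it.

## Isotopomer fitting

An observed trace is deconvolved as a non-negative combination of
unit-fraction basis multiplets simulated with the observation's exact
acquisition parameters (including `k`). NNLS (active-set, via
`scipy.optimize.nnls`) guarantees physical fractions; percentages are the
normalised coefficients. Fraction σ come from the delta method applied to
the active-set covariance. Options:

- **Nuisance refinement** — coordinate descent alternating NNLS with
  bounded golden-section searches over R₂ and a global frequency offset
  (≤20 outer iterations, relative residual tolerance 1e-8), for
  observations whose linewidth or referencing differs from the basis.
- **Degeneracy guard** — basis pairs with normalised inner product
  > 0.999 are declared indistinguishable and the fit refuses, rather than
  silently splitting a fraction between identical columns.
- **Grid oracle** — an exhaustive simplex grid search (scale solved in
  closed form per grid point via the Gram matrix) provides an independent
  check on ≤3-candidate problems; it exists for validation, not analysis.

The enhancement-consistency routine re-fits one mixture at several `k`
with the sampled point count divided by `1+k` — emulating the practice of
buying acquisition time with enhancement — and reports the spread of the
recovered fractions, which is below 0.2 percentage points for noiseless
inputs across 1× to 8×.

## Synthetic data: what it emulates, what it does not

The generator produces every input the analysis modules accept, with the
ground truth serialised alongside. Noise is complex Gaussian **in the time
domain** (how receiver noise actually enters) before transformation, and
signal-to-noise is quoted as tallest-peak-height over baseline RMS.
Default noise levels target SNR ≈ 820 for the non-enhanced ¹³C trace and
≈ 330 for the 1D pair — representative of real short acquisitions of
perfusate samples. Shipped cases:

| case | system | ground truth |
|---|---|---|
| `fig4_glucoseC6` | glucose C4–C6, observed C6 | 6.8 / 41.2 / 52.0 % for [6-¹³C]/[5,6-¹³C]/[U-¹³C] |
| `fig5_alanineC3` | alanine, observed C3 | 12.1 / 87.9 % for [3-¹³C]/[2,3-¹³C] |
| `fig7_alanine_NH` | alanine + amine ¹⁵N, long-range N–H | three equal species → 7-component 2D multiplet |
| `fig2_filter_lactate` | lactate methyl, 1D pair | 40 % ¹³C incorporation |

Chemical shifts and coupling constants are literature-typical values
(alanine ¹J(C2,C3) = 34.9 Hz, ¹J(C1,C2) = 54 Hz; lactate ¹J(C2,C3) = 37 Hz;
glucose ¹J(C5,C6) = 43 Hz, long-range J(C4,C6) = 4 Hz; ¹J_CH = 145 Hz;
alanine ¹J(C2,N) = 5.5 Hz, ²J(C3,N) = 0), shipped as editable data — they
calibrate the demonstrations, they are not measurements. The
seven-component ¹⁵N case needs one sub-population whose C–N coupling is
unresolvably small next to one where it is resolved; since a coupling
table belongs to the template, that species uses a template variant with
`j_cn = 0`, and the 2D simulator accepts explicit (template, isotopomer,
fraction) components for exactly this purpose.

What the generator does **not** emulate: baseline distortion, solvent
residuals, NUS sampling masks, temperature/pH shift drifts, intensity
miscalibration between the paired spectra, and strong-coupling artefacts.
Passing round-trip tests therefore demonstrate correctness of the
*analysis chain under the stated model*, not robustness to every artefact
of real spectra.

## Numerical choices and degenerate inputs

- Frequency grid: fftshifted, carrier centred; ppm axes derive from the
  carrier and the nucleus' spectrometer frequency. Exports order columns
  low-to-high Hz; plotting in NMR convention (ppm right-to-left) is the
  reader's choice.
- First-point halving makes the spectrum integral equal the t=0 FID
  amplitude, which is what guarantees integral conservation under `k`.
- No apodization is implemented. Acquisition parameters should let the
  FID decay within the window (`R₂ · T_acq ≳ 5`); otherwise truncation
  sidelobes appear, and the peak counter will honestly count them. The
  fixtures respect this constraint.
- Peak counting (2D): local maxima via a 3×3 maximum filter, threshold
  relative to the global maximum, then greedy strongest-first merging of
  maxima closer than `min_separation_lines` grid points in both axes —
  deterministic by construction. An all-zero spectrum counts 0.
- Enumeration of candidate isotopomers refuses more than 20 sites (2²⁰
  patterns); the grid oracle refuses more than 3 candidates and steps
  below 0.001.
- Empty mixtures (a species filter can remove everything) simulate to
  all-zero spectra with a warning; the fitter rejects all-zero
  observations instead of returning arbitrary fractions.
- Couplings are stored signed, simulated as |J|: relative coupling signs
  are unobservable in this experiment class.

## Known limitations

- Weak coupling only; closely spaced strongly coupled carbons (e.g. some
  sugar ring pairs at low field) violate the cosine-product model.
- Vendor raw/processed spectrum import is not implemented; spectra enter
  through the native JSON + CSV container or a two-column CSV.
- The uncertainty model is single-σ Gaussian propagation (delta method for
  the fitted fractions); no replicate or bootstrap model.
- The 2D model has no t₂ relaxation and treats F2 lines as pure
  Lorentzians at a fixed position.
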