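# Methods

`quenchbind` analyses the binding of a small quencher molecule (e.g. the food
contaminant acrylamide) to a fluorescent protein (e.g. soy protein isolate),
and follows the bound complex through a static in vitro digestion simulation.
This note records the models, the defaults and why, the numerical choices, and
what the synthetic-data tests do and do not demonstrate.

## Fluorescence quenching

A titration series of emission scans (280 nm excitation, 300–500 nm emission)
at quencher concentrations [Q] is reduced to peak intensities F. The peak is
the spectrum maximum inside the emission window — not a fixed-wavelength
readout — because the emission maximum shifts on binding and a fixed-λ readout
would conflate the shift with the quench. Argmax ties resolve to the lowest
wavelength; a λmax change within one grid step is labelled "none", otherwise
"blue"/"red" relative to the zero-quencher scan. Background subtraction is the
caller's responsibility (`subtract_blank` is provided).

Two linear models are fitted by ordinary least squares:

* **Stern–Volmer**: F₀/F = 1 + K_SV·[Q]. The intercept is fitted freely even
  though the model forces it to 1: a free intercept departing from 1 by more
  than 0.05 is a background-subtraction diagnostic and triggers a warning.
  The slope is reported as K_SV regardless. K_q = K_SV/τ₀; the fluorophore
  lifetime τ₀ defaults to 10⁻⁸ s (the biopolymer convention, and consistent
  with K_q being exactly 10⁸ × K_SV in this kind of study); it is a parameter
  everywhere. Quenching is classified *static* iff K_q strictly exceeds
  2.0 × 10¹⁰ L·mol⁻¹·s⁻¹ (diffusion-limit rule; the boundary value itself is
  *not static*).
* **Double-logarithmic**: log₁₀((F₀−F)/F) = log₁₀K_A + n·log₁₀[Q], giving the
  apparent binding constant K_A = 10^intercept and site count n = slope.
  Base-10 axes are the convention; the result is base-independent because
  K_A = base^intercept. Points with F ≥ F₀ at [Q] > 0 are rejected with a
  warning; fewer than three usable points is an error. A non-positive
  Stern–Volmer slope is flagged as degenerate, not raised, since an
  unquenched series legitimately gives K_SV = 0.

## Thermodynamics

From temperature-resolved K_A values: ΔG = −RT ln K_A (kJ/mol per
temperature), ΔH = −R·slope of ln K_A vs 1/T (one value per series — a
two-parameter van't Hoff model; per-adjacent-pair enthalpies are exposed as a
curvature diagnostic only), and ΔS = (ΔH − ΔG)/T in J·mol⁻¹·K⁻¹. R = 8.314
J·mol⁻¹·K⁻¹. Interaction forces follow the Ross–Subramanian sign rules:
ΔH < 0 & ΔS < 0 → hydrogen bonding + van der Waals; ΔH > 0 & ΔS > 0 →
hydrophobic; ΔH < 0 (or |ΔH| within a configurable 5 kJ/mol near-zero band)
with ΔS > 0 → electrostatic. ΔH > 0 with ΔS < 0 has no assignment and returns
`unclassified` explicitly. Spontaneity is ΔG < 0 per temperature.

## Assay equations

Binding rate B(%) = 100(A − A₀)/A, sulfhydryl content = 73.53·A₄₁₂·D/C
(µmol/g; the factor is 10⁶ divided by Ellman's extinction coefficient
13,600 M⁻¹cm⁻¹, valid when C is in g/L — the unit is documented and
configurable only by scaling C), and release rate R(%) = 100·A₁/A. A free
amount exceeding the total clamps the binding rate to 0 with a warning rather
than erroring, because triplicate HPLC noise makes small negatives routine;
release rates above 100 % are flagged but returned. Replicates are aggregated
as mean ± SD of per-replicate rates, not rates of replicate means.

## Digestion bookkeeping

The three electrolyte fluids (SSF pH 7, SGF pH 3, SIF pH 7) are checked by
dilution algebra: final mmol/L = stock (mol/L) × volume (mL) / 500 mL × 1000,
compared to the declared value after rounding to its printed precision. The
built-in tables declare 19 component concentrations; all 19 validate.

Phases: oral (sample + amylase + SSF + CaCl₂ + water, scaled proportionally
from the 10 mL reference that totals 21 mL), gastric (digesta + SGF + pepsin
to 2000 U/mL, pH 3, 2 h) and intestinal (digesta + SIF + pancreatin to
2000 U/mL + bile to 0.16 mol/L, pH 7, 2 h), all at 55 rpm / 37 °C. Choices
where the protocol is silent, each flagged in the plan's `assumptions`:

* digesta:electrolyte mixing ratio defaults to 1:1 v/v (the standardized
  static-digestion convention these fluids follow); configurable;
* enzymes are dosed as dry additions (no volume) in opaque activity units;
  bile is dosed from a 1 mol/L liquid stock by closed-form dilution
  (c₁v₁ = c₂v₂), erroring when the stock cannot reach the target. "mol/L of
  bile" is chemically loose (bile is a mixture) and is carried verbatim;
* gastric/intestinal CaCl₂ follows the oral-phase dose scaled by volume;
* pH-adjustment titrant volume defaults to 0 mL and is a parameter.

Volume conservation (output = input + additions) holds at every phase by
construction and is property-tested; a conserved non-interacting tracer
exits every phase at exactly 100 % release, which is the null test that the
dilution factors feeding the release-rate equation are coherent.

## Amide-I secondary structure

The amide I region (1700–1600 cm⁻¹) is baseline-corrected with a straight
line between the window endpoints (the simplest reproducible choice), and
candidate component bands are seeded at negative minima of the
Savitzky–Golay second derivative (window 9 points, order 3, both
configurable), keeping minima deeper than 10 % of the global minimum and at
least 4 cm⁻¹ apart, deepest first, capped at `n_bands`. Any assignment window
left without a candidate is seeded at its midpoint — one component per
assignment window is the amide-I convention — so noisy spectra cannot
silently drop a structure class. Gaussians are then refined by bounded least
squares: centers within ±4 cm⁻¹ of their seeds, FWHM in 5–30 cm⁻¹,
non-negative amplitudes. Areas (amplitude·σ·√2π) are pooled by assignment
window — β-sheet 1610–1640 ∪ 1682–1700, random coil 1640–1650, α-helix
1650–1660, β-turn 1660–1682 cm⁻¹, the standard convention, configurable —
and renormalised to sum to 100.

Published structure percentages for this system come from unspecified
curve-fitting software, so they serve here as *generator truth* for recovery
tests, never as an acceptance target on real spectra.

## Statistics

Levene's test (center = mean) gates variance homogeneity and a
Kolmogorov–Smirnov normality check gates distribution shape before a one-way
ANOVA — the gating used in this literature. With triplicates a per-group
normality test is meaningless, so the K-S check runs on pooled group-centered
residuals with Lilliefors-corrected p-values (parameters are estimated from
the data); a Monte-Carlo p-value option exists for very small pooled samples.
A failed gate raises unless explicitly overridden, and the gate outcomes are
always reported. Pairwise differences use Tukey HSD, and letters come from
the insert–absorb compact-letter-display algorithm: two groups share a letter
iff their difference is non-significant at α; the group with the largest mean
carries "A" (ties broken by group order).

Calibration is assessed *conditional on the gates passing*: the
unconditional rejection rate is mechanically ≈ α·P(gates pass) under the
null, which would understate the ANOVA's size rather than measure it. On
5000 null simulations (4 groups × 3 replicates) the conditional type-I error
sits within the binomial 95 % CI of α = 0.05.

## Synthetic data: what it shows and what it does not

Titrations are generated by inverting the double-log model,
F = F₀/(1 + K_A(T)[Q]ⁿ), with K_A(T) linked across temperatures by an exact
two-parameter van't Hoff enthalpy; the default grid is the study design
(9 quencher levels 0–200 µmol/L; 297/304/311 K). Noise is additive Gaussian
with σ expressed as a fraction of F₀, truncated at zero (a documented bias
source at high noise). Each temperature receives an independent noise stream
seeded by (scenario seed, temperature), so repeat runs are byte-identical
but scans are statistically independent, as separate measurements are.
Emission spectra are single Gaussian bands whose amplitudes follow the
titration and whose center shifts linearly with [Q]; amide spectra are
Gaussian mixtures with prescribed area fractions; release tables draw
replicate rates N(mean, sd) per (treatment, phase) group.

Passing recovery tests therefore demonstrates correct *inversion of the
stated models and correct bookkeeping* — they say nothing about inner-filter
effects, scattering, non-Gaussian band shapes, baseline drift, or any other
feature of real instruments that the generators deliberately omit.

**A known, quantified limitation**: at 0.5 % intensity noise the
three-temperature chain (double-log fit per temperature → van't Hoff) is
nearly unbiased for ΔH (≈ −0.5 % bias) but has ≈ 39 % per-seed standard
deviation, because the double-log intercept extrapolates about four decades
beyond the data and the 1/T lever arm across 297–311 K is only 1.5 × 10⁻⁴.
Even a 100-seed ensemble mean carries ≈ 3.9 % standard error, so a "ΔH
within 2 %" expectation at that noise level is not statistically attainable
under this design; the corresponding acceptance test measures and reports
the ensemble-mean error honestly rather than relaxing the band. Noiseless
chains recover ΔH to 10⁻⁹ relative error.

## Problem sizes used

Defaults mirror the study design throughout: 9-point titrations at 3
temperatures; amide spectra 1450–1750 cm⁻¹ at 0.5 cm⁻¹; 100 seeds for the
noisy-chain summary; 50 seeds for noisy amide-I recovery; 5000 null
simulations for the type-I calibration.
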