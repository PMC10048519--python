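# quenchbind

Analysis toolkit for protein–small-molecule interaction studies of the kind
used in food-safety chemistry: a fluorescent protein (e.g. soy protein
isolate) binds a small ligand/contaminant (e.g. acrylamide), the binding is
characterised by fluorescence quenching and van't Hoff thermodynamics, and
the complex is followed through a static in vitro oral–gastric–intestinal
digestion to ask how much of the ligand is released.

It is aimed at bench scientists who have titration spectra, FTIR scans and
replicate HPLC tables, and want the standard work-up — fitted constants,
thermodynamic signs, fluid recipes checked, ANOVA letters — reproducibly and
with the bookkeeping made explicit.

## What it computes

* **Quenching** — from emission spectra or titration curves:
  Stern–Volmer F₀/F = 1 + K_SV[Q] (with K_q = K_SV/τ₀ and the static /
  not-static rule at K_q = 2×10¹⁰ L·mol⁻¹·s⁻¹) and the double-log plot
  log₁₀((F₀−F)/F) = log₁₀K_A + n·log₁₀[Q] for the binding constant and site
  count; λmax blue/red-shift tracking.
* **Thermodynamics** — ΔG = −RT ln K_A, ΔH from the van't Hoff slope,
  ΔS = (ΔH−ΔG)/T, Ross–Subramanian force classification, spontaneity.
* **Assays** — binding rate B(%) = 100(A−A₀)/A, Ellman sulfhydryl content
  73.53·A₄₁₂·D/C (µmol/g), release rate R(%) = 100·A₁/A, replicate
  aggregation.
* **Digestion** — SSF/SGF/SIF electrolyte dilution validation, per-phase
  volume and enzyme/bile bookkeeping, conserved-tracer null checks.
* **FTIR** — amide I/II peak positions; Gaussian deconvolution of the amide
  I band into β-sheet / random coil / α-helix / β-turn percentages.
* **Statistics** — Levene + Kolmogorov–Smirnov gated one-way ANOVA with
  Tukey HSD compact-letter display, as release/sulfhydryl figures report it.
* **Synthetic data** — generators with known ground truth for every input,
  so the full pipeline is testable without instrument data.

## Worked example

```python
from quenchbind import analyze_series, fit_stern_volmer, classify_mechanism
from quenchbind.synthetic import QuenchScenario, gen_titration

# temperature-resolved binding constants -> full thermodynamic work-up
res = analyze_series([(297, 4.13e4), (304, 3.68e4), (311, 1.65e4)])
print(f"dH = {res.dh:.2f} kJ/mol")
print(f"dG = {[round(g, 2) for g in res.dg]} kJ/mol")
print(f"dS = {[round(s, 1) for s in res.ds]} J/mol/K")
print(res.forces.value, res.spontaneous)

# a noiseless synthetic titration inverts exactly under the fits
curve, truth = gen_titration(QuenchScenario(ka_ref=1.2e4, n=1.0), t=297.0)
ksv, kq, r2, _ = fit_stern_volmer(curve)
print(f"Ksv = {ksv:.3g} L/mol, Kq = {kq:.3g} L/mol/s, {classify_mechanism(kq).value}")
```

prints

```
dH = -50.03 kJ/mol
dG = [-26.24, -26.57, -25.11] kJ/mol
dS = [-80.1, -77.2, -80.1] J/mol/K
hbond_vdw (True, True, True)
Ksv = 1.2e+04 L/mol, Kq = 1.2e+12 L/mol/s, static
```

i.e. binding is enthalpy-driven (ΔH and ΔS both negative → hydrogen bonding
plus van der Waals forces), spontaneous at all three temperatures, and the
quenching rate constant sits two orders of magnitude above the diffusion
limit, so quenching is static (ground-state complex formation).

A command-line interface mirrors the library:

```
quenchbind thermo --pairs "297:4.13e4,304:3.68e4,311:1.65e4"
quenchbind fit-sv --input titration.csv --tau0 1e-8
quenchbind digest validate-fluids
quenchbind synth titration --seed 1 --out data/
```

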