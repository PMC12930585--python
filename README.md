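# avdflux

Quantitative analysis toolkit for microbial production of
5-aminovaleramide (5-AVD), a lysine-derived C5 amide monomer, in
*Corynebacterium glutamicum*.  The package covers the full analysis
chain of a strain-engineering study: fermentation stoichiometry,
¹³C/¹⁵N isotope-labeling computations, EMU-based ¹³C metabolic flux
estimation with Monte-Carlo confidence intervals, and NADPH redox
accounting — plus synthetic-data generators that stand in for the raw
measurements and provide ground truth for every step.

It is written for metabolic engineers and systems biologists who want
to rerun, audit or extend this kind of analysis from Python.

## What it computes

**Physiology.** From a culture time course (time, OD₆₆₀, concentrations)
it derives the specific growth rate μ (slope of ln CDW vs *t*),
biomass-specific rates *q*ᵢ = μ·(dCᵢ/dX)·1000/Mᵢ in mmol g⁻¹ h⁻¹, molar
yields *Y* = 1000·*q*_P/*q*_S (mmol mol⁻¹), molar product selectivity,
space–time yields, and specific enzyme activities (mU mg⁻¹) from
substrate-depletion assays.

**¹³C flux analysis.** An atom-mapped central-metabolism network
(EMP, oxidative/non-oxidative PP pathway, TCA cycle with anaplerosis
and malic enzyme, the aspartate route to lysine with meso-DAP
scrambling, the DavB step to 5-AVD, and the GapN bypass) is decomposed
into elementary metabolite units (EMUs).  Fragment mass isotopomer
distributions (MIDs) are simulated by cascaded linear solves per EMU
size; measured GC-MS MIDs are corrected for natural isotopes of the
derivatization remainder by non-negative least squares; free fluxes are
estimated by variance-weighted least squares on the null space of the
stoichiometric matrix (glucose uptake ≡ 100%), with multi-start global
search and Monte-Carlo 95% confidence intervals.

**Redox accounting.** From a flux vector the NADPH ledger tallies
supply per pathway (oxPPP 2 NADPH/1 CO₂, GapN 1/0, TCA-ICD 1/2, malic
enzyme 1/1).  Because ¹³C labeling cannot separate GAPDH from GapN
(identical carbon transfer), the GapN flux is inferred by closing the
NADPH balance at a stated total demand (250% of glucose uptake), and
the carbon economy is reported as NADPH formed per CO₂ released.

## Worked example

```bash
python examples/01_physiology.py
```

```
growth rate mu        = 0.120 +- 0.000 1/h   (truth 0.120)
glucose uptake q_GLC  = 3.35 mmol/g/h          (truth 3.45)
5-AVD secretion q_AVD = 1.09 mmol/g/h          (truth 1.09)
molar yield Y_AVD/GLC = 325.0 mmol/mol       (truth 316.0)
space-time yield      = 0.060 g/L/h overall, 0.188 g/L/h max
molar selectivity     = 97.2 %  (product purity of the secreted spectrum)
```

A synthetic batch culture of the GapN-expressing producer is generated
with 2% multiplicative measurement noise and analyzed blind: the fitted
growth rate, uptake/secretion rates and molar yield recover the
generating truth within the noise, and the selectivity line shows that
36.3 g/L 5-AVD next to 1.6 g/L lysine (0.3 g/L of it from the medium)
is a >97% molar-pure product stream.

The other examples walk the remaining capabilities, each printing the
numbers it computes and what they mean:

| script | capability |
| --- | --- |
| `examples/01_physiology.py` | rates, yields, selectivity, space–time yield |
| `examples/02_isotope_tools.py` | ¹⁵N mass-shift diagnosis, natural-isotope correction |
| `examples/03_simulate_labeling.py` | forward EMU simulation under both tracers |
| `examples/04_flux_estimation.py` | multi-start flux fit with Monte-Carlo CIs |
| `examples/05_redox_ledger.py` | GapN deconvolution and NADPH/CO₂ carbon economy |

A thin CLI wraps the same flows for batch use:
`avdflux synthesize`, `avdflux physiology`, `avdflux simulate-mids`,
`avdflux fit`, `avdflux redox` (see `avdflux --help`).

## Layout

```
src/avdflux/
  compounds.py    compound registry, unit conversions
  physiology.py   growth, rates, yields, selectivity, enzyme activity
  network.py      atom-mapped network model, validation, cofactor queries
  networks.py     shipped central network + toy models
  emu.py          EMU decomposition and MID simulation, tracer specs
  isotopes.py     natural-isotope patterns, MID correction, 15N shifts
  fitting.py      null-space flux parameterization, fit, Monte-Carlo CIs
  redox.py        NADPH ledger, GapN deconvolution, carbon economy
  synthetic.py    scenario generators with ground truth
  bundle.py/cli.py  problem-directory I/O and the command line
  data/           network CSV, drains CSV, fragment YAML, isotope table
```
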