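# Methods

This note documents the models, conventions and numerical choices
behind avdflux, and what the synthetic-data validation does and does
not demonstrate.

## Fermentation stoichiometry

Cultures are modeled as balanced exponential growth: dX/dt = μX with
substrate consumption and product formation proportional to biomass
(dCᵢ/dt = ±qᵢMᵢX/1000, Cᵢ in g/L, qᵢ in mmol g⁻¹ h⁻¹).  μ is the
least-squares slope of ln CDW vs time; it is exact on noiseless
exponential data.  Because concentration is then linear in CDW, each
qᵢ comes from the slope of Cᵢ vs X, which is robust to the sampling
grid.  The exponential window is chosen automatically as the
contiguous run of ≥4 samples maximizing R² of ln CDW vs t (longest run
wins near-ties); callers can override it with explicit bounds.

OD₆₆₀ is converted to cell dry weight with a correlation factor of
0.32 g L⁻¹ per OD unit by default.  This is a stand-in: the factor is
strain- and spectrophotometer-specific and must be calibrated; every
function takes it as a parameter, and the shipped tests use data where
it either cancels or is set explicitly.

Selectivity is molar by default (mass basis behind a flag), with
optional subtraction of product amounts already present at inoculation
— relevant for complex media that carry lysine.  Sugar accounting for
molasses media uses hexose equivalents (sucrose = 2).  Standard errors
of derived rates use first-order propagation of the regression errors.

Specific enzyme activity is the initial-rate slope of substrate
depletion, 1 mU = 1 nmol min⁻¹, per mg total protein; flat traces are
flagged as valid negative controls rather than errors.

Intracellular pools convert from μmol g_CDW⁻¹ to cytoplasmic mM with a
volume factor of 1.95 μL mg_CDW⁻¹ (the units cancel directly).

## Network model

The shipped central-metabolism network for the lysine/5-AVD producer
covers EMP glycolysis, the oxidative and non-oxidative PP pathway, the
TCA cycle, PEP carboxylase anaplerosis, malic enzyme back-flux,
glutamate dehydrogenase, a lumped aspartate/diaminopimelate route to
lysine, the DavB monooxygenase step to 5-AVD, and the NADP⁺-dependent
GapN bypass at the GAP node.  Only carbon is atom-mapped (letter
strings, 1-based, contiguous per metabolite); H/O/N are balanced
through signed per-reaction cofactor counts (NADPH, NADH, ATP, O₂,
NH₄).  CO₂ is a balanced one-carbon metabolite with an efflux
reaction, so label incorporation through PEP carboxylase is modeled.

Scrambling at symmetric intermediates is encoded as equal-weight
atom-map variants: succinate/fumarate in the lumped TCA step, and
meso-diaminopimelate in the lysine route (the classic positional
scrambling of the dehydrogenase pathway).  Validation rejects carbon
imbalance per reaction (naming it), inconsistent carbon counts, and
balanced metabolites that are not both produced and consumed.

Cofactor demand queries solve a minimal-total-flux linear program for
one unit of target with biomass drains zeroed.  The LP is degenerate
between the native GAPDH and the GapN bypass (same carbons, same route
length); a vanishing secondary cost (ε = 10⁻³) on cofactor-producing
flux breaks the tie toward the canonical route, so the query reports
the pathway's intrinsic requirement — 4 mol NADPH per mol lysine
(glutamate dehydrogenase, aspartate semialdehyde dehydrogenase,
dihydrodipicolinate reductase, diaminopimelate dehydrogenase), and the
same 4 for 5-AVD since DavB consumes O₂ but no NADPH.

Anabolic precursor drains ship as an editable CSV in percent of
glucose uptake, computed from standard biomass precursor demands
(μmol g⁻¹) at μ = 0.12 h⁻¹ and q_GLC = 3.45 mmol g⁻¹ h⁻¹.  The same
drain table is used for both producer scenarios; the ~6% difference
their growth rates would imply is below the resolution of the method.

## EMU simulation

MIDs are simulated with the elementary-metabolite-unit decomposition:
starting from the target fragments, the minimal set of atom subsets is
traced backward through the atom maps; balances are linear within an
EMU size, so the cascade solves one dense linear system per size
(1 … 6 here), with condensation reactions entering as convolutions of
smaller-EMU MIDs.  Reversible reactions become forward/backward pairs
with fluxes (exch + max(net,0), exch + max(−net,0)).  Dense LU is used
throughout — the largest level here has a few dozen unknowns, so a
sparse path would add complexity without benefit.

Tracers are mixtures of positional isotopologues with a purity model:
each nominally labeled position is ¹³C with probability equal to the
purity (default 0.99); unlabeled positions carry natural abundance
(0.0107).  Simulated MIDs therefore include substrate natural
abundance, which fixes the correction convention below.

The simulator is validated against an independent brute-force oracle
that iterates full joint isotopomer distributions (2ⁿ states per
metabolite) to a fixed point; agreement is to 10⁻⁹ on the toy networks
and 10⁻⁸ on the central network.  Structural invariants tested:
MID normalization, natural-abundance output under an unlabeled tracer,
and invariance under flux rescaling.

## Natural-isotope correction

A raw [M−57]⁺ cluster is modeled as the backbone MID convolved with
the natural isotope pattern of everything else in the ion (analyte
heteroatoms plus the TBDMS-derivatization remainder), shipped per
fragment as an elemental "correction formula" in editable YAML.
Correction solves the banded linear model by non-negative least
squares and renormalizes — plain inversion produces negative fractions
at low signal.  The isotope abundance table (IUPAC 2013 values) ships
as data so results are bit-stable.

By default only non-backbone atoms are deconvolved: the simulator
already models backbone natural ¹³C, so removing it in correction
would double-count.  `correct_backbone=True` removes it too, in which
case a fully unlabeled analyte corrects to [1, 0, …].

Deconvolution amplifies noise, so corrected-channel standard
deviations are propagated through the pseudo-inverse of the correction
matrix; the flux fit weights channels with these propagated SDs
(floored at the raw SD).  Without this the optimum's SSR is visibly
above its χ² band.

## Flux estimation

Net fluxes are parameterized exactly on the null space of the balance
matrix with equality constraints for glucose uptake (≡ 100%), drains
and any clamped reactions; the coordinates are the fluxes of chosen
free reactions (oxPPP, malic enzyme, 5-AVD export in the shipped
setup), which keeps parameters interpretable and boundable.  Exchange
fluxes use exch = β·x/(1−x) with x ∈ [0, 0.95] and β = 100%, keeping
the search bounded while allowing effectively unbounded exchange.

The objective is the variance-weighted SSR over all MID channels of
both tracer experiments jointly plus measured rates.  Dependent
irreversible fluxes are kept nonnegative by large penalty residuals
(10³ per unit violation) rather than hard failures, so the optimizer
sees a gradient back to feasibility; restart points are screened to
start inside the irreversibility-feasible region (net fluxes sampled
up to 150% of uptake), which avoids a degenerate flat basin at the
feasibility boundary.  Restarts use `scipy.optimize.least_squares`
(trust-region reflective, tolerances 10⁻¹⁰) from seeded uniform draws;
results are bit-reproducible for a fixed seed.  "Converged to the same
solution" means all restart SSRs within 10⁻³ relative and net fluxes
within 0.5 percentage points of the best.

95% confidence intervals resample every measurement from
Normal(value, SD) (MIDs renormalized), refit from the best solution,
and take 2.5/97.5 percentiles per flux; more than 20% refit failures
is an error.  On a one-parameter problem the MC interval matches the
profile-likelihood interval within sampling error (tested).

The GAPDH/GapN split is structurally unidentifiable from ¹³C data
(identical carbon mapping), so fits clamp GapN to zero and estimate
the total GAP-node flux; the split is recovered afterwards by the
NADPH balance: GapN = demand − (2·oxPPP + ICD + ME), GAPDH = node
total − GapN.  The 250% total demand is a named parameter
(`NADPH_DEMAND_AVD`), defined as the summed NADPH-forming flux of the
GapN-free reference strain and carried over under the assumption of
equal growth and product formation; it is never hard-coded inside the
operation.

## Redox ledger

Pathway stoichiometries are fixed defaults: oxPPP 2 NADPH/1 CO₂, GapN
1/0, TCA-ICD 1 NADPH/2 CO₂ (the full TCA turn's decarboxylations are
attributed to the ICD-dependent NADPH), malic enzyme 1/1.  Other
decarboxylations (PDH, lysine decarboxylation, DavB) are deliberately
excluded from the NADPH carbon economy — the ratio describes the cost
of redox supply, not total CO₂ production.  A ledger with no
decarboxylating NADPH source reports +∞ (a tagged sentinel, not an
exception) so pipelines can state "carbon-free NADPH supply".

## Synthetic data: scope and limits

The generators emulate (a) exponential batch time courses with
multiplicative Gaussian noise on OD and concentrations (2% default)
truncated at substrate exhaustion, and (b) raw GC-MS MID tables:
simulated backbone MIDs convolved with the derivative pattern, with
additive Gaussian channel noise (0.4 mol% default, a common GC-MS
floor) and renormalization.  The two shipped producer scenarios pin
their physiology to the published strain table (μ = 0.12 h⁻¹,
q_GLC = 3.45, q_5-AVD = 1.09 for the GapN strain; 0.11/3.35/0.79 for
the reference) and their flux vectors are constructed so the redox
ledger carries the published structure — 250% NADPH supply, 53.8% GapN
share of the GAP node, NADPH/CO₂ of 1.27 and 1.0 — with the remaining
freedom (exchange fluxes, PP-pathway split between strains) set to
values typical for C. glutamicum on glucose.

What passing tests show: the estimator recovers the parameters of data
generated under its own model assumptions, with calibrated confidence
intervals, at realistic noise.  What they do not show: robustness to
model misspecification in real data — wrong biomass composition,
channel-correlated GC-MS errors, metabolic non-stationarity, unlabeled
biomass carry-over, or an incomplete reaction network.  The network
and drain files are editable data precisely so a laboratory's own
supplementary tables can be swapped in.

## Known limitations

- Isotopically stationary analysis only; no transient (INST) mode.
- Carbon-only atom tracing; ¹⁵N handling is limited to mass-shift
  diagnosis of analyte nitrogen counts.
- The lysine route is lumped; intermediate pools (aspartate
  semialdehyde, dihydrodipicolinate) are not explicit.
- Monte-Carlo CIs assume independent Gaussian measurement errors;
  renormalization-induced correlations are ignored (slightly
  conservative channel SDs compensate in practice).
- The minimal-route cofactor query reports one canonical route; it is
  not a flux-variability analysis.
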