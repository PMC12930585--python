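# Anabolic precursor drain fluxes for a 5-AVD producer growing at
# mu = 0.12 1/h with q_GLC = 3.45 mmol/g/h, as percent of glucose uptake.
# Computed from standard biomass precursor demands (umol per g CDW):
# flux% = demand * mu / (q_GLC * 1000) * 100.  Editable data: replace
# with strain-specific values to match a measured biomass composition.
precursor,flux_percent
G6P,0.71
F6P,0.25
P5P,3.12
E4P,0.93
GAP,0.45
PGA,5.20
PEP,1.81
PYR,9.85
ACA,10.18
OAA,6.21
AKG,3.75
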