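# Measured GC-MS fragments ([M-57]+ of TBDMS derivatives unless noted).
# metabolite/atoms place each fragment on the network model: proteinogenic
# amino acids report the labeling of their central-metabolic precursors
# (Ala <- pyruvate, Ser <- 3-phosphoglycerate, Asp <- oxaloacetate,
# Glu <- 2-oxoglutarate), lysine and 5-AVD are measured directly from the
# supernatant.  correction_formula lists every atom of the ion except the
# backbone carbons: analyte heteroatoms plus the derivatization remainder
# after loss of the tert-butyl group.  Editable data, not code: swap in
# the laboratory's own fragment table to analyze real measurements.
- fragment_id: Ala_m57
  metabolite: PYR
  atoms: [1, 2, 3]
  ion: "[M-57]+"
  correction_formula: {C: 8, H: 26, N: 1, O: 2, Si: 2}
- fragment_id: Ser_m57
  metabolite: PGA
  atoms: [1, 2, 3]
  ion: "[M-57]+"
  correction_formula: {C: 14, H: 40, N: 1, O: 3, Si: 3}
- fragment_id: Asp_m57
  metabolite: OAA
  atoms: [1, 2, 3, 4]
  ion: "[M-57]+"
  correction_formula: {C: 14, H: 40, N: 1, O: 4, Si: 3}
- fragment_id: Glu_m57
  metabolite: AKG
  atoms: [1, 2, 3, 4, 5]
  ion: "[M-57]+"
  correction_formula: {C: 14, H: 42, N: 1, O: 4, Si: 3}
- fragment_id: Lys_m57
  metabolite: LYS
  atoms: [1, 2, 3, 4, 5, 6]
  ion: "[M-57]+"
  correction_formula: {C: 14, H: 47, N: 2, O: 2, Si: 3}
- fragment_id: Avd_m57
  metabolite: AVD
  atoms: [1, 2, 3, 4, 5]
  ion: "[M-57]+"
  correction_formula: {C: 8, H: 31, N: 2, O: 1, Si: 2}
- fragment_id: Rib_m57
  metabolite: P5P
  atoms: [1, 2, 3, 4, 5]
  ion: "[M-57]+"
  correction_formula: {C: 14, H: 40, O: 8, Si: 3, P: 1}
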