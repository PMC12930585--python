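# Natural isotope abundances (IUPAC 2013 representative values), as
# probability of a +0, +1, +2 ... Da mass shift per atom of the element.
# Pinned as shipped data so corrected MIDs are bit-stable across versions.
H: [0.999885, 0.000115]
C: [0.9893, 0.0107]
N: [0.99636, 0.00364]
O: [0.99757, 0.00038, 0.00205]
Si: [0.92223, 0.04685, 0.03092]
S: [0.9499, 0.0075, 0.0425, 0.0, 0.0001]
P: [1.0]
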