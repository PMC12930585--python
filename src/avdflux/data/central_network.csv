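# Central carbon metabolism of lysine/5-AVD producing C. glutamicum:
# EMP glycolysis, oxidative/non-oxidative PP pathway, TCA cycle with
# anaplerosis (PEP carboxylase) and malic enzyme back-flux, glutamate
# dehydrogenase, the aspartate/diaminopimelate route to lysine (lumped,
# with meso-DAP scrambling), the DavB step to 5-aminovaleramide, and the
# NADP+-dependent GapN bypass at the GAP node.  Atom transitions follow
# the letter-string convention; cofactors are signed (+ produced).
rxn_id,equation,atom_transitions,reversible,cofactors
upt,GLC.ext -> G6P,abcdef -> abcdef,0,ATP:-1
pgi,G6P -> F6P,abcdef -> abcdef,1,
pfk_ald,F6P -> GAP + GAP,abcdef -> cba + def,0,ATP:-1
gapdh,GAP -> PGA,abc -> abc,0,NADH:1 ATP:1
gapn,GAP -> PGA,abc -> abc,0,NADPH:1
eno,PGA -> PEP,abc -> abc,0,
pyk,PEP -> PYR,abc -> abc,0,ATP:1
oxppp,G6P -> P5P + CO2,abcdef -> bcdef + a,0,NADPH:2
tkt1,P5P + P5P -> S7P + GAP,abcde + ABCDE -> abABCDE + cde,1,
tal,S7P + GAP -> F6P + E4P,abcdefg + ABC -> abcABC + defg,1,
tkt2,P5P + E4P -> F6P + GAP,abcde + ABCD -> abABCD + cde,1,
pdh,PYR -> ACA + CO2,abc -> bc + a,0,NADH:1
cs_icd,OAA + ACA -> AKG + CO2,abcd + ef -> dcbfe + a,0,NADPH:1
akgdh_fum,AKG -> MAL + CO2,abcde -> bcde + a; abcde -> edcb + a,0,NADH:2 ATP:1
mdh,MAL -> OAA,abcd -> abcd,0,NADH:1
pepc,PEP + CO2 -> OAA,abc + d -> abcd,0,
mae,MAL -> PYR + CO2,abcd -> abc + d,0,NADPH:1
gdh,AKG -> GLU,abcde -> abcde,0,NADPH:-1 NH4:-1
aat,OAA + GLU -> ASP + AKG,abcd + ABCDE -> abcd + ABCDE,0,
lys_syn,ASP + PYR -> LYS + CO2,abcd + efg -> abcdgf + e; abcd + efg -> efgdcb + a,0,NADPH:-3 NH4:-2 ATP:-1
davb,LYS -> AVD + CO2,abcdef -> bcdef + a,0,O2:-1
lys_out,LYS -> LYS.ext,abcdef -> abcdef,0,
avd_out,AVD -> AVD.ext,abcde -> abcde,0,
co2_out,CO2 -> CO2.ext,a -> a,0,
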