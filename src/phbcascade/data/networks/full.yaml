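# Full 19-reaction maltodextrin -> PHB cascade.
#
# Maltodextrin is modelled as a boundary pool of glucose units (C6H10O5,
# mM glucose equivalent); PHB as a boundary pool of monomer units (C4H6O2).
# CoA and NADP(H) use opaque moiety tokens (CoAm, NADPm) plus explicit
# C/H/O counts for the transferable acyl / hydride part, so every reaction
# balances C, H, O and P exactly once H2O is written.
variant: full
species:
  - {id: MD,      name: maltodextrin glucose-unit pool, role: boundary,
     composition: {C: 6, H: 10, O: 5}}
  - {id: PHB,     name: PHB monomer pool, role: boundary,
     composition: {C: 4, H: 6, O: 2}}
  - {id: CO2,     name: carbon dioxide, role: boundary,
     composition: {C: 1, O: 2}}
  - {id: H2O,     name: water, role: boundary,
     composition: {H: 2, O: 1}}
  - {id: Pi,      name: inorganic phosphate, role: internal,
     composition: {H: 3, O: 4, P: 1}}
  - {id: G1P,     name: glucose 1-phosphate, role: internal,
     composition: {C: 6, H: 13, O: 9, P: 1}}
  - {id: G6P,     name: glucose 6-phosphate, role: internal,
     composition: {C: 6, H: 13, O: 9, P: 1}}
  - {id: 6PG,     name: 6-phosphogluconate, role: internal,
     composition: {C: 6, H: 13, O: 10, P: 1}}
  - {id: Ru5P,    name: ribulose 5-phosphate, role: internal,
     composition: {C: 5, H: 11, O: 8, P: 1}}
  - {id: Xu5P,    name: xylulose 5-phosphate, role: internal,
     composition: {C: 5, H: 11, O: 8, P: 1}}
  - {id: R5P,     name: ribose 5-phosphate, role: internal,
     composition: {C: 5, H: 11, O: 8, P: 1}}
  - {id: F6P,     name: fructose 6-phosphate, role: internal,
     composition: {C: 6, H: 13, O: 9, P: 1}}
  - {id: E4P,     name: erythrose 4-phosphate, role: internal,
     composition: {C: 4, H: 9, O: 7, P: 1}}
  - {id: S7P,     name: sedoheptulose 7-phosphate, role: internal,
     composition: {C: 7, H: 15, O: 10, P: 1}}
  - {id: G3P,     name: glyceraldehyde 3-phosphate, role: internal,
     composition: {C: 3, H: 7, O: 6, P: 1}}
  - {id: DHAP,    name: dihydroxyacetone phosphate, role: internal,
     composition: {C: 3, H: 7, O: 6, P: 1}}
  - {id: F16P,    name: fructose 1,6-bisphosphate, role: internal,
     composition: {C: 6, H: 14, O: 12, P: 2}}
  - {id: AcP,     name: acetyl phosphate, role: internal,
     composition: {C: 2, H: 5, O: 5, P: 1}}
  - {id: CoA,     name: coenzyme A, role: internal,
     composition: {CoAm: 1}}
  - {id: AcCoA,   name: acetyl-CoA, role: internal,
     composition: {CoAm: 1, C: 2, H: 2, O: 1}}
  - {id: AcAcCoA, name: acetoacetyl-CoA, role: internal,
     composition: {CoAm: 1, C: 4, H: 4, O: 2}}
  - {id: HBCoA,   name: 3-hydroxybutyryl-CoA, role: internal,
     composition: {CoAm: 1, C: 4, H: 6, O: 2}}
  - {id: NADP,    name: NADP+, role: internal,
     composition: {NADPm: 1}}
  - {id: NADPH,   name: NADPH, role: internal,
     composition: {NADPm: 1, H: 2}}
reactions:
  - {id: aGP,   name: alpha-glucan phosphorylase, reversible: true,
     stoich: {MD: -1, Pi: -1, G1P: 1}}
  - {id: PGM,   name: phosphoglucomutase, reversible: true,
     stoich: {G1P: -1, G6P: 1}}
  - {id: PGI,   name: phosphoglucose isomerase, reversible: true,
     stoich: {G6P: -1, F6P: 1}}
  - {id: G6PDH, name: glucose 6-phosphate dehydrogenase, reversible: false,
     stoich: {G6P: -1, NADP: -1, H2O: -1, 6PG: 1, NADPH: 1}}
  - {id: 6PGDH, name: 6-phosphogluconate dehydrogenase, reversible: false,
     stoich: {6PG: -1, NADP: -1, Ru5P: 1, CO2: 1, NADPH: 1}}
  - {id: RPE,   name: ribulose 5-phosphate 3-epimerase, reversible: true,
     stoich: {Ru5P: -1, Xu5P: 1}}
  - {id: RPI,   name: ribose 5-phosphate isomerase, reversible: true,
     stoich: {Ru5P: -1, R5P: 1}}
  - {id: TK1,   name: transketolase reaction 1, reversible: true,
     stoich: {Xu5P: -1, R5P: -1, S7P: 1, G3P: 1}}
  - {id: TK2,   name: transketolase reaction 2, reversible: true,
     stoich: {Xu5P: -1, E4P: -1, G3P: 1, F6P: 1}}
  - {id: TAL,   name: transaldolase, reversible: true,
     stoich: {S7P: -1, G3P: -1, E4P: 1, F6P: 1}}
  - {id: TIM,   name: triose phosphate isomerase, reversible: true,
     stoich: {G3P: -1, DHAP: 1}}
  - {id: ALD,   name: fructose-bisphosphate aldolase, reversible: true,
     stoich: {DHAP: -1, G3P: -1, F16P: 1}}
  - {id: FBP,   name: fructose 1,6-bisphosphatase, reversible: false,
     stoich: {F16P: -1, H2O: -1, F6P: 1, Pi: 1}}
  - {id: XPK,   name: xylulose 5-phosphate phosphoketolase, reversible: false,
     stoich: {Xu5P: -1, Pi: -1, AcP: 1, G3P: 1, H2O: 1}}
  - {id: FPK,   name: fructose 6-phosphate phosphoketolase, reversible: false,
     stoich: {F6P: -1, Pi: -1, AcP: 1, E4P: 1, H2O: 1}}
  - {id: PTA,   name: phosphate acetyltransferase, reversible: true,
     stoich: {AcP: -1, CoA: -1, AcCoA: 1, Pi: 1}}
  - {id: PhaA,  name: acetyl-CoA acetyltransferase, reversible: true,
     stoich: {AcCoA: -2, AcAcCoA: 1, CoA: 1}}
  - {id: PhaB,  name: acetoacetyl-CoA reductase, reversible: false,
     stoich: {AcAcCoA: -1, NADPH: -1, HBCoA: 1, NADP: 1}}
  - {id: PhaC,  name: PHB synthase, reversible: false,
     stoich: {HBCoA: -1, PHB: 1, CoA: 1}}
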