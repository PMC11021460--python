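# Model 2 (synthetic stand-in): Model 1 after the second calibration round,
# which adjusts only the alpha-glucan phosphorylase equilibrium constant
# (less favorable phosphorolysis on shortened dextrins) and the PhaC
# binding coefficient (stronger product binding).
reactions:
  aGP:
    vmax: 1.0
    km:
      MD: 5.0
      Pi: 1.0
      G1P: 0.1
    keq: 0.05
  PGM:
    vmax: 1.0
    km:
      G1P: 0.1
      G6P: 0.1
    keq: 17.0
  PGI:
    vmax: 1.0
    km:
      G6P: 0.1
      F6P: 0.1
    keq: 0.3
  G6PDH:
    vmax: 1.0
    km:
      G6P: 0.1
      NADP: 0.1
  6PGDH:
    vmax: 1.0
    km:
      6PG: 0.1
      NADP: 0.1
  RPE:
    vmax: 1.0
    km:
      Ru5P: 0.1
      Xu5P: 0.1
    keq: 1.5
  RPI:
    vmax: 1.0
    km:
      Ru5P: 0.1
      R5P: 0.1
    keq: 2.3
  TK1:
    vmax: 1.0
    km:
      Xu5P: 0.02
      R5P: 0.02
      S7P: 0.1
      G3P: 0.1
    keq: 1.2
  TK2:
    vmax: 1.0
    km:
      Xu5P: 0.02
      E4P: 0.02
      G3P: 0.1
      F6P: 0.1
    keq: 10.0
  TAL:
    vmax: 1.0
    km:
      S7P: 0.1
      G3P: 0.1
      E4P: 0.1
      F6P: 0.1
    keq: 1.05
  TIM:
    vmax: 1.0
    km:
      G3P: 0.1
      DHAP: 0.1
    keq: 22.0
  ALD:
    vmax: 1.0
    km:
      DHAP: 0.1
      G3P: 0.1
      F16P: 0.1
    keq: 10.0
  FBP:
    vmax: 1.0
    km:
      F16P: 0.1
  XPK:
    vmax: 1.0
    km:
      Xu5P: 0.02
      Pi: 0.5
  FPK:
    vmax: 0.12
    km:
      F6P: 0.02
      Pi: 0.5
  PTA:
    vmax: 1.0
    km:
      AcP: 0.02
      CoA: 0.02
      AcCoA: 0.1
      Pi: 1.0
    keq: 60.0
  PhaA:
    vmax: 1.0
    km:
      AcCoA: 0.2
      AcAcCoA: 0.01
      CoA: 0.1
    keq: 4.0e-05
  PhaB:
    vmax: 1.0
    km:
      AcAcCoA: 0.005
      NADPH: 0.02
  PhaC:
    vmax: 1.0
    km:
      HBCoA: 0.1
    c_bind: 400.0
    n: 1.0
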