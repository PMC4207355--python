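# Solventogenic (stationary) phase: acetate and butyrate supplied as
# additional nutrients, export of the acids shut off (uptake only), and a
# growth pin at the wild-type solventogenic rate of 0.32 h^-1.  Amino-acid
# export caps must be added per model (the exchange list is model-specific).
phase: solventogenic
pinned_growth: 0.32
nutrient_bounds:
  EX_glc__D_e: [-10.0, 0.0]
  EX_ac_e: [-1000.0, 0.0]
  EX_but_e: [-1000.0, 0.0]
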