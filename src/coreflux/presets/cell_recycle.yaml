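# Cell recycle: ammonia and phosphate uptake limited to 80% of the FVA
# maximal uptake at the wild-type optimum (compute the bounds with
# restrict_uptake_fraction and merge them in), growth at 0.17 h^-1.
phase: solventogenic
pinned_growth: 0.17
nutrient_bounds:
  EX_glc__D_e: [-10.0, 0.0]
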