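# Glycerol co-feed: glycerol uptake at 20 mmol gDW^-1 h^-1 (equivalent
# carbon flux to glucose at 10); the glycerol uptake reaction must exist
# in (or be added to) the model.
phase: acidogenic
pinned_growth: null
nutrient_bounds:
  EX_glyc_e: [-20.0, 0.0]
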