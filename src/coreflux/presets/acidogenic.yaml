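# Acidogenic (exponential growth) phase: glucose as sole carbon source at
# 10 mmol gDW^-1 h^-1, no additional constraints.  Exchange ids follow the
# BiGG-style convention and should be overridden to match the model in use.
phase: acidogenic
pinned_growth: null
nutrient_bounds:
  EX_glc__D_e: [-10.0, 0.0]
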