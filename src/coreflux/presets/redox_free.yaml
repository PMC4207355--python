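# Redox-unconstrained: free interconversion of NAD/NADH and NADP/NADPH,
# glucose at 10 mmol gDW^-1 h^-1, no growth pin (product values are each
# product's FVA maximum).
phase: acidogenic
pinned_growth: null
redox_free: true
nutrient_bounds:
  EX_glc__D_e: [-10.0, 0.0]
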