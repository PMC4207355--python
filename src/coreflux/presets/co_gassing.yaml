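# CO gassing: CO inhibits the hydrogenase (flux pinned to zero) and the
# culture takes up butyrate during sparging; growth at 0.47 h^-1.
phase: acidogenic
pinned_growth: 0.47
blocked_reactions: [HYDA]
nutrient_bounds:
  EX_glc__D_e: [-10.0, 0.0]
  EX_but_e: [-1000.0, 0.0]
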