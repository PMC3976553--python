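# Normal (competent) synthetic mitral valve, coarse mesh sized so both
# contact arms of the closure experiment finish in minutes on one CPU.
geometry:
  target_edge_length: 3.0
  annulus: {ap_diameter: 30.0, cc_diameter: 36.0, saddle_height: 4.0}
  leaflets: {anterior_height: 23.0, posterior_height: 16.5}
solver:
  T_end: 0.2
  output_stride: 500
  closure: {annular_area_contraction: 0.3}
contact:
  friction: 0.05
report:
  threshold_kpa: 50.0
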