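# Pathologic synthetic mitral valve with functional regurgitation: dilated
# annulus, apically displaced papillary tips, hypokinetic annular
# contraction.  Same leaflets, chordae and materials as the normal preset.
geometry:
  target_edge_length: 3.0
  annulus: {ap_diameter: 30.0, cc_diameter: 36.0, saddle_height: 4.0}
  leaflets: {anterior_height: 23.0, posterior_height: 16.5}
  pathologic:
    annular_dilation: 1.25
    pm_displacement: [0.0, 0.0, -2.0]
solver:
  T_end: 0.2
  output_stride: 500
  closure: {annular_area_contraction: 0.05}
contact:
  friction: 0.05
report:
  threshold_kpa: 50.0
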