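# Desk-scale demo: one camera field of view over a single ten-capillary
# strip (6 control / 2 gentamicin / 2 ampicillin lanes), fluorescent mode.
# The miniature deck equals one field of view so the scan is a single tile;
# the optics keep the native 29.4 um/pixel pitch of the full instrument.
seed: 7
out_dir: scratch/demo_run
deck: {width_mm: 9.65, depth_mm: 7.2965, z_travel_mm: 130.0}
optics:
  sensor_px: [328, 248]
  fov_mm: [9.65, 7.2965]
scan:
  overlap_frac: 0.0
  interval_min: 30.0
  duration_h: 6.0
  homing: once
scenario:
  pack: ecoli_25922
  mode: fluorescence
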