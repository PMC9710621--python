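# Time-lapse simulation: one colony, frames + ground truth every 6 minutes.
simulation:
  seed: 1
  dt: 0.016666666666666666   # 1 min
  duration: 6.0              # h
  emit_every: 6
  model:
    kind: sizer
    trigger_mean: 3.0
    trigger_cv: 0.12
    rate_cv: 0.1
  fluorescence: 1.0

fluorescence:
  psf_sigma: 2.0
  shot_noise: true

outputs: [frames, masks, coco, trackmate]
output_dir: timelapse_out
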