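# Batch ground-truth dataset: independent colonies, one annotated frame each.
dataset:
  n_images: 128
  image_size: 512
  calibration: 0.09        # µm / pixel
  cell_count_range: [0, 512]
  seed: 0
  emitters: [yolo, coco, masks]

simulation:
  model:
    kind: sizer
    trigger_mean: 3.0      # divide at ~3 µm
    trigger_cv: 0.12
    rate_cv: 0.1

render:
  background_level: 0.7
  cell_level: 0.25
  output_depth: 8

output_dir: dataset_out
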