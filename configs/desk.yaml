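# Desk-scale experiment: 64x64 phantoms, lightweight backbone, CPU-friendly.
phantom:
  image_height: 64
  image_width: 64
  lesion_probability: 0.5
  malignant_fraction: 0.5
  lesion_radius_range: [5, 9]
  speckle_strength: 0.15
  contrast_lesion: -0.25
  seed: 0
  n_train: 200
  n_val: 50
  n_test: 50
train:
  desk_profile: true
  seed: 0
eval:
  threshold: 0.5
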