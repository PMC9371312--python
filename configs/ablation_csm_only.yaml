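# Fine segmentation from category attention only (no gland-masked self-attention).
phantom:
  image_height: 64
  image_width: 64
  seed: 0
  n_train: 200
  n_val: 50
  n_test: 50
model:
  fine:
    use_csm: true
    use_akgm: false
train:
  desk_profile: true
  seed: 0
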