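# Reference-scale profile: 256x256 inputs, VGG16 backbone, Adam 1e-4,
# batch 16, up to 100 epochs with patience 10. Intended for GPU-scale or
# patient overnight CPU runs; not exercised by the test suite.
phantom:
  image_height: 256
  image_width: 256
  lesion_radius_range: [16, 36]
  seed: 0
  n_train: 2000
  n_val: 400
  n_test: 400
model:
  image_size: 256
  backbone:
    kind: vgg16
    channels: 64
    aspp_rates: [1, 2, 4]
    stride: 8
    pretrained: false
  cls:
    d1: 32
    num_classes: 2
train:
  learning_rate: 0.0001
  max_epochs: 100
  batch_size: 16
  patience: 10
  seed: 0
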