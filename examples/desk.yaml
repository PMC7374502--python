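# Desk-scale setup: 128x128 synthetic scenes, small 3-stage backbone,
# learning rate suited to training from scratch. Omitted keys keep package
# defaults (see penseg.config).
scene:
  image_size: [128, 128]
  n_animals: [3, 8]
  seed: 1

network:
  stages: 4
  base_width: 8
  embedding_dim: 8

train:
  learning_rate: 0.003
  epochs: 50
  batch_size: 2
  seed: 1
  augment: true

postprocess:
  tau: 0.5
  min_pixels: 20
  clustering:
    min_cluster_size: 100
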