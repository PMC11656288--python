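# Desk-scale profile: everything runs on one CPU in minutes.
# A 4-stage segmenter (3 wavelet levels) on 32x32x16 synthetic phantoms.
wavelet:
  family: db2
model:
  stages: 4
  encoder_channels: [4, 8, 16, 16]
  base_resolution: [32, 32, 16]
  sa_reduction: 2
  subband_channels: 4
  seed: 0
refine:
  channels: [4, 8, 16, 16]
  seed: 1
source:
  epochs: 60
  learning_rate: 0.05
  momentum: 0.9
  seed: 0
undertrained:
  stop_epochs: [4, 6, 9, 12, 16, 20]
refine_training:
  epochs: 30
  learning_rate: 0.2
  momentum: 0.9
  seed: 0
tta:
  iterations: 200
  learning_rate: 0.0005
  momentum: 0.0
  lambda1: 0.5
  lambda2: 1.0
  ablation: total
  seed: 0
synthetic:
  extents: [32, 32, 16]
  fg_range: [0.02, 0.10]
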