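# Full-scale profile matching the published experimental setup.
# Requires GPU-scale compute; provided for reference, not for CPU runs.
wavelet:
  family: db2          # Daubechies family; the order is a documented choice
model:
  stages: 5            # four-level wavelet fusion into encoder stages 2-5
  encoder_channels: [16, 32, 64, 128, 256]
  base_resolution: [256, 256, 64]
  sa_reduction: 2
  subband_channels: 8
  seed: 0
refine:
  channels: [16, 32, 64, 64]
  seed: 1
source:
  epochs: 2000
  learning_rate: 0.0005
  momentum: 0.0
  seed: 0
undertrained:
  stop_epochs: [30, 40, 50, 60, 70, 80]
refine_training:
  epochs: 1000
  learning_rate: 0.0005
  momentum: 0.0
  seed: 0
tta:
  iterations: 200
  learning_rate: 0.0005
  momentum: 0.0
  lambda1: 0.5
  lambda2: 1.0
  ablation: total
  seed: 0
preprocess:
  target_spacing: [1.5, 1.5, 1.5]   # liver protocol; prostate uses 0.7 isotropic
  target_extents: [256, 256, 64]
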