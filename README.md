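# wavtta

Single-sample test-time adaptation (TTA) for 3-D binary segmentation with a
wavelet-attention V-Net, implemented in pure scientific Python (numpy/scipy
plus a small built-in reverse-mode autodiff engine — no deep-learning
framework required).

## What it does

A V-Net-style 3-D segmenter is augmented with a *wavelet attention module*:
a multilevel separable discrete wavelet transform of the input volume
produces eight sub-bands per level; each level's bands are gated by a
learned channel-attention block (pool + two fully connected stages +
sigmoid) and fused into the matching-resolution encoder stage.

The pipeline follows a source-training / per-sample-adaptation scheme:

1. **Source training** — supervised Dice-loss training (SGD, batch size 1);
   the mean foreground class ratio of the training labels is stored as a
   shape prior.
2. **Undertrained corpus** — snapshots of an early-stopped training run
   predict on the training set, yielding realistic broken segmentations.
3. **Refine model** — a four-stage encoder/decoder with sigmoid head is
   trained (MSE) to map broken segmentations to their labels.
4. **Single-sample TTA** — for each unlabeled test volume the model is
   reset to the source checkpoint; only the sub-band attention blocks and
   batch-norm affine parameters are optimized (200 SGD steps, lr 5e-4) on a
   hybrid unsupervised objective

   `L = 0.5 * L_entropy + 1.0 * L_shape + L_refine`

   combining per-voxel two-class Shannon entropy, a symmetric Bernoulli-KL
   between the predicted soft foreground ratio and the source class-ratio
   prior, and the MSE between the prediction and its refine-model
   reconstruction.  Batch-norm layers normalize with the test sample's own
   statistics.

Evaluation uses the Dice coefficient and the 95th-percentile symmetric
surface distance (HD95, in mm).

A seeded synthetic benchmark (`wavtta.synthetic`) generates single-organ
phantoms and intensity-only domain shifts (gamma, polynomial bias field,
Gaussian noise, optional inversion) at `mild` / `moderate` / `strong`
presets, so the entire pipeline is testable offline at desk scale.

## CLI

`examples/desk.yaml` is a CPU-friendly profile (4-stage model, 32x32x16
phantoms); `examples/paper.yaml` documents the full-scale configuration
(5 stages, 256x256x64, 2000 source epochs — GPU territory).

```bash
# synthetic benchmark with manifest (bit-exactly regenerable)
wavtta simulate --preset strong --seed 0 --n-source 6 --n-target 10 \
    --extents 32,32,16 --out runs/sim

# source training (stores the class-ratio prior + early-stop snapshots)
wavtta train-source --config examples/desk.yaml --data runs/sim --out runs/src

# undertrained corpus and refine model
wavtta make-undertrained --config examples/desk.yaml --data runs/sim --out runs/corpus
wavtta train-refine --config examples/desk.yaml --corpus runs/corpus --out runs/refine

# adapt to one unlabeled volume (--iterations 0 = no-adaptation baseline)
wavtta adapt --config examples/desk.yaml --checkpoint runs/src/source.ckpt \
    --refine runs/refine/refine.ckpt --volume runs/sim/target/volume_000.nii.gz \
    --out runs/adapt0

# metrics and the six-way loss ablation
wavtta evaluate --pred runs/preds --ref runs/refs --out metrics.csv
wavtta ablation --config examples/desk.yaml --checkpoint runs/src/source.ckpt \
    --refine runs/refine/refine.ckpt --data runs/sim --out ablation.csv
```

## Package layout

| module | contents |
| --- | --- |
| `wavtta.wavelet` | periodized orthonormal multilevel 3-D DWT/IDWT (Daubechies haar/db2/db3/db4) |
| `wavtta.nn` | minimal numpy autodiff engine, conv/BN/linear layers, SGD |
| `wavtta.models` | wavelet-attention segmenter, refine network, parameter partition, checkpoints |
| `wavtta.losses` | Dice, entropy, symmetric class-ratio KL, refine MSE, weighted total |
| `wavtta.tta` | source training, undertrained corpus, refine training, single-sample adaptation, ablation |
| `wavtta.metrics` | Dice, HD95 (pooled symmetric, mm), mean +/- SD summaries |
| `wavtta.synthetic` | seeded phantoms, domain-shift presets, benchmark bundles with manifests |
| `wavtta.io_cli` | NIfTI I/O + preprocessing, YAML config, `wavtta` CLI |

## Notes

- Everything is seeded; adaptation of each sample starts fresh from the
  source checkpoint, so per-sample results are order-independent.
- The wavelet transform uses periodization (ceil-halving extents, exact
  reconstruction); odd extents are handled by last-sample duplication.
- Convolution GEMMs run internally in float32 for CPU speed; the autodiff
  graph and all loss values are float64.
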