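# polypvit

Reference implementation of a colon-polyp segmentation architecture that
combines three pieces:

* **Adaptive deformable convolutional backbone** — four residual blocks whose
  final convolutions are modulated by an attention map derived from the
  block's own activations.  The map reweights the kernel taps and produces
  per-kernel-row/column sampling offsets that are read with bilinear
  interpolation (zero outside the frame).
* **Conditional positional encoding** — token embeddings generated from the
  token content itself by a depthwise 3x3 convolution (a Position Encoding
  Generator), instead of fixed or learned absolute tables.
* **Transformer encoder–decoder with class query tokens** — a pre-norm
  four-block encoder, and a decoder in which two learnable query tokens
  (background, polyp) cross-attend to the encoded features; per-patch class
  logits are the inner products between features and query embeddings,
  bilinearly upsampled and argmax-ed (ties toward background).

Everything runs on plain NumPy: the package ships a small reverse-mode
autodiff engine (`polypvit.autodiff`) so the model trains end to end with
Adam on one CPU — no deep-learning framework required.  A seeded synthetic
colonoscopy-like image generator makes the whole pipeline trainable and
testable with no downloads.

## Layout

| module | contents |
| --- | --- |
| `polypvit.autodiff` | NumPy tensor autodiff (conv2d, bilinear shifts, matmul, softmax, ...) |
| `polypvit.nn` | parameter containers, Adam |
| `polypvit.synthetic` | seeded image/mask generator + Kvasir-style writer |
| `polypvit.data_io` | paired-folder loading, 256x256 preprocessing, affine augmentation, 80:20 + k-fold splits |
| `polypvit.adcn` | attention maps, kernel modulation/averaging, offsets, deformable convolution, backbone |
| `polypvit.cpe` | patch extraction, PEG embeddings, token/position combination |
| `polypvit.transformer` | layer norm, MHSA/MHCA, encoder, query-token decoder, mask head |
| `polypvit.model` | `ArchConfig` + the assembled `PolypViT` (full and ablated variants) |
| `polypvit.training` | loss, lr schedule, channel dropout, training loop, checkpoints |
| `polypvit.evaluation` | confusion/overlap metrics, k-fold cross-validation harness |
| `polypvit.cli` | `polypvit synth|train|evaluate|predict` |

## CLI

All commands share `--config <yaml>`, dotted `--set key=value` overrides,
`--seed N` and `--out DIR`, and write a `manifest.json` recording the
resolved configuration.  Exit codes: 0 ok, 2 config error, 3 data error.

```bash
# 1. generate a synthetic dataset (images/*.jpg + masks/*.png)
polypvit synth -n 100 --seed 0 --out data/synth \
    --set synthetic.image_size=64

# 2. train a tiny model on it
polypvit train --data data/synth --seed 0 --out runs/demo \
    --set arch.image_size=64 --set arch.widths=[8,16,32,32] \
    --set arch.strides=[2,2,1,1] --set arch.d_model=32 \
    --set arch.heads=4 --set arch.depth=2 --set train.epochs=10

# 3. evaluate the checkpoint (or run k-fold CV with --folds 5)
polypvit evaluate --data data/synth --checkpoint runs/demo/checkpoint.npz \
    --out runs/demo/eval --set arch.image_size=64 ...

# 4. predict masks for a folder of images
polypvit predict --checkpoint runs/demo/checkpoint.npz \
    --input data/synth/images --out runs/demo/pred
```

Real datasets in the Kvasir-seg / CVC-ClinicDB folder convention
(`<root>/images/*.jpg|png|tif`, `<root>/masks/*.png|tif`) are loaded the same
way; inputs are resized to the configured working size (256x256 by default)
with bilinear (images) / nearest + midpoint-threshold binarization (masks).

The ablated variant (`--set train.ablation=resnet_only`) replaces the
deformable convolutions with plain ones and the conditional embeddings with
a learned absolute position table, keeping encoder/decoder identical.

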