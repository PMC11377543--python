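"""Full segmentation model: deformable backbone + CPE + encoder-decoder.

:class:`PolypViT` wires the pieces end to end: the four-block deformable
residual backbone extracts a feature grid, cells are tokenized (patch size 1)
and linearly projected to the model dimension, the PEG adds conditional
positional embeddings, the transformer encoder contextualizes the tokens,
and the query-token decoder produces per-class embeddings whose inner
products with the encoded features become the mask logits, bilinearly
upsampled to the input resolution.

The ablated variant (``resnet_only``) replaces the deformable convolutions
with plain ones (no modulation, zero offsets) and the conditional embeddings
with a learned absolute position table; encoder and decoder are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .adcn import DeformableBackbone
from .cpe import depthwise_conv3x3
from .nn import Module, he_normal, normal_init
from . import transformer as tf

__all__ = ["ArchConfig", "PolypViT"]


@dataclass
class ArchConfig:
    """Architecture hyperparameters.  Defaults are the full-scale settings
    (256x256 input, stride-16 backbone, d=256, 8 heads, depth 4)."""

    image_size: int = 256
    in_channels: int = 3
    widths: tuple[int, ...] = (64, 128, 256, 512)
    strides: tuple[int, ...] = (2, 2, 2, 2)
    d_model: int = 256
    heads: int = 8
    depth: int = 4
    mlp_ratio: int = 4
    n_classes: int = 2
    deform_mode: str = "base_grid"
    cross_residual: bool = True

    def __post_init__(self):
        self.widths = tuple(self.widths)
        self.strides = tuple(self.strides)
        if self.d_model % self.heads:
            raise ValueError("d_model must be divisible by heads")
        stride = int(np.prod(self.strides))
        if self.image_size % stride:
            raise ValueError("image_size must be divisible by the backbone stride")

    @property
    def grid(self) -> int:
        return self.image_size // int(np.prod(self.strides))

    @property
    def n_tokens(self) -> int:
        return self.grid * self.grid

    @classmethod
    def tiny(cls) -> "ArchConfig":
        """Desk-scale profile: 64x64 input, 16x16 token grid, d=32."""
        return cls(image_size=64, widths=(8, 16, 32, 32), strides=(2, 2, 1, 1),
                   d_model=32, heads=4, depth=2)


def _norm(d: int) -> tf.NormParams:
    return tf.NormParams(gamma=ad.parameter(np.ones(d)), beta=ad.parameter(np.zeros(d)))


def _attention(rng: np.random.Generator, d: int, heads: int) -> tf.AttentionParams:
    std = 1.0 / np.sqrt(d)
    return tf.AttentionParams(
        wq=ad.parameter(normal_init(rng, (d, d), std)),
        wk=ad.parameter(normal_init(rng, (d, d), std)),
        wv=ad.parameter(normal_init(rng, (d, d), std)),
        wo=ad.parameter(normal_init(rng, (d, d), std)),
        heads=heads,
    )


def _mlp(rng: np.random.Generator, d: int, ratio: int) -> tf.MlpParams:
    hidden = ratio * d
    return tf.MlpParams(
        w1=ad.parameter(normal_init(rng, (d, hidden), np.sqrt(2.0 / d))),
        b1=ad.parameter(np.zeros(hidden)),
        w2=ad.parameter(normal_init(rng, (hidden, d), np.sqrt(2.0 / hidden))),
        b2=ad.parameter(np.zeros(d)),
    )


class PolypViT(Module):
    """End-to-end trainable segmentation model (NumPy autodiff backed)."""

    def __init__(self, arch: ArchConfig | None = None, ablation: str = "full",
                 seed: int = 0):
        if ablation not in ("full", "resnet_only"):
            raise ValueError(f"unknown ablation key {ablation!r}")
        self.arch = arch or ArchConfig()
        self.ablation = ablation
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        a = self.arch
        self.backbone = DeformableBackbone(
            in_channels=a.in_channels, widths=a.widths, strides=a.strides,
            deform_mode=a.deform_mode, rng=rng)
        c_out = self.backbone.out_channels
        self.proj_w = ad.parameter(he_normal(rng, (c_out, a.d_model), c_out))
        self.proj_b = ad.parameter(np.zeros(a.d_model))
        if ablation == "full":
            self.peg_kernel = ad.parameter(normal_init(rng, (a.d_model, 3, 3), 0.1))
            self.abs_pos = None
        else:
            self.peg_kernel = None
            self.abs_pos = ad.parameter(normal_init(rng, (a.n_tokens, a.d_model), 0.1))
        self.enc_blocks = [
            tf.EncoderBlockParams(ln1=_norm(a.d_model),
                                  attn=_attention(rng, a.d_model, a.heads),
                                  ln2=_norm(a.d_model),
                                  mlp=_mlp(rng, a.d_model, a.mlp_ratio))
            for _ in range(a.depth)
        ]
        self.queries = tf.QueryTokens(
            tokens=ad.parameter(normal_init(rng, (a.n_classes, a.d_model), 1.0)),
            n_classes=a.n_classes)
        self.decoder = tf.DecoderParams(
            ln_q=_norm(a.d_model),
            self_attn=_attention(rng, a.d_model, a.heads),
            ln_cross=_norm(a.d_model),
            cross_attn=_attention(rng, a.d_model, a.heads),
            ln_mlp=_norm(a.d_model),
            mlp=_mlp(rng, a.d_model, a.mlp_ratio),
            cross_residual=a.cross_residual)

    # -- forward ----------------------------------------------------------
    def tokens_from_images(self, x):
        """Backbone + projection: (N,3,H,W) -> (N, n, d) tokens plus grid."""
        feat = self.backbone.forward(x, deformable=(self.ablation == "full"))
        n, c, gh, gw = feat.data.shape if ad.is_tensor(feat) else feat.shape
        tokens = ad.transpose(ad.reshape(feat, (n, c, gh * gw)), (0, 2, 1))
        tokens = ad.add(ad.matmul(tokens, self.proj_w), self.proj_b)
        return tokens, (gh, gw)

    def add_positions(self, tokens, grid_shape):
        if self.ablation == "full":
            n, ntok, d = tokens.data.shape if ad.is_tensor(tokens) else tokens.shape
            gh, gw = grid_shape
            grid = ad.transpose(ad.reshape(tokens, (n, gh, gw, d)), (0, 3, 1, 2))
            emb = depthwise_conv3x3(grid, self.peg_kernel)
            emb = ad.transpose(ad.reshape(emb, (n, d, gh * gw)), (0, 2, 1))
            return ad.add(tokens, emb)
        return ad.add(tokens, self.abs_pos)

    def forward(self, images, train: bool = False, dropout_p: float = 0.0,
                dropout_site: str = "none", dropout_rng=None):
        """Images (N,3,H,W) in [0,1] -> mask logits tensor (N,2,H,W)."""
        from .training import channel_dropout  # local import avoids a cycle

        x = np.asarray(images, dtype=np.float64) if not ad.is_tensor(images) else images
        shape = x.shape if not ad.is_tensor(x) else x.data.shape
        h, w = shape[-2:]
        tokens, grid_shape = self.tokens_from_images(x)
        tokens = self.add_positions(tokens, grid_shape)
        enc = tf.encode(tokens, self.enc_blocks)
        features = enc.features
        if train and dropout_site == "encoder_out" and dropout_p > 0:
            features = channel_dropout(features, dropout_p, dropout_rng)
        dec = tf.decode(features, self.queries, self.decoder)
        qe = dec.z5
        if train and dropout_site == "decoder_out" and dropout_p > 0:
            qe = channel_dropout(qe, dropout_p, dropout_rng)
        logits = tf.logits_to_grid(features, qe, grid_shape)
        return tf.upsample_logits(logits, (h, w))

    def predict(self, images) -> np.ndarray:
        """Predicted masks (N,H,W) uint8 {0,1}; ties break toward background."""
        arr = np.asarray(images, dtype=np.float64)
        single = arr.ndim == 3
        if single:
            arr = arr[None]
        with ad.no_grad():
            logits = self.forward(arr)
        data = logits.data if ad.is_tensor(logits) else logits
        labels = (data[:, 1] > data[:, 0]).astype(np.uint8)
        return labels[0] if single else labels

    def predict_mask(self, image_hwc: np.ndarray) -> np.ndarray:
        """Convenience for a single H x W x 3 image."""
        return self.predict(np.transpose(image_hwc, (2, 0, 1)))

    def config_dict(self) -> dict:
        return {"arch": asdict(self.arch), "ablation": self.ablation, "seed": self.seed}
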