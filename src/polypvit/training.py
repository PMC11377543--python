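"""Loss, learning-rate schedule, channel dropout, model assembly and training.

The loss is the standard per-pixel negative log-likelihood of the true class,
averaged over pixels and batch.  (The printed loss formula lacks the negative
sign and the ground-truth indicator; as printed it is not minimized by
correct predictions, so the conventional reading is executed and the printed
form lives only in this comment.)

The schedule multiplies the initial rate by ``decay_factor`` every
``decay_period`` epochs: lr = lr0 * factor^floor(epoch / period).  With the
stated defaults (0.001, 0.01, 20) training effectively freezes after epoch
40, which is why the factor is configurable.

All randomness (batch order, dropout, parameter init) is driven by explicit
seeds; with dropout off, two runs with the same seed are identical step for
step.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .model import ArchConfig, PolypViT
from .nn import Adam
from .synthetic import LabeledImage

__all__ = [
    "TrainConfig",
    "TrainingDivergedError",
    "cross_entropy_loss",
    "lr_at_epoch",
    "channel_dropout",
    "build_model",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    lr0: float = 0.001
    decay_factor: float = 0.01
    decay_period: int = 20
    epochs: int = 15
    batch_size: int = 4
    dropout_prob: float = 0.0
    dropout_site: str = "none"  # encoder_out | decoder_out | none
    seed: int = 0
    ablation: str = "full"      # full | resnet_only
    literal_update: bool = False  # apply the printed kernel rule after each step
    max_steps: int | None = None
    stop_at_val_dice: float | None = None  # optional early stop once reached
    shuffle: bool = True

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not 0 < self.decay_factor <= 1:
            raise ValueError("decay_factor must be in (0, 1]")
        if self.decay_period < 1:
            raise ValueError("decay_period must be >= 1")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.dropout_site not in ("encoder_out", "decoder_out", "none"):
            raise ValueError(f"unknown dropout site {self.dropout_site!r}")


class TrainingDivergedError(RuntimeError):
    pass


def cross_entropy_loss(probabilities, labels, check: bool = True):
    """Mean negative log-likelihood of the true class per pixel.

    ``probabilities`` holds per-pixel class distributions with the class axis
    third from the end — (C, H, W) or (N, C, H, W) — and ``labels`` the
    integer masks of matching shape without the class axis.  Probabilities at
    the true label are clamped at 1e-12 before the log.
    """
    labels_arr = np.asarray(labels)
    probs_data = probabilities.data if ad.is_tensor(probabilities) else np.asarray(probabilities)
    n_classes = probs_data.shape[-3]
    if check:
        if not np.isin(labels_arr, np.arange(n_classes)).all():
            raise ValueError("labels must be valid class indices")
        sums = probs_data.sum(axis=-3)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("per-pixel probabilities must sum to 1")
    onehot = np.stack([(labels_arr == j).astype(np.float64) for j in range(n_classes)],
                      axis=-3)
    p_true = ad.tsum(ad.mul(probabilities, onehot), axis=-3)
    return ad.neg(ad.tmean(ad.log(ad.maximum(p_true, 1e-12))))


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """lr0 * decay_factor ** floor(epoch / decay_period)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.lr0 * config.decay_factor ** (epoch // config.decay_period)


def channel_dropout(x, p: float, rng: np.random.Generator, training: bool = True):
    """Zero whole channels with probability p; survivors scaled by 1/(1-p).

    For NCHW feature maps the channel axis is 1; for token sequences
    (N, n, d) or (n, d) the embedding axis is the channel axis.  Identity at
    evaluation time.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if not training or p == 0:
        return x
    shape = x.data.shape if ad.is_tensor(x) else np.asarray(x).shape
    if len(shape) == 4:      # N, C, H, W
        mask_shape = (shape[0], shape[1], 1, 1)
    elif len(shape) == 3:    # N, n, d
        mask_shape = (shape[0], 1, shape[2])
    elif len(shape) == 2:    # n, d
        mask_shape = (1, shape[1])
    else:
        raise ValueError(f"unsupported shape {shape}")
    keep = rng.random(mask_shape) >= p
    if p == 1.0:
        scale = np.zeros(mask_shape)
    else:
        scale = keep.astype(np.float64) / (1.0 - p)
    return ad.mul(x, scale)


def build_model(config: TrainConfig, arch: ArchConfig | None = None,
                seed: int | None = None) -> PolypViT:
    """Assemble the full or ablated model with seeded initialization."""
    return PolypViT(arch=arch, ablation=config.ablation,
                    seed=config.seed if seed is None else seed)


def _apply_literal_update(model: PolypViT, step: float) -> None:
    """Apply the printed kernel rule to each block's deformable weights,
    using the batch-mean pooled attention map cached by the last forward."""
    from .adcn import literal_kernel_update

    for block in model.backbone.blocks:
        if block.last_phi_k is not None:
            updated = literal_kernel_update(block.w2.data, block.last_phi_k, step=step)
            block.w2.data = updated.base


# ---------------------------------------------------------------------------
# training loop

def _stack(pairs: list[LabeledImage]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.image.transpose(2, 0, 1) for p in pairs])
    y = np.stack([np.asarray(p.mask) for p in pairs]).astype(int)
    return x, y


def _dice_binary(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = np.logical_and(pred, truth).sum()
    total = pred.sum() + truth.sum()
    return 1.0 if total == 0 else 2.0 * inter / total


def evaluate_loss_dice(model: PolypViT, pairs: list[LabeledImage],
                       batch_size: int = 8) -> tuple[float, float]:
    """Mean NLL loss and image-averaged Dice on a labelled set."""
    losses, dices = [], []
    for lo in range(0, len(pairs), batch_size):
        chunk = pairs[lo:lo + batch_size]
        x, y = _stack(chunk)
        with ad.no_grad():
            logits = model.forward(x)
        data = logits.data if ad.is_tensor(logits) else logits
        probs = ad.softmax(data, axis=1)
        losses.append(float(cross_entropy_loss(probs, y, check=False)) * len(chunk))
        preds = (data[:, 1] > data[:, 0])
        for i in range(len(chunk)):
            dices.append(_dice_binary(preds[i], y[i] > 0))
    return sum(losses) / len(pairs), float(np.mean(dices))


def train(model: PolypViT, train_pairs: list[LabeledImage],
          val_pairs: list[LabeledImage], config: TrainConfig,
          checkpoint_path: str | Path | None = None,
          verbose: bool = False) -> tuple[list[dict], dict]:
    """Adam training with the decayed schedule; keeps the best-val-Dice state.

    Returns ``(history, best_state)`` where history has one row per epoch
    (epoch, lr, train_loss, val_loss, val_dice) and best_state is a parameter
    ``state_dict``.  Raises :class:`TrainingDivergedError` on NaN loss.
    """
    if not train_pairs:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    opt = Adam(params, lr=config.lr0)
    history: list[dict] = []
    best_dice, best_state = -1.0, model.state_dict()
    steps_done = 0
    for epoch in range(config.epochs):
        opt.lr = lr_at_epoch(epoch, config)
        order = rng.permutation(len(train_pairs)) if config.shuffle \
            else np.arange(len(train_pairs))
        epoch_losses = []
        for lo in range(0, len(order), config.batch_size):
            if config.max_steps is not None and steps_done >= config.max_steps:
                break
            batch = [train_pairs[i] for i in order[lo:lo + config.batch_size]]
            x, y = _stack(batch)
            use_dropout = config.dropout_prob > 0 and config.dropout_site != "none"
            logits = model.forward(
                x, train=True,
                dropout_p=config.dropout_prob if use_dropout else 0.0,
                dropout_site=config.dropout_site if use_dropout else "none",
                dropout_rng=rng if use_dropout else None)
            probs = ad.softmax(logits, axis=1)
            loss = cross_entropy_loss(probs, y, check=False)
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise TrainingDivergedError(
                    f"NaN/Inf loss at epoch {epoch}, step {steps_done}")
            model.zero_grad()
            loss.backward()
            opt.step()
            if config.literal_update and config.ablation == "full":
                _apply_literal_update(model, step=opt.lr)
            epoch_losses.append(loss_val)
            steps_done += 1
        val_loss, val_dice = (float("nan"), float("nan"))
        if val_pairs:
            val_loss, val_dice = evaluate_loss_dice(model, val_pairs)
            if val_dice > best_dice:
                best_dice = val_dice
                best_state = model.state_dict()
        else:
            best_state = model.state_dict()
        row = {
            "epoch": epoch,
            "lr": lr_at_epoch(epoch, config),
            "train_loss": float(np.mean(epoch_losses)) if epoch_losses else float("nan"),
            "val_loss": val_loss,
            "val_dice": val_dice,
        }
        history.append(row)
        if verbose:
            print(f"epoch {epoch:3d}  lr {row['lr']:.2e}  "
                  f"train {row['train_loss']:.4f}  val {val_loss:.4f}  dice {val_dice:.4f}")
        if config.max_steps is not None and steps_done >= config.max_steps:
            break
        if (config.stop_at_val_dice is not None and val_pairs
                and val_dice >= config.stop_at_val_dice):
            break
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path, state=best_state,
                        extra={"best_val_dice": best_dice, "train_config": asdict(config)})
    return history, best_state


def write_history_csv(history: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "lr", "train_loss",
                                                "val_loss", "val_dice"])
        writer.writeheader()
        writer.writerows(history)


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: PolypViT, path: str | Path,
                    state: dict | None = None, extra: dict | None = None) -> None:
    """Single-file checkpoint: parameters + model config (+ metadata)."""
    state = model.state_dict() if state is None else state
    meta = {"config": model.config_dict(), "extra": extra or {}}
    arrays = {f"param/{k}": v for k, v in state.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> tuple[PolypViT, dict]:
    """Rebuild the model from a checkpoint; forward outputs are bit-identical."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    cfg = meta["config"]
    model = PolypViT(arch=ArchConfig(**cfg["arch"]), ablation=cfg["ablation"],
                     seed=cfg["seed"])
    model.load_state_dict(state)
    return model, meta["extra"]


class TrainablePredictor:
    """fit/predict wrapper used by the cross-validation harness."""

    def __init__(self, arch: ArchConfig, config: TrainConfig, seed: int):
        self.config = config
        self.model = build_model(config, arch=arch, seed=seed)

    def fit(self, pairs: list[LabeledImage]) -> list[dict]:
        n_val = max(1, len(pairs) // 10) if len(pairs) > 1 else 0
        val = pairs[:n_val]
        tr = pairs[n_val:] if n_val else pairs
        history, best = train(self.model, tr, val, self.config)
        self.model.load_state_dict(best)
        return history

    def predict_mask(self, image_hwc: np.ndarray) -> np.ndarray:
        return self.model.predict_mask(image_hwc)
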