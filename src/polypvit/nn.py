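"""Light parameter-container and optimizer utilities for the NumPy autodiff core."""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Adam", "he_normal", "normal_init"]


class Module:
    """Base class whose :meth:`parameters` walks attributes recursively.

    Attributes that are trainable :class:`Tensor` leaves, sub-``Module``s, or
    lists/tuples/dicts of those are discovered automatically and returned as a
    flat ``name -> Tensor`` mapping with dotted paths.
    """

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        self._collect("", out)
        return out

    def _collect(self, prefix: str, out: dict[str, Tensor]) -> None:
        for name, value in vars(self).items():
            self._collect_value(f"{prefix}{name}", value, out)

    @staticmethod
    def _collect_value(path: str, value, out: dict[str, Tensor]) -> None:
        if isinstance(value, Tensor):
            if value.requires_grad:
                out[path] = value
        elif isinstance(value, Module):
            value._collect(path + ".", out)
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                Module._collect_value(f"{path}.{i}", item, out)
        elif isinstance(value, dict):
            for k, item in value.items():
                Module._collect_value(f"{path}.{k}", item, out)
        elif dataclasses.is_dataclass(value) and not isinstance(value, type):
            for f in dataclasses.fields(value):
                Module._collect_value(f"{path}.{f.name}", getattr(value, f.name), out)

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    # -- state (de)serialization -------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Adam:
    """Adam optimizer over a name->Tensor parameter mapping."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = dict(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def normal_init(rng: np.random.Generator, shape: tuple, std: float) -> np.ndarray:
    return rng.normal(0.0, std, size=shape)
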