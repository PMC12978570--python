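"""Encoder, projection head, and SimSiam predictor on the autodiff core.

The desk-scale preset is a 4-block strided convolutional encoder over
64x64 single-channel views (each block: 3x3 conv, stride 2, ReLU),
followed by a linear layer to the backbone feature, a 3-layer MLP
projection head, and a 2-layer MLP predictor.  Projections are
L2-normalized before entering any cosine-based objective.  A full-size
ResNet-18 preset is named in the config enum for interface parity but is
not provided by this implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .autodiff import Tensor, conv2d
from .losses import l2_normalize

__all__ = ["ModelConfig", "ContrastiveModel", "Adam"]


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "tiny_cnn"
    input_size: int = 64
    channels: Tuple[int, ...] = (8, 16, 32, 64)
    feature_dim: int = 128
    embed_dim: int = 32
    predictor_hidden: int = 16

    def __post_init__(self):
        if self.backbone == "resnet18":
            raise ValueError(
                "the resnet18 full-size preset is not provided by this build; "
                "use backbone='tiny_cnn'"
            )
        if self.backbone != "tiny_cnn":
            raise ValueError(f"unknown backbone {self.backbone!r}")


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class ContrastiveModel:
    """Student parameters + forward passes for backbone/projection/predictor."""

    def __init__(self, cfg: ModelConfig, rng_seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(rng_seed)
        p: Dict[str, np.ndarray] = {}
        c_in = 1
        for i, c_out in enumerate(cfg.channels):
            p[f"conv{i}_w"] = _he_init(rng, (c_out, c_in, 3, 3), 9 * c_in)
            p[f"conv{i}_b"] = np.zeros(c_out)
            c_in = c_out
        side = cfg.input_size // 2 ** len(cfg.channels)
        flat = c_in * side * side
        p["fc_w"] = _he_init(rng, (flat, cfg.feature_dim), flat)
        p["fc_b"] = np.zeros(cfg.feature_dim)
        d, e = cfg.feature_dim, cfg.embed_dim
        p["proj1_w"] = _he_init(rng, (d, d), d)
        p["proj1_b"] = np.zeros(d)
        p["proj2_w"] = _he_init(rng, (d, d), d)
        p["proj2_b"] = np.zeros(d)
        p["proj3_w"] = _he_init(rng, (d, e), d)
        p["proj3_b"] = np.zeros(e)
        h = cfg.predictor_hidden
        p["pred1_w"] = _he_init(rng, (e, h), e)
        p["pred1_b"] = np.zeros(h)
        p["pred2_w"] = _he_init(rng, (h, e), h)
        p["pred2_b"] = np.zeros(e)
        self.params: Dict[str, Tensor] = {
            k: Tensor(v, requires_grad=True) for k, v in p.items()
        }
        self._flat = flat

    # -- parameter plumbing -------------------------------------------------
    def param_names(self) -> List[str]:
        return sorted(self.params)

    def state_arrays(self) -> Dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_state(self, arrays: Dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = np.asarray(arrays[k], dtype=np.float64).copy()

    # teacher side holds only backbone + projection parameters
    TEACHER_PREFIXES = ("conv", "fc", "proj")

    def teacher_names(self) -> List[str]:
        return [k for k in self.param_names() if k.startswith(self.TEACHER_PREFIXES)]

    # -- forward passes -----------------------------------------------------
    def backbone(self, x: Tensor, params: Dict[str, Tensor] = None) -> Tensor:
        """x: (N, 1, H, W) -> (N, feature_dim)."""
        p = params or self.params
        h = x
        for i in range(len(self.cfg.channels)):
            h = conv2d(h, p[f"conv{i}_w"], p[f"conv{i}_b"], stride=2, pad=1).relu()
        h = h.reshape(h.shape[0], self._flat)
        return h @ p["fc_w"] + p["fc_b"]

    def project(self, feats: Tensor, params: Dict[str, Tensor] = None) -> Tensor:
        """3-layer MLP head; output NOT normalized (VICReg uses raw output)."""
        p = params or self.params
        h = (feats @ p["proj1_w"] + p["proj1_b"]).relu()
        h = (h @ p["proj2_w"] + p["proj2_b"]).relu()
        return h @ p["proj3_w"] + p["proj3_b"]

    def predictor(self, z: Tensor) -> Tensor:
        p = self.params
        h = (z @ p["pred1_w"] + p["pred1_b"]).relu()
        return h @ p["pred2_w"] + p["pred2_b"]

    def embed_views(self, x: np.ndarray, params: Dict[str, Tensor] = None,
                    requires_grad: bool = True) -> Tensor:
        """Images (N, H, W) -> unit-norm embeddings (N, embed_dim)."""
        xt = Tensor(np.asarray(x)[:, None, :, :])
        if not requires_grad:
            frozen = {k: Tensor(v.data) for k, v in (params or self.params).items()}
            params = frozen
        feats = self.backbone(xt, params)
        return l2_normalize(self.project(feats, params))


class Adam:
    """Adam over a dict of parameter Tensors."""

    def __init__(self, params: Dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, lr_scale: float = 1.0) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * lr_scale * mhat / (np.sqrt(vhat) + self.eps)

    def state(self) -> Dict[str, np.ndarray]:
        out = {"t": np.array(self.t)}
        for k in self.params:
            out[f"m_{k}"] = self.m[k].copy()
            out[f"v_{k}"] = self.v[k].copy()
        return out

    def load_state(self, state: Dict[str, np.ndarray]) -> None:
        self.t = int(state["t"])
        for k in self.params:
            self.m[k] = state[f"m_{k}"].copy()
            self.v[k] = state[f"v_{k}"].copy()
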