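"""Training loop tying views, losses, EMA teacher, and feature bank together.

One optimization step: build four augmented views per sample, run the
online encoder+projection on the globals and locals, run the EMA teacher
on the globals, derive the multi-positive weight matrix from teacher
similarities, evaluate the composite objective, backpropagate through
the online branch only, take an Adam step (cosine-decayed), update the
teacher by EMA, and push the teacher embeddings into the FIFO bank.

Inference-time embedding uses a single deterministic, un-augmented,
energy-centered global crop per segment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .losses import (
    FeatureBank,
    composite_loss,
    compute_weights,
    ema_update,
    l2_normalize,
    multi_positive_nt_xent,
    one_hot_weights,
    simsiam_loss,
    standard_pairing,
    supcon_weights,
    vicreg_loss,
)
from .models import Adam, ContrastiveModel, ModelConfig
from .preprocess import (
    SpectrogramConfig,
    load_wav,
    logmel,
    normalize_spectrogram,
    resample,
)
from .views import (
    GLOBAL_FRAMES,
    AugmentationPolicy,
    crop_global,
    crop_local,
    augment,
    energy_center,
)

__all__ = [
    "TrainingConfig",
    "SegmentDataset",
    "TrainState",
    "train",
    "train_steps",
    "forward_views",
    "embed",
    "save_checkpoint",
    "load_checkpoint",
]

CONTEXT_FRAMES = 320


@dataclass(frozen=True)
class TrainingConfig:
    tau: float = 0.2
    theta: float = 0.7
    k: int = 5
    bank_capacity: int = 512
    alpha: float = 1.0
    beta: float = 0.5
    gamma: float = 0.1
    ema_momentum: float = 0.99
    lr: float = 3e-3
    # paired-only positives until the teacher has drifted from its random
    # initialization; spurious soft positives from an uninformative teacher
    # otherwise drag unrelated samples together early in training
    soft_positive_warmup: int = 100
    batch_size: int = 32
    steps: int = 300
    cosine_schedule: bool = True
    loss_mode: str = "teacher"  # teacher | vanilla | supcon
    vic_weights: Tuple[float, float, float] = (1.0, 1.0, 0.04)


class SegmentDataset:
    """Per-segment context spectrograms sliced from parent-clip log-mels.

    Spectrograms are computed once per recording over the whole clip and
    a 320-frame context window centered on each 2-s segment is sliced on
    demand (the 256-frame global crop cannot fit inside a lone 198-frame
    segment spectrogram).
    """

    def __init__(self, manifest: pd.DataFrame, cfg: SpectrogramConfig = SpectrogramConfig()):
        self.cfg = cfg
        self.clips: Dict[str, np.ndarray] = {}
        frame_rate = 1000.0 / cfg.hop_ms
        for rec_id, grp in manifest.groupby("recording_id", sort=True):
            wav_path = grp["wav_path"].iloc[0]
            wave, sr = load_wav(wav_path)
            if sr != cfg.sample_rate:
                wave = resample(wave, sr, cfg.sample_rate)
            self.clips[rec_id] = logmel(wave, cfg, normalize=False).astype(np.float32)
        self.table = manifest.reset_index(drop=True).copy()
        self.table["center_frame"] = (
            (self.table["segment_start_s"] + self.table["segment_end_s"]) / 2.0 * frame_rate
        ).astype(int)

    def __len__(self) -> int:
        return len(self.table)

    def context(self, idx: int) -> np.ndarray:
        """Normalized (frames x mel) context window for one segment."""
        row = self.table.iloc[idx]
        clip = self.clips[row["recording_id"]]
        n = clip.shape[0]
        start = int(np.clip(row["center_frame"] - CONTEXT_FRAMES // 2, 0, max(n - CONTEXT_FRAMES, 0)))
        ctx = clip[start : start + CONTEXT_FRAMES]
        if ctx.shape[0] < CONTEXT_FRAMES:  # clip shorter than the context window
            ctx = np.pad(ctx, ((0, CONTEXT_FRAMES - ctx.shape[0]), (0, 0)))
        return normalize_spectrogram(np.asarray(ctx, dtype=np.float64))

    def labels(self) -> np.ndarray:
        return self.table["dominant_archetype"].to_numpy()

    def keys(self) -> pd.DataFrame:
        cols = ["site_id", "recording_id", "segment_start_s", "segment_end_s", "dominant_archetype"]
        return self.table[[c for c in cols if c in self.table.columns]].copy()


# -- view resizing -----------------------------------------------------------

_RESIZE_CACHE: Dict[Tuple[int, int], np.ndarray] = {}


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    key = (n_in, n_out)
    if key not in _RESIZE_CACHE:
        m = np.zeros((n_out, n_in))
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0, n_in - 1)
        j0 = np.floor(src).astype(int)
        frac = src - j0
        j1 = np.minimum(j0 + 1, n_in - 1)
        m[np.arange(n_out), j0] += 1 - frac
        m[np.arange(n_out), j1] += frac
        _RESIZE_CACHE[key] = m
    return _RESIZE_CACHE[key]


def resize_view(view: np.ndarray, out_shape: Tuple[int, int]) -> np.ndarray:
    """Separable bilinear resize (time x mel)."""
    r_t = _interp_matrix(view.shape[0], out_shape[0])
    r_f = _interp_matrix(view.shape[1], out_shape[1])
    return r_t @ view @ r_f.T


# -- train state -------------------------------------------------------------


@dataclass
class TrainState:
    model: ContrastiveModel
    teacher: Dict[str, np.ndarray]
    optimizer: Adam
    bank: FeatureBank
    rng: np.random.Generator
    cfg: TrainingConfig
    step: int = 0
    history: List[dict] = field(default_factory=list)


def _init_state(model_cfg: ModelConfig, cfg: TrainingConfig, seed: int) -> TrainState:
    model = ContrastiveModel(model_cfg, rng_seed=seed)
    teacher = {k: model.params[k].data.copy() for k in model.teacher_names()}
    return TrainState(
        model=model,
        teacher=teacher,
        optimizer=Adam(model.params, lr=cfg.lr),
        bank=FeatureBank(cfg.bank_capacity, model_cfg.embed_dim),
        rng=np.random.default_rng(seed),
        cfg=cfg,
    )


def _batch_views(dataset: SegmentDataset, idx: np.ndarray,
                 policy: AugmentationPolicy, rng: np.random.Generator,
                 size: int) -> Tuple[np.ndarray, np.ndarray]:
    """Interleaved global views (2B, size, size) and local views (2B, size, size)."""
    g_list, l_list = [], []
    for i in idx:
        ctx = dataset.context(int(i))
        for _ in range(2):
            v, _off = crop_global(ctx, rng)
            v, _rec = augment(v, policy, rng)
            g_list.append(resize_view(v, (size, size)))
        for _ in range(2):
            v, _off = crop_local(ctx, rng)
            v, _rec = augment(v, policy, rng)
            l_list.append(resize_view(v, (size, size)))
    return np.stack(g_list), np.stack(l_list)


def forward_views(viewset, model: ContrastiveModel,
                  teacher: Optional[Dict[str, np.ndarray]] = None) -> Dict[str, Tensor]:
    """Run one ViewSet through the online (and optionally teacher) branch.

    Returns unit-norm online projections for the two globals and two
    locals, plus teacher projections of the globals when given.
    """
    size = model.cfg.input_size
    g = np.stack([resize_view(v, (size, size)) for v in viewset.globals()])
    l = np.stack([resize_view(v, (size, size)) for v in viewset.locals()])
    out = {
        "z_global": model.embed_views(g),
        "z_local": model.embed_views(l),
    }
    if teacher is not None:
        t_params = {k: Tensor(v) for k, v in teacher.items()}
        out["t_global"] = model.embed_views(g, params=t_params, requires_grad=False)
    return out


def train_steps(state: TrainState, dataset: SegmentDataset, n_steps: int,
                policy: Optional[AugmentationPolicy] = None,
                labels: Optional[np.ndarray] = None) -> TrainState:
    """Run n_steps of optimization, appending to state.history."""
    cfg = state.cfg
    policy = policy or AugmentationPolicy()
    model = state.model
    size = model.cfg.input_size
    total = max(cfg.steps, state.step + n_steps)
    for _ in range(n_steps):
        idx = state.rng.integers(0, len(dataset), size=cfg.batch_size)
        g_views, l_views = _batch_views(dataset, idx, policy, state.rng, size)

        # online branch
        xg = Tensor(g_views[:, None, :, :])
        feats_g = model.backbone(xg)
        proj_g = model.project(feats_g)
        z_g = l2_normalize(proj_g)
        xl = Tensor(l_views[:, None, :, :])
        proj_l = model.project(model.backbone(xl))
        z_l = l2_normalize(proj_l)

        # teacher branch (frozen copies; no gradients)
        t_params = {k: Tensor(v) for k, v in state.teacher.items()}
        t_g = model.embed_views(g_views, params=t_params, requires_grad=False).data

        pair = standard_pairing(2 * cfg.batch_size)
        m = len(state.bank)
        if cfg.loss_mode == "teacher":
            theta = cfg.theta if state.step >= cfg.soft_positive_warmup else np.inf
            weights = compute_weights(t_g, pair, theta, cfg.k, bank_size=m)
        elif cfg.loss_mode == "vanilla":
            weights = one_hot_weights(pair, bank_size=m)
        elif cfg.loss_mode == "supcon":
            if labels is None:
                raise ValueError("supcon mode requires per-sample labels")
            view_labels = np.repeat(labels[idx], 2)
            weights = supcon_weights(view_labels, pair, bank_size=m)
        else:
            raise ValueError(f"unknown loss_mode {cfg.loss_mode!r}")

        bank_data = state.bank.data if m else None
        l_ctr = multi_positive_nt_xent(z_g, bank_data, weights, cfg.tau)
        lv, li, lc = cfg.vic_weights
        if cfg.beta != 0.0 or cfg.gamma != 0.0:
            l_siam = simsiam_loss([z_g], [z_l], model.predictor)
            l_vic = vicreg_loss(proj_g[0::2], proj_g[1::2],
                                lambda_v=lv, lambda_i=li, lambda_c=lc)
        else:
            l_siam = Tensor(0.0)
            l_vic = Tensor(0.0)
        breakdown = composite_loss(l_ctr, l_siam, l_vic,
                                   cfg.alpha, cfg.beta, cfg.gamma, cfg.tau)
        total_t: Tensor = breakdown.total
        if not np.isfinite(float(total_t.data)):
            raise FloatingPointError(
                f"non-finite loss at step {state.step}: "
                f"ctr={breakdown.l_ctr} siam={breakdown.l_siam} vic={breakdown.l_vic}"
            )
        total_t.backward()
        lr_scale = 1.0
        if cfg.cosine_schedule:
            lr_scale = 0.5 * (1.0 + np.cos(np.pi * state.step / max(total, 1)))
        state.optimizer.step(lr_scale)

        # EMA teacher + bank (push after the loss uses the bank)
        student = [state.model.params[k].data for k in sorted(state.teacher)]
        updated = ema_update([state.teacher[k] for k in sorted(state.teacher)],
                             student, cfg.ema_momentum)
        for k, arr in zip(sorted(state.teacher), updated):
            state.teacher[k] = arr
        if cfg.loss_mode != "vanilla":
            state.bank.push(t_g)

        state.step += 1
        state.history.append(
            dict(step=state.step, l_ctr=breakdown.l_ctr, l_siam=breakdown.l_siam,
                 l_vic=breakdown.l_vic, total=float(total_t.data))
        )
    return state


def train(dataset: SegmentDataset, model_cfg: ModelConfig = ModelConfig(),
          cfg: TrainingConfig = TrainingConfig(), seed: int = 0,
          policy: Optional[AugmentationPolicy] = None,
          labels: Optional[np.ndarray] = None) -> TrainState:
    """Fresh state + cfg.steps optimization steps."""
    state = _init_state(model_cfg, cfg, seed)
    return train_steps(state, dataset, cfg.steps, policy=policy, labels=labels)


def embed(dataset: SegmentDataset, state: TrainState) -> pd.DataFrame:
    """One unit-norm embedding per segment from a deterministic global crop."""
    model = state.model
    size = model.cfg.input_size
    rows = []
    batch = 64
    for lo in range(0, len(dataset), batch):
        views = []
        for i in range(lo, min(lo + batch, len(dataset))):
            ctx = dataset.context(i)
            center = energy_center(ctx)
            start = int(np.clip(center - GLOBAL_FRAMES // 2, 0,
                                max(ctx.shape[0] - GLOBAL_FRAMES, 0)))
            crop = ctx[start : start + GLOBAL_FRAMES]
            views.append(resize_view(crop, (size, size)))
        z = model.embed_views(np.stack(views), requires_grad=False).data
        rows.append(z)
    z_all = np.concatenate(rows, axis=0)
    out = dataset.keys()
    for d in range(z_all.shape[1]):
        out[f"e{d}"] = z_all[:, d]
    return out


def embedding_matrix(table: pd.DataFrame) -> np.ndarray:
    cols = [c for c in table.columns if c.startswith("e") and c[1:].isdigit()]
    cols.sort(key=lambda c: int(c[1:]))
    return table[cols].to_numpy(dtype=np.float64)


# -- checkpointing ------------------------------------------------------------


def save_checkpoint(state: TrainState, path) -> Path:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    payload: Dict[str, np.ndarray] = {}
    for k, v in state.model.state_arrays().items():
        payload[f"param_{k}"] = v
    for k, v in state.teacher.items():
        payload[f"teacher_{k}"] = v
    for k, v in state.optimizer.state().items():
        payload[f"opt_{k}"] = v
    payload["bank"] = state.bank.data
    payload["step"] = np.array(state.step)
    meta = dict(
        cfg=asdict(state.cfg),
        model_cfg=asdict(state.model.cfg),
        rng_state=json.dumps(state.rng.bit_generator.state, default=str),
        history=state.history,
    )
    payload["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)
    return path


def load_checkpoint(path) -> TrainState:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
        model_cfg = ModelConfig(**{**meta["model_cfg"],
                                   "channels": tuple(meta["model_cfg"]["channels"]),
                                   })
        cfg = TrainingConfig(**{**meta["cfg"],
                                "vic_weights": tuple(meta["cfg"]["vic_weights"])})
        state = _init_state(model_cfg, cfg, seed=0)
        state.model.load_state(
            {k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")}
        )
        state.teacher = {
            k[len("teacher_"):]: data[k].copy()
            for k in data.files if k.startswith("teacher_")
        }
        state.optimizer.load_state(
            {k[len("opt_"):]: data[k] for k in data.files if k.startswith("opt_")}
        )
        state.bank = FeatureBank(cfg.bank_capacity, model_cfg.embed_dim)
        if data["bank"].size:
            state.bank.push(data["bank"])
        state.step = int(data["step"])
        state.history = meta["history"]
        rng_state = json.loads(meta["rng_state"])
        _restore_ints(rng_state)
        state.rng = np.random.default_rng(0)
        state.rng.bit_generator.state = rng_state
    return state


def _restore_ints(obj) -> None:
    """JSON round-trips PCG64 128-bit ints as strings; restore them."""
    if isinstance(obj, dict):
        for k, v in obj.items():
            if isinstance(v, str) and v.isdigit():
                obj[k] = int(v)
            else:
                _restore_ints(v)
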