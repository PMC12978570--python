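"""Multi-scale view generation: global/local crops plus spectrogram augmentations.

Each training sample yields four views of its (normalized) log-mel source:
two 256-frame global crops at independent random offsets and two 96-frame
local crops centered on the high-energy region with +/-24-frame jitter.
Augmentations follow the SpecAugment family adapted to normalized inputs:
time/frequency masking and spectral notching fill with the per-view mean
(~0 after z-normalization), temporal shift rolls with zero-fill,
truncation zero-fills a trailing fraction, and Gaussian noise adds i.i.d.
perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "AugmentationPolicy",
    "ViewSet",
    "energy_center",
    "crop_global",
    "crop_local",
    "augment",
    "make_viewset",
    "GLOBAL_FRAMES",
    "LOCAL_FRAMES",
]

GLOBAL_FRAMES = 256
LOCAL_FRAMES = 96
LOCAL_JITTER = 24
_SMOOTH_WIDTH = 9


@dataclass(frozen=True)
class AugmentationPolicy:
    """Per-operation application probabilities and magnitude ranges."""

    p_time_mask: float = 0.5
    time_mask_max: int = 32
    p_freq_mask: float = 0.5
    freq_mask_max: int = 16
    p_notch: float = 0.3
    notch_center_range: Tuple[int, int] = (4, 48)  # mel-bin range (low frequencies)
    notch_width_max: int = 8
    p_shift: float = 0.3
    shift_max: int = 16
    p_truncate: float = 0.2
    truncate_max_frac: float = 0.25
    p_noise: float = 0.5
    noise_sigma_range: Tuple[float, float] = (0.05, 0.2)

    def __post_init__(self):
        for p in (self.p_time_mask, self.p_freq_mask, self.p_notch,
                  self.p_shift, self.p_truncate, self.p_noise):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def identity(cls) -> "AugmentationPolicy":
        return cls(p_time_mask=0, p_freq_mask=0, p_notch=0,
                   p_shift=0, p_truncate=0, p_noise=0)


@dataclass
class ViewSet:
    global_1: np.ndarray
    global_2: np.ndarray
    local_1: np.ndarray
    local_2: np.ndarray
    provenance: Dict[str, dict] = field(default_factory=dict)

    def globals(self):
        return (self.global_1, self.global_2)

    def locals(self):
        return (self.local_1, self.local_2)


def energy_center(spec: np.ndarray) -> int:
    """Frame index of maximum smoothed per-frame energy (ties -> smallest)."""
    if spec.shape[0] < 1:
        raise ValueError("spectrogram has no frames")
    e = (spec**2).sum(axis=1)
    kernel = np.ones(_SMOOTH_WIDTH) / _SMOOTH_WIDTH
    smooth = np.convolve(e, kernel, mode="same")
    return int(np.argmax(smooth))


def _pad_to(spec: np.ndarray, n_frames: int) -> np.ndarray:
    """Symmetric zero-padding of the time axis up to n_frames."""
    deficit = n_frames - spec.shape[0]
    if deficit <= 0:
        return spec
    before = deficit // 2
    return np.pad(spec, ((before, deficit - before), (0, 0)))


def crop_global(spec: np.ndarray, rng: np.random.Generator,
                n_frames: int = GLOBAL_FRAMES) -> Tuple[np.ndarray, int]:
    """Contiguous crop at a uniform random offset; short sources are padded."""
    spec = _pad_to(spec, n_frames)
    hi = spec.shape[0] - n_frames
    offset = int(rng.integers(0, hi + 1)) if hi > 0 else 0
    return spec[offset : offset + n_frames].copy(), offset


def crop_local(spec: np.ndarray, rng: np.random.Generator,
               n_frames: int = LOCAL_FRAMES, jitter: int = LOCAL_JITTER) -> Tuple[np.ndarray, int]:
    """Crop centered on the energy peak with uniform temporal jitter."""
    spec = _pad_to(spec, n_frames)
    center = energy_center(spec) + int(rng.integers(-jitter, jitter + 1))
    start = center - n_frames // 2
    start = int(np.clip(start, 0, spec.shape[0] - n_frames))
    return spec[start : start + n_frames].copy(), start


def augment(view: np.ndarray, policy: AugmentationPolicy,
            rng: np.random.Generator) -> Tuple[np.ndarray, List[dict]]:
    """Apply the augmentation suite; returns (augmented view, ops applied)."""
    out = view.copy()
    nt, nf = out.shape
    record: List[dict] = []
    fill = float(out.mean())

    if rng.uniform() < policy.p_time_mask and policy.time_mask_max > 0:
        w = int(rng.integers(1, min(policy.time_mask_max, nt - 1) + 1))
        t0 = int(rng.integers(0, nt - w + 1))
        out[t0 : t0 + w, :] = fill
        record.append(dict(op="time_mask", start=t0, width=w))
    if rng.uniform() < policy.p_freq_mask and policy.freq_mask_max > 0:
        w = int(rng.integers(1, min(policy.freq_mask_max, nf - 1) + 1))
        f0 = int(rng.integers(0, nf - w + 1))
        out[:, f0 : f0 + w] = fill
        record.append(dict(op="freq_mask", start=f0, width=w))
    if rng.uniform() < policy.p_notch:
        lo, hi = policy.notch_center_range
        center = int(rng.integers(lo, min(hi, nf - 1) + 1))
        w = int(rng.integers(1, policy.notch_width_max + 1))
        a = max(0, center - w // 2)
        b = min(nf, a + w)
        out[:, a:b] = fill
        record.append(dict(op="spectral_notch", center=center, width=w))
    if rng.uniform() < policy.p_shift and policy.shift_max > 0:
        s = int(rng.integers(-policy.shift_max, policy.shift_max + 1))
        if s != 0:
            shifted = np.zeros_like(out)
            if s > 0:
                shifted[s:] = out[:-s]
            else:
                shifted[:s] = out[-s:]
            out = shifted
        record.append(dict(op="temporal_shift", shift=s))
    if rng.uniform() < policy.p_truncate and policy.truncate_max_frac > 0:
        frac = float(rng.uniform(0.0, policy.truncate_max_frac))
        k = int(round(frac * nt))
        if k > 0:
            out[nt - k :, :] = 0.0
        record.append(dict(op="truncation", frames=k))
    if rng.uniform() < policy.p_noise:
        sigma = float(rng.uniform(*policy.noise_sigma_range))
        out = out + rng.normal(0.0, sigma, size=out.shape)
        record.append(dict(op="gaussian_noise", sigma=sigma))
    return out, record


def make_viewset(spec: np.ndarray, policy: AugmentationPolicy,
                 rng: np.random.Generator) -> ViewSet:
    """Two independently cropped+augmented globals and two locals."""
    prov: Dict[str, dict] = {}
    views = {}
    for name in ("global_1", "global_2"):
        v, off = crop_global(spec, rng)
        v, rec = augment(v, policy, rng)
        views[name] = v
        prov[name] = dict(offset=off, ops=rec)
    for name in ("local_1", "local_2"):
        v, off = crop_local(spec, rng)
        v, rec = augment(v, policy, rng)
        views[name] = v
        prov[name] = dict(offset=off, ops=rec)
    return ViewSet(provenance=prov, **views)
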