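"""Waveform-to-spectrogram preprocessing and leakage-safe data splits.

The pipeline mirrors standard PAM practice for low-frequency fish calls:
downsample to 10 kHz, cut non-overlapping 2-second windows, STFT with a
25 ms Hamming window and 10 ms hop (no center padding, so a 2-s segment
yields exactly 198 frames), project onto 128 HTK-mel triangular filters
spanning 0-5 kHz, compress with log(1+x), and z-normalize each
spectrogram.  Train/test splitting happens at the parent-recording level
so no recording contributes segments to both partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly
from scipy.signal.windows import hamming

__all__ = [
    "SpectrogramConfig",
    "load_wav",
    "resample",
    "segment",
    "stft_power",
    "mel_filterbank",
    "logmel",
    "normalize_spectrogram",
    "split_by_recording",
    "stratified_balance",
    "n_stft_frames",
]

_NORM_EPS = 1e-8


@dataclass(frozen=True)
class SpectrogramConfig:
    sample_rate: float = 10_000.0
    window_ms: float = 25.0
    hop_ms: float = 10.0
    n_mels: int = 128
    fmin: float = 0.0
    fmax: float = 5_000.0
    n_fft: Optional[int] = None  # default: next power of two above the window

    def __post_init__(self):
        if self.fmax > self.sample_rate / 2:
            raise ValueError("fmax must not exceed Nyquist")
        if self.hop_ms > self.window_ms:
            raise ValueError("hop must not exceed window")

    @property
    def win_length(self) -> int:
        return int(round(self.window_ms * 1e-3 * self.sample_rate))

    @property
    def hop_length(self) -> int:
        return int(round(self.hop_ms * 1e-3 * self.sample_rate))

    @property
    def fft_size(self) -> int:
        if self.n_fft is not None:
            return self.n_fft
        n = 1
        while n < self.win_length:
            n *= 2
        return n


def load_wav(path) -> Tuple[np.ndarray, float]:
    """Read a mono PCM WAV into float64 in [-1, 1]."""
    sr, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=np.float64), float(sr)


def resample(waveform: np.ndarray, native_rate: float, target_rate: float) -> np.ndarray:
    """Anti-aliased downsampling (polyphase).  Upsampling is out of contract."""
    if target_rate > native_rate:
        raise ValueError("upsampling is out of contract (target_rate > native_rate)")
    if target_rate == native_rate:
        return np.asarray(waveform, dtype=np.float64)
    from math import gcd

    g = gcd(int(native_rate), int(target_rate))
    up, down = int(target_rate) // g, int(native_rate) // g
    return resample_poly(np.asarray(waveform, dtype=np.float64), up, down)


def segment(waveform: np.ndarray, rate: float, seg_len_s: float = 2.0) -> List[np.ndarray]:
    """Non-overlapping fixed-length windows; trailing remainder dropped."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    n = int(round(seg_len_s * rate))
    k = len(waveform) // n
    return [waveform[i * n : (i + 1) * n] for i in range(k)]


def n_stft_frames(n_samples: int, cfg: SpectrogramConfig) -> int:
    return (n_samples - cfg.win_length) // cfg.hop_length + 1


def stft_power(waveform: np.ndarray, cfg: SpectrogramConfig) -> np.ndarray:
    """Power spectrogram, frames x bins, Hamming window, no center padding."""
    win = hamming(cfg.win_length, sym=False)
    hop, wl, nfft = cfg.hop_length, cfg.win_length, cfg.fft_size
    n_frames = n_stft_frames(len(waveform), cfg)
    if n_frames < 1:
        return np.zeros((0, nfft // 2 + 1))
    idx = np.arange(wl)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = waveform[idx] * win
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    return np.abs(spec) ** 2


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(cfg: SpectrogramConfig, n_mels: Optional[int] = None) -> np.ndarray:
    """HTK-mel triangular filters, area-normalized; shape (n_mels, n_bins)."""
    n_mels = n_mels or cfg.n_mels
    n_bins = cfg.fft_size // 2 + 1
    fft_freqs = np.linspace(0, cfg.sample_rate / 2, n_bins)
    mel_pts = np.linspace(_hz_to_mel(cfg.fmin), _hz_to_mel(cfg.fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, n_bins))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-9)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-9)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
        fb[m] *= 2.0 / max(hi - lo, 1e-9)  # unit-area (Slaney-style) normalization
    return fb


def mel_center_freqs(cfg: SpectrogramConfig, n_mels: Optional[int] = None) -> np.ndarray:
    n_mels = n_mels or cfg.n_mels
    mel_pts = np.linspace(_hz_to_mel(cfg.fmin), _hz_to_mel(cfg.fmax), n_mels + 2)
    return _mel_to_hz(mel_pts)[1:-1]


def normalize_spectrogram(s: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance over the whole matrix; all-zero safe."""
    mu = s.mean()
    sd = s.std()
    if sd < _NORM_EPS:
        return np.zeros_like(s)
    return (s - mu) / sd


def logmel(segment_wave: np.ndarray, cfg: SpectrogramConfig, normalize: bool = True) -> np.ndarray:
    """log(1+x)-compressed mel power spectrogram, frames x n_mels."""
    power = stft_power(segment_wave, cfg)
    fb = mel_filterbank(cfg)
    mel = power @ fb.T
    out = np.log1p(mel)
    if normalize:
        out = normalize_spectrogram(out)
    return out


def split_by_recording(table: pd.DataFrame, train_frac: float = 0.8, rng_seed: int = 0) -> pd.DataFrame:
    """Assign train/test at the recording level (no segment leakage)."""
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    recs = np.array(sorted(table["recording_id"].unique()))
    if len(recs) < 2:
        raise ValueError("need at least 2 recordings to split")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(recs))
    n_train = int(round(train_frac * len(recs)))
    n_train = min(max(n_train, 1), len(recs) - 1)
    train_ids = set(recs[perm[:n_train]])
    out = table.copy()
    out["partition"] = np.where(out["recording_id"].isin(train_ids), "train", "test")
    return out


def stratified_balance(
    table: pd.DataFrame,
    rng_seed: int = 0,
    label_col: str = "dominant_archetype",
    strata_cols: Tuple[str, ...] = ("site_id",),
) -> pd.DataFrame:
    """Downsample every class to the smallest class count, without replacement.

    Sampling is stratified over ``strata_cols`` so site proportions within
    each class are preserved where counts allow.  Rows labeled noise must
    be excluded upstream.
    """
    counts = table[label_col].value_counts()
    if counts.empty:
        raise ValueError("table has no labeled rows")
    empty = counts[counts == 0]
    if len(empty):
        raise ValueError(f"class {empty.index[0]!r} has zero rows")
    target = int(counts.min())
    rng = np.random.default_rng(rng_seed)
    picked = []
    for label, grp in table.groupby(label_col, sort=True):
        if len(grp) == target:
            picked.append(grp)
            continue
        # proportional allocation across strata, largest-remainder rounding
        sizes = grp.groupby(list(strata_cols), sort=True).size()
        quota = sizes / sizes.sum() * target
        alloc = np.floor(quota).astype(int)
        rem = target - alloc.sum()
        order = np.argsort(-(quota - alloc).to_numpy(), kind="stable")
        for i in order[:rem]:
            alloc.iloc[i] += 1
        for key, k in alloc.items():
            key = key if isinstance(key, tuple) else (key,)
            sub = grp
            for col, val in zip(strata_cols, key):
                sub = sub[sub[col] == val]
            k = min(int(k), len(sub))
            if k > 0:
                picked.append(sub.iloc[rng.permutation(len(sub))[:k]])
    out = pd.concat(picked).sort_index()
    # largest-remainder may undershoot when a stratum is exhausted; top up
    deficit = {
        label: target - n
        for label, n in out[label_col].value_counts().items()
        if n < target
    }
    if deficit:
        extra = []
        for label, d in deficit.items():
            pool = table[(table[label_col] == label) & (~table.index.isin(out.index))]
            extra.append(pool.iloc[rng.permutation(len(pool))[:d]])
        out = pd.concat([out, *extra]).sort_index()
    return out
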