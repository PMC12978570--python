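"""Classical embedding baselines: cepstral features and linear projection.

Two fixed-dimension baselines accompany the learned embeddings:

* ``gtcc_mfcc`` (93-d): 80 gammatone cepstral coefficients (ERB-spaced
  4th-order gammatone magnitude responses applied to STFT power frames,
  log, DCT-II) concatenated with 13 mel-frequency cepstral coefficients,
  each averaged over frames of the 2-s segment;
* ``logmel_pca`` (100-d): 64-band log-mel spectrograms flattened and
  projected onto the top 100 principal components fit on the training
  partition only.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.fft import dct
from sklearn.decomposition import PCA

from .preprocess import SpectrogramConfig, mel_filterbank, stft_power

__all__ = ["mfcc", "gtcc", "concat_cepstral", "LogMelPCA", "gammatone_filterbank"]

_LOG_EPS = 1e-10

GTCC_MFCC_DIM = 93


def mfcc(segment_wave: np.ndarray, cfg: SpectrogramConfig = SpectrogramConfig(),
         n_coef: int = 13, n_mels: int = 40) -> np.ndarray:
    """Frame-averaged MFCCs (DCT-II of log mel energies)."""
    power = stft_power(segment_wave, cfg)
    fb = mel_filterbank(cfg, n_mels=n_mels)
    loge = np.log(power @ fb.T + _LOG_EPS)
    ceps = dct(loge, type=2, norm="ortho", axis=1)[:, :n_coef]
    return ceps.mean(axis=0)


def _erb(f: np.ndarray) -> np.ndarray:
    return 24.7 * (4.37 * f / 1000.0 + 1.0)


def _hz_to_erbscale(f):
    return 21.4 * np.log10(1.0 + 4.37 * np.asarray(f, dtype=float) / 1000.0)


def _erbscale_to_hz(e):
    return (10.0 ** (np.asarray(e, dtype=float) / 21.4) - 1.0) * 1000.0 / 4.37


def gammatone_filterbank(cfg: SpectrogramConfig, n_filters: int = 80,
                         fmin: float = 50.0) -> np.ndarray:
    """ERB-spaced 4th-order gammatone power responses, (n_filters, n_bins)."""
    n_bins = cfg.fft_size // 2 + 1
    freqs = np.linspace(0, cfg.sample_rate / 2, n_bins)
    centers = _erbscale_to_hz(
        np.linspace(_hz_to_erbscale(fmin), _hz_to_erbscale(cfg.fmax), n_filters)
    )
    fb = np.zeros((n_filters, n_bins))
    for i, fc in enumerate(centers):
        b = 1.019 * _erb(np.array(fc))
        # |H(f)|^2 of an order-4 gammatone: [1 + ((f-fc)/b)^2]^-4
        fb[i] = (1.0 + ((freqs - fc) / b) ** 2) ** -4
        fb[i] /= fb[i].sum()
    return fb


def gtcc(segment_wave: np.ndarray, cfg: SpectrogramConfig = SpectrogramConfig(),
         n_coef: int = 80, n_filters: int = 80) -> np.ndarray:
    """Frame-averaged gammatone cepstral coefficients."""
    if n_coef > n_filters:
        raise ValueError("n_coef must not exceed the filter count")
    power = stft_power(segment_wave, cfg)
    fb = gammatone_filterbank(cfg, n_filters=n_filters)
    loge = np.log(power @ fb.T + _LOG_EPS)
    ceps = dct(loge, type=2, norm="ortho", axis=1)[:, :n_coef]
    return ceps.mean(axis=0)


def concat_cepstral(segment_wave: np.ndarray,
                    cfg: SpectrogramConfig = SpectrogramConfig()) -> np.ndarray:
    """[gtcc | mfcc] -> 93-d feature vector per segment."""
    return np.concatenate([gtcc(segment_wave, cfg), mfcc(segment_wave, cfg)])


class LogMelPCA:
    """PCA over flattened 64-band log-mel spectrograms (fit on train only)."""

    def __init__(self, n_components: int = 100, n_mels: int = 64):
        self.n_components = n_components
        self.n_mels = n_mels
        self._pca: Optional[PCA] = None

    def fit(self, training_specs: np.ndarray) -> "LogMelPCA":
        """training_specs: (n_samples, frames, n_mels) or (n_samples, dim)."""
        x = self._flatten(training_specs)
        if self.n_components > min(x.shape):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n_samples, dim)="
                f"{min(x.shape)}"
            )
        self._pca = PCA(n_components=self.n_components, svd_solver="full")
        self._pca.fit(x)
        return self

    def transform(self, specs: np.ndarray) -> np.ndarray:
        if self._pca is None:
            raise RuntimeError("fit() must be called before transform()")
        return self._pca.transform(self._flatten(specs))

    @property
    def components(self) -> np.ndarray:
        if self._pca is None:
            raise RuntimeError("fit() must be called before accessing components")
        return self._pca.components_

    @property
    def explained_variance(self) -> np.ndarray:
        return self._pca.explained_variance_

    @staticmethod
    def _flatten(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        return x.reshape(x.shape[0], -1)
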