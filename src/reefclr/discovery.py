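"""Cross-site acoustic-signature discovery.

Embeddings from all sites are clustered jointly with a Gaussian Mixture
Model in the shared latent space; clusters whose cohesion (mean
pairwise cosine similarity) falls below a low threshold (default 0.10)
are discarded as noisy groupings.  Each retained cluster becomes an
acoustic signature summarized by its mean spectrogram and simple
descriptors: the frequency band holding the central 90 % of time-
averaged spectral energy, its bandwidth, and a harmonicity score (the
normalized height of the strongest non-zero-lag autocorrelation peak of
the linear-frequency spectrum — 0 for no comb structure, toward 1 for a
perfect harmonic comb).  A signature counts as present at a site when
that site contributes at least ``presence_min_count`` members; the
dictionary tallies multi-site versus single-site signatures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment, cluster_embeddings
from .preprocess import SpectrogramConfig, mel_center_freqs

__all__ = [
    "AcousticSignature",
    "SignatureDictionary",
    "joint_cluster",
    "cohesion",
    "filter_clusters",
    "describe_signature",
    "build_dictionary",
    "per_site_report",
    "spectral_flatness",
]


@dataclass
class AcousticSignature:
    cluster_id: int
    site_counts: Dict[str, int]
    cohesion: float
    mean_spectrogram: np.ndarray
    freq_band: Tuple[float, float]
    bandwidth: float
    harmonicity: float
    exemplar_keys: List[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return sum(self.site_counts.values())


@dataclass
class SignatureDictionary:
    signatures: List[AcousticSignature]
    presence: pd.DataFrame  # signatures x sites boolean matrix
    presence_min_count: int

    @property
    def n_multi_site(self) -> int:
        return int((self.presence.sum(axis=1) > 1).sum())

    @property
    def n_single_site(self) -> int:
        return int((self.presence.sum(axis=1) == 1).sum())

    def sites_of(self, cluster_id: int) -> List[str]:
        row = self.presence.loc[cluster_id]
        return sorted(row.index[row])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.signatures:
            rows.append(
                dict(
                    cluster_id=s.cluster_id,
                    sites=",".join(self.sites_of(s.cluster_id)),
                    n_members=s.size,
                    cohesion=s.cohesion,
                    freq_lo_hz=s.freq_band[0],
                    freq_hi_hz=s.freq_band[1],
                    bandwidth_hz=s.bandwidth,
                    harmonicity=s.harmonicity,
                )
            )
        return pd.DataFrame(rows).sort_values("cluster_id").reset_index(drop=True)

    def to_json(self) -> str:
        payload = []
        for s in self.signatures:
            payload.append(
                dict(
                    cluster_id=int(s.cluster_id),
                    site_counts={k: int(v) for k, v in s.site_counts.items()},
                    sites_present=self.sites_of(s.cluster_id),
                    cohesion=float(s.cohesion),
                    freq_band_hz=[float(s.freq_band[0]), float(s.freq_band[1])],
                    bandwidth_hz=float(s.bandwidth),
                    harmonicity=float(s.harmonicity),
                    exemplars=[int(i) for i in s.exemplar_keys],
                )
            )
        return json.dumps(
            dict(
                presence_min_count=self.presence_min_count,
                n_multi_site=self.n_multi_site,
                n_single_site=self.n_single_site,
                signatures=payload,
            ),
            indent=2,
        )


def joint_cluster(embeddings: np.ndarray, k: int = 60, seed: int = 0) -> ClusterAssignment:
    """Single GMM fit on the pooled multi-site embedding table."""
    return cluster_embeddings(np.asarray(embeddings), "gmm", k=k, seed=seed)


def cohesion(embeddings: np.ndarray) -> float:
    """Mean cosine similarity over all unordered distinct member pairs."""
    x = np.asarray(embeddings, dtype=np.float64)
    n = len(x)
    if n < 2:
        raise ValueError("cohesion undefined for singleton clusters")
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    u = x / norms
    s = u @ u.T
    iu = np.triu_indices(n, k=1)
    return float(s[iu].mean())


def filter_clusters(assignment: ClusterAssignment, embeddings: np.ndarray,
                    threshold: float = 0.10) -> Tuple[List[int], Dict[int, float]]:
    """Retain clusters with cohesion >= threshold.

    Returns (retained cluster ids, cohesion of every non-singleton
    cluster).  Singleton clusters are flagged by omission.
    """
    x = np.asarray(embeddings)
    coh: Dict[int, float] = {}
    for cid in sorted(set(assignment.labels.tolist()) - {-1}):
        members = x[assignment.labels == cid]
        if len(members) < 2:
            continue
        coh[cid] = cohesion(members)
    retained = [cid for cid, c in coh.items() if c >= threshold]
    return retained, coh


def _band_descriptors(mean_spec: np.ndarray, cfg: SpectrogramConfig,
                      coverage: float = 0.90) -> Tuple[Tuple[float, float], float, float]:
    """(freq band, bandwidth, harmonicity) from a mean log-mel spectrogram."""
    centers = mel_center_freqs(cfg, mean_spec.shape[1])
    profile = mean_spec.mean(axis=0)
    profile = profile - profile.min()
    if profile.sum() <= 0:
        return (0.0, 0.0), 0.0, 0.0
    cdf = np.cumsum(profile) / profile.sum()
    tail = (1.0 - coverage) / 2.0
    lo = float(centers[int(np.searchsorted(cdf, tail))])
    hi = float(centers[min(int(np.searchsorted(cdf, 1.0 - tail)), len(centers) - 1)])

    # harmonicity on a linear-frequency resampling of the profile
    f_lin = np.linspace(centers[0], centers[-1], 256)
    p_lin = np.interp(f_lin, centers, profile)
    p_lin = p_lin - p_lin.mean()
    ac = np.correlate(p_lin, p_lin, mode="full")[len(p_lin) - 1 :]
    if ac[0] <= 0:
        harm = 0.0
    else:
        ac = ac / ac[0]
        interior = ac[2:-1]
        peaks = [i + 2 for i in range(len(interior))
                 if ac[i + 2] > ac[i + 1] and ac[i + 2] >= ac[i + 3]]
        harm = float(max((ac[i] for i in peaks), default=0.0))
        harm = float(np.clip(harm, 0.0, 1.0))
    return (lo, hi), hi - lo, harm


def describe_signature(
    cluster_id: int,
    member_specs: Sequence[np.ndarray],
    member_embeddings: np.ndarray,
    member_sites: Sequence[str],
    cfg: SpectrogramConfig = SpectrogramConfig(),
    member_keys: Optional[Sequence[int]] = None,
    n_exemplars: int = 5,
) -> AcousticSignature:
    """Summarize one retained cluster into a dictionary entry."""
    if len(member_specs) == 0:
        raise ValueError("empty cluster")
    specs = np.stack([np.asarray(s) for s in member_specs])
    mean_spec = specs.mean(axis=0)
    band, bw, harm = _band_descriptors(mean_spec, cfg)
    emb = np.asarray(member_embeddings, dtype=np.float64)
    coh = cohesion(emb) if len(emb) > 1 else float("nan")
    centroid = emb.mean(axis=0)
    centroid /= max(np.linalg.norm(centroid), 1e-12)
    sims = (emb / np.linalg.norm(emb, axis=1, keepdims=True)) @ centroid
    order = np.argsort(-sims)[:n_exemplars]
    keys = list(member_keys) if member_keys is not None else list(range(len(emb)))
    sites = pd.Series(list(member_sites))
    return AcousticSignature(
        cluster_id=int(cluster_id),
        site_counts=sites.value_counts().to_dict(),
        cohesion=coh,
        mean_spectrogram=mean_spec,
        freq_band=band,
        bandwidth=bw,
        harmonicity=harm,
        exemplar_keys=[keys[i] for i in order],
    )


def spectral_flatness(mean_spec: np.ndarray) -> float:
    """Flatness (geometric/arithmetic mean ratio) of the time-averaged profile.

    Near 1 for noise-like spectra, near 0 for peaked/tonal structure.
    """
    profile = np.asarray(mean_spec).mean(axis=0)
    profile = profile - profile.min() + 1e-12
    return float(np.exp(np.mean(np.log(profile))) / profile.mean())


def build_dictionary(signatures: Sequence[AcousticSignature],
                     presence_min_count: int = 10,
                     flatness_max: Optional[float] = None) -> SignatureDictionary:
    """Apply the site-presence rule and tally shared vs site-specific entries.

    ``flatness_max``, when set, drops signatures whose mean spectrogram
    is noise-like (spectral flatness above the cutoff) — an automated
    stand-in for expert screening of noise-dominated clusters; off by
    default.
    """
    if flatness_max is not None:
        signatures = [
            s for s in signatures if spectral_flatness(s.mean_spectrogram) <= flatness_max
        ]
    sites = sorted({s for sig in signatures for s in sig.site_counts})
    ids = [sig.cluster_id for sig in signatures]
    pres = pd.DataFrame(False, index=ids, columns=sites)
    for sig in signatures:
        for site, count in sig.site_counts.items():
            pres.loc[sig.cluster_id, site] = count >= presence_min_count
    return SignatureDictionary(
        signatures=sorted(signatures, key=lambda s: s.cluster_id),
        presence=pres,
        presence_min_count=presence_min_count,
    )


def per_site_report(dictionary: SignatureDictionary) -> pd.DataFrame:
    """Per-site signature count and mean cohesion of present signatures."""
    rows = []
    for site in dictionary.presence.columns:
        present = [
            s for s in dictionary.signatures
            if dictionary.presence.loc[s.cluster_id, site]
        ]
        rows.append(
            dict(
                site=site,
                n_signatures=len(present),
                mean_cohesion=float(np.mean([s.cohesion for s in present]))
                if present else float("nan"),
            )
        )
    return pd.DataFrame(rows)
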