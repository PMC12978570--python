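"""Clustering algorithms and external/internal evaluation metrics.

Six algorithm families over any embedding table (K-Means, GMM,
agglomerative, spectral, DBSCAN, HDBSCAN), external label-agreement
metrics (ARI, AMI, Hungarian accuracy) and internal quality indices
(silhouette, Davies-Bouldin, Calinski-Harabasz).  Density-method noise
points (label -1) are excluded from internal metrics and reported as a
separate noise fraction.  Euclidean geometry is used throughout; on
unit-norm embeddings it is monotone in cosine distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn import metrics as skm
from sklearn.cluster import (
    DBSCAN,
    HDBSCAN,
    AgglomerativeClustering,
    KMeans,
    SpectralClustering,
)
from sklearn.mixture import GaussianMixture

__all__ = [
    "ClusterAssignment",
    "MetricReport",
    "cluster_embeddings",
    "ari",
    "ami",
    "hungarian_accuracy",
    "silhouette",
    "davies_bouldin",
    "calinski_harabasz",
    "sweep_k",
    "evaluate",
    "contingency",
]

FIXED_K_METHODS = ("kmeans", "gmm", "agglomerative", "spectral")
DENSITY_METHODS = ("dbscan", "hdbscan")


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    method: str
    k: Optional[int] = None
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.tolist()) - {-1})

    @property
    def noise_fraction(self) -> float:
        return float(np.mean(self.labels == -1))


@dataclass
class MetricReport:
    ari: Optional[float] = None
    ami: Optional[float] = None
    hungarian_acc: Optional[float] = None
    silhouette: Optional[float] = None
    dbi: Optional[float] = None
    ch: Optional[float] = None
    noise_fraction: float = 0.0

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def cluster_embeddings(x: np.ndarray, method: str, k: Optional[int] = None,
                       params: Optional[dict] = None, seed: int = 0) -> ClusterAssignment:
    """Fit one clustering algorithm; deterministic under seed."""
    x = np.asarray(x, dtype=np.float64)
    params = dict(params or {})
    method = method.lower()
    if method in FIXED_K_METHODS:
        if k is None:
            raise ValueError(f"{method} requires a cluster count k")
        if k > len(x):
            raise ValueError(f"k={k} exceeds the number of points {len(x)}")
    if method == "kmeans":
        model = KMeans(n_clusters=k, n_init=10, random_state=seed, **params)
        labels = model.fit_predict(x)
    elif method == "gmm":
        model = GaussianMixture(
            n_components=k, covariance_type=params.pop("covariance_type", "full"),
            n_init=params.pop("n_init", 5), random_state=seed,
            reg_covar=params.pop("reg_covar", 1e-6), **params,
        )
        labels = model.fit(x).predict(x)
    elif method == "agglomerative":
        labels = AgglomerativeClustering(n_clusters=k, **params).fit_predict(x)
    elif method == "spectral":
        model = SpectralClustering(
            n_clusters=k, random_state=seed,
            assign_labels=params.pop("assign_labels", "kmeans"), **params,
        )
        labels = model.fit_predict(x)
    elif method == "dbscan":
        labels = DBSCAN(**params).fit_predict(x)
    elif method == "hdbscan":
        labels = HDBSCAN(**params).fit_predict(x)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    labels = np.asarray(labels, dtype=int)
    if method in FIXED_K_METHODS:
        n_found = len(set(labels.tolist()))
        if n_found < k:
            import warnings

            warnings.warn(f"{method} produced {k - n_found} empty clusters")
    return ClusterAssignment(labels=labels, method=method, k=k, params=params, seed=seed)


def _check_lengths(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty input")
    return a, b


def ari(true_labels, pred_labels) -> float:
    """Pair-counting adjusted Rand index."""
    t, p = _check_lengths(true_labels, pred_labels)
    return float(skm.adjusted_rand_score(t, p))


def ami(true_labels, pred_labels) -> float:
    """Adjusted mutual information (arithmetic-mean normalization)."""
    t, p = _check_lengths(true_labels, pred_labels)
    return float(skm.adjusted_mutual_info_score(t, p, average_method="arithmetic"))


def contingency(true_labels, pred_labels) -> np.ndarray:
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    tu, ti = np.unique(t, return_inverse=True)
    pu, pi = np.unique(p, return_inverse=True)
    table = np.zeros((len(tu), len(pu)), dtype=int)
    np.add.at(table, (ti, pi), 1)
    return table


def hungarian_accuracy(true_labels, pred_labels) -> float:
    """Best accuracy under an optimal one-to-one cluster/class matching."""
    t, p = _check_lengths(true_labels, pred_labels)
    table = contingency(t, p)
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / len(t))


def _drop_noise(x: np.ndarray, labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    keep = labels != -1
    return x[keep], labels[keep]


def silhouette(x: np.ndarray, labels) -> float:
    """Mean silhouette (b - a)/max(a, b), Euclidean.

    Distances are taken with an exact elementwise norm (not the quadratic
    expansion shortcut) so values agree with the definition to ~1e-12.
    """
    from scipy.spatial.distance import cdist

    x, labels = _drop_noise(np.asarray(x, dtype=np.float64), np.asarray(labels))
    clusters = sorted(set(labels.tolist()))
    if len(clusters) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    d = cdist(x, x, metric="euclidean")
    vals = np.zeros(len(x))
    members = {c: np.flatnonzero(labels == c) for c in clusters}
    for i in range(len(x)):
        own = members[labels[i]]
        if len(own) == 1:
            vals[i] = 0.0
            continue
        a = d[i, own].sum() / (len(own) - 1)
        b = min(d[i, members[c]].mean() for c in clusters if c != labels[i])
        vals[i] = (b - a) / max(a, b)
    return float(vals.mean())


def davies_bouldin(x: np.ndarray, labels) -> float:
    """Mean over clusters of the worst (s_i + s_j) / d_ij ratio."""
    x, labels = _drop_noise(np.asarray(x, dtype=np.float64), np.asarray(labels))
    clusters = sorted(set(labels.tolist()))
    cents = np.stack([x[labels == c].mean(axis=0) for c in clusters])
    spread = np.array([
        np.mean(np.linalg.norm(x[labels == c] - cents[i], axis=1))
        for i, c in enumerate(clusters)
    ])
    total = 0.0
    for i in range(len(clusters)):
        total += max(
            (spread[i] + spread[j]) / np.linalg.norm(cents[i] - cents[j])
            for j in range(len(clusters)) if j != i
        )
    return float(total / len(clusters))


def calinski_harabasz(x: np.ndarray, labels) -> float:
    x, labels = _drop_noise(np.asarray(x, dtype=np.float64), np.asarray(labels))
    return float(skm.calinski_harabasz_score(x, labels))


def sweep_k(x: np.ndarray, method: str, k_values: Sequence[int],
            seed: int = 0) -> List[Tuple[int, float]]:
    """Silhouette as a function of the requested cluster count."""
    out = []
    for k in k_values:
        assignment = cluster_embeddings(x, method, k=k, seed=seed)
        out.append((int(k), silhouette(x, assignment.labels)))
    return out


def evaluate(x: np.ndarray, assignment: ClusterAssignment,
             true_labels=None) -> MetricReport:
    """External metrics (when labels are given) plus internal indices."""
    labels = assignment.labels
    report = MetricReport(noise_fraction=assignment.noise_fraction)
    if true_labels is not None:
        report.ari = ari(true_labels, labels)
        report.ami = ami(true_labels, labels)
        report.hungarian_acc = hungarian_accuracy(true_labels, labels)
    x_in, l_in = _drop_noise(np.asarray(x, dtype=np.float64), labels)
    if len(set(l_in.tolist())) >= 2:
        report.silhouette = silhouette(x_in, l_in)
        report.dbi = davies_bouldin(x_in, l_in)
        report.ch = calinski_harabasz(x_in, l_in)
    return report
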