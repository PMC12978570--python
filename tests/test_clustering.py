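"""Clustering metrics vs independent brute-force oracles, and algorithm wrappers."""

import itertools
import math

import numpy as np
import pytest

from reefclr.clustering import (
    ami,
    ari,
    calinski_harabasz,
    cluster_embeddings,
    contingency,
    davies_bouldin,
    evaluate,
    hungarian_accuracy,
    silhouette,
    sweep_k,
)

# ---------------------------------------------------------------------------
# brute-force oracle implementations (definitions only, no sklearn)
# ---------------------------------------------------------------------------


def oracle_ari(t, p):
    table = contingency(t, p)
    n = table.sum()
    comb = lambda x: x * (x - 1) / 2.0
    index = comb(table).sum()
    a = comb(table.sum(axis=1)).sum()
    b = comb(table.sum(axis=0)).sum()
    expected = a * b / comb(n)
    maximum = (a + b) / 2.0
    if maximum == expected:
        return 1.0
    return (index - expected) / (maximum - expected)


def oracle_ami(t, p):
    table = contingency(t, p).astype(float)
    n = table.sum()
    ai, bj = table.sum(axis=1), table.sum(axis=0)
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            if table[i, j] > 0:
                mi += table[i, j] / n * math.log(n * table[i, j] / (ai[i] * bj[j]))
    # expected MI under the permutation model (hypergeometric sum)
    emi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            a, b = int(ai[i]), int(bj[j])
            lo, hi = max(1, a + b - int(n)), min(a, b)
            for nij in range(lo, hi + 1):
                term = nij / n * math.log(n * nij / (a * b))
                prob = (
                    math.comb(b, nij) * math.comb(int(n) - b, a - nij) / math.comb(int(n), a)
                )
                emi += term * prob
    h = lambda c: -sum(x / n * math.log(x / n) for x in c if x > 0)
    denom = (h(ai) + h(bj)) / 2.0 - emi
    if denom == 0:
        return 1.0 if (mi - emi) == 0 else 0.0
    return (mi - emi) / denom


def oracle_hungarian(t, p):
    table = contingency(t, p)
    r, c = table.shape
    k = max(r, c)
    best = 0
    for perm in itertools.permutations(range(k), r):
        s = sum(table[i, perm[i]] for i in range(r) if perm[i] < c)
        best = max(best, s)
    return best / table.sum()


def oracle_silhouette(x, labels):
    n = len(x)
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([d[i, j] for j in same])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == c])
            for c in set(labels) if c != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def oracle_dbi(x, labels):
    cids = sorted(set(labels))
    cents = {c: x[labels == c].mean(axis=0) for c in cids}
    s = {c: np.mean(np.linalg.norm(x[labels == c] - cents[c], axis=1)) for c in cids}
    total = 0.0
    for c in cids:
        total += max(
            (s[c] + s[o]) / np.linalg.norm(cents[c] - cents[o])
            for o in cids if o != c
        )
    return total / len(cids)


def oracle_ch(x, labels):
    cids = sorted(set(labels))
    n, k = len(x), len(cids)
    mean = x.mean(axis=0)
    between = sum(
        (labels == c).sum() * np.sum((x[labels == c].mean(axis=0) - mean) ** 2)
        for c in cids
    )
    within = sum(
        np.sum((x[labels == c] - x[labels == c].mean(axis=0)) ** 2) for c in cids
    )
    return (between / (k - 1)) / (within / (n - k))


def random_instance(rng, n_max=20, d=3, k_max=4):
    n = int(rng.integers(6, n_max + 1))
    x = rng.normal(size=(n, d))
    k = int(rng.integers(2, k_max + 1))
    labels = rng.integers(0, k, size=n)
    while len(set(labels.tolist())) < 2:
        labels = rng.integers(0, k, size=n)
    return x, labels


# ---------------------------------------------------------------------------


class TestExternalMetricOracles:
    def test_ari_worked_example(self):
        assert ari([1, 1, 2, 2], [1, 2, 2, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_identical_partitions(self):
        labels = [0, 0, 1, 1, 2]
        assert ari(labels, labels) == 1.0
        assert ami(labels, labels) == 1.0
        assert hungarian_accuracy(labels, labels) == 1.0

    def test_hungarian_single_cluster_prediction(self):
        assert hungarian_accuracy([0, 0, 1, 1], [0, 0, 0, 0]) == pytest.approx(0.5)

    def test_permutation_invariance(self, rng):
        for _ in range(10):
            _, t = random_instance(rng)
            _, p = random_instance(rng, n_max=len(t))
            p = p[: len(t)] if len(p) >= len(t) else np.resize(p, len(t))
            remap = {c: 10 - c for c in set(p.tolist())}
            p2 = np.array([remap[c] for c in p])
            assert ari(t, p) == pytest.approx(ari(t, p2), abs=1e-12)
            assert ami(t, p) == pytest.approx(ami(t, p2), abs=1e-9)
            assert hungarian_accuracy(t, p) == pytest.approx(hungarian_accuracy(t, p2))

    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(100):
            x, t = random_instance(rng)
            _, p = random_instance(rng)
            p = np.resize(p, len(t))
            assert ari(t, p) == pytest.approx(oracle_ari(t, p), abs=1e-9)
            assert ami(t, p) == pytest.approx(oracle_ami(t, p), abs=1e-6)
            assert hungarian_accuracy(t, p) == pytest.approx(oracle_hungarian(t, p), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ari([1, 2], [1, 2, 3])


class TestInternalMetricOracles:
    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(100):
            x, labels = random_instance(rng)
            assert silhouette(x, labels) == pytest.approx(oracle_silhouette(x, labels), abs=1e-9)
            assert davies_bouldin(x, labels) == pytest.approx(oracle_dbi(x, labels), abs=1e-9)
            assert calinski_harabasz(x, labels) == pytest.approx(oracle_ch(x, labels), rel=1e-9)

    def test_dbi_closed_form_duplicate_clusters(self, rng):
        """Two same-shape clusters, spread s at distance d -> DBI = 2s/d."""
        base = np.array([[1.0, 0.0], [-1.0, 0.0]])  # spread s = 1 around centroid
        x = np.vstack([base, base + np.array([0.0, 10.0])])
        labels = np.array([0, 0, 1, 1])
        assert davies_bouldin(x, labels) == pytest.approx(2 * 1.0 / 10.0, abs=1e-12)

    def test_ch_scale_invariance(self, rng):
        x, labels = random_instance(rng)
        assert calinski_harabasz(3.7 * x, labels) == pytest.approx(
            calinski_harabasz(x, labels), rel=1e-9
        )

    def test_silhouette_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.ones((5, 2)), np.zeros(5))

    def test_tight_far_clusters_silhouette_near_one(self, rng):
        a = rng.normal(scale=1e-3, size=(10, 2))
        b = rng.normal(scale=1e-3, size=(10, 2)) + 100.0
        x = np.vstack([a, b])
        labels = np.array([0] * 10 + [1] * 10)
        assert silhouette(x, labels) > 0.99


def make_blobs(rng, k=3, n_per=30, sep=20.0, d=4):
    centers = rng.normal(scale=sep, size=(k, d))
    x = np.vstack([centers[i] + rng.normal(size=(n_per, d)) for i in range(k)])
    labels = np.repeat(np.arange(k), n_per)
    return x, labels


class TestClusterEmbeddings:
    def test_blob_recovery_kmeans(self, rng):
        x, labels = make_blobs(rng)
        a = cluster_embeddings(x, "kmeans", k=3, seed=0)
        assert ari(labels, a.labels) == 1.0

    def test_deterministic_under_seed(self, rng):
        x, _ = make_blobs(rng)
        a1 = cluster_embeddings(x, "gmm", k=3, seed=5)
        a2 = cluster_embeddings(x, "gmm", k=3, seed=5)
        assert np.array_equal(a1.labels, a2.labels)

    def test_dbscan_blobs(self, rng):
        x, labels = make_blobs(rng, sep=50.0)
        a = cluster_embeddings(x, "dbscan", params=dict(eps=5.0, min_samples=3))
        assert a.n_clusters >= 3

    @pytest.mark.parametrize("method", ["agglomerative", "spectral", "hdbscan"])
    def test_other_methods_run(self, method, rng):
        x, labels = make_blobs(rng, sep=50.0)
        k = None if method == "hdbscan" else 3
        a = cluster_embeddings(x, method, k=k, seed=0)
        assert len(a.labels) == len(x)

    def test_k_exceeds_n_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_embeddings(rng.normal(size=(4, 2)), "kmeans", k=10)


class TestSweepAndEvaluate:
    def test_sweep_k_peak_at_true_k(self, rng):
        x, _ = make_blobs(rng, k=3, sep=30.0)
        curve = sweep_k(x, "kmeans", range(2, 8), seed=0)
        assert len(curve) == 6
        best_k = max(curve, key=lambda kv: kv[1])[0]
        assert best_k == 3

    def test_evaluate_with_and_without_labels(self, rng):
        x, labels = make_blobs(rng)
        a = cluster_embeddings(x, "kmeans", k=3, seed=0)
        rep = evaluate(x, a, true_labels=labels)
        assert rep.ari == rep.hungarian_acc == 1.0
        assert rep.ami == pytest.approx(1.0)
        assert -1 <= rep.silhouette <= 1 and rep.dbi >= 0 and rep.ch >= 0
        rep2 = evaluate(x, a)
        assert rep2.ari is None and rep2.ami is None and rep2.hungarian_acc is None
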