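"""Teacher-guided multi-positive contrastive objectives.

The loss system couples four pieces:

* a multi-positive NT-Xent: for anchor i with weight row W_i,

      L_ctr = -(1/2B) sum_i sum_j W_ij log  exp(s_ij / tau)
                                           -----------------------
                                           sum_{l != i} exp(s_il / tau)

  where s are cosine similarities among the 2B in-batch online
  embeddings plus M bank entries; the denominator masks only the self
  pair.  W assigns weight 1 to the paired augmentation and (1+t_sim)/2
  to up-to-k teacher neighbors above a similarity threshold, then
  row-normalizes, so every row sums to 1.  Bank entries are pure
  negatives (their W columns are zero).
* an EMA teacher whose parameters trail the student, providing the
  stable similarities used to pick soft positives;
* a FIFO feature bank of past teacher embeddings enlarging the negative
  set;
* SimSiam (predictor vs stop-gradient across global/local views) and
  VICReg (variance/invariance/covariance) auxiliaries, combined as
  total = alpha*L_ctr + beta*L_siam + gamma*L_vic.

Setting threshold > 1, M = 0, beta = gamma = 0 reduces the engine
exactly to vanilla SimCLR NT-Xent; label-driven weights turn the same
engine into the semi-supervised / SupCon modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Union

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "FeatureBank",
    "PositiveWeightMatrix",
    "LossBreakdown",
    "cosine_matrix",
    "standard_pairing",
    "compute_weights",
    "one_hot_weights",
    "supcon_weights",
    "multi_positive_nt_xent",
    "vanilla_mode",
    "ema_update",
    "simsiam_loss",
    "vicreg_loss",
    "composite_loss",
    "l2_normalize",
]

ArrayLike = Union[np.ndarray, Tensor]


def _as_tensor(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def l2_normalize(x: Tensor, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=1, keepdims=True) + eps) ** 0.5
    return x / norm


def cosine_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cosine similarities between rows of a and rows of b."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if (na < 1e-12).any() or (nb < 1e-12).any():
        raise ValueError("cosine similarity undefined for zero rows")
    return (a / na[:, None]) @ (b / nb[:, None]).T


def standard_pairing(two_b: int) -> np.ndarray:
    """Involution pairing view 2i with view 2i+1."""
    if two_b % 2:
        raise ValueError("need an even number of views")
    p = np.arange(two_b)
    p[0::2] += 1
    p[1::2] -= 1
    return p


@dataclass
class PositiveWeightMatrix:
    """Row-normalized positive weights; columns beyond 2B (bank) are zero."""

    W: np.ndarray  # (2B, 2B + M)
    Z: np.ndarray  # per-anchor unnormalized row sums
    theta: float
    k: int
    pair_of: np.ndarray

    @property
    def n_views(self) -> int:
        return self.W.shape[0]


def compute_weights(
    t_batch: np.ndarray,
    pair_of: np.ndarray,
    theta: float = 0.7,
    k: int = 5,
    bank_size: int = 0,
) -> PositiveWeightMatrix:
    """Teacher-guided soft-positive weights.

    Unnormalized: 1 for the paired view, (1 + sim(t_i, t_j))/2 for the
    top-k in-batch teacher neighbors with sim > theta (self and the
    paired view excluded), 0 otherwise; rows are then normalized to 1.
    """
    t_batch = np.asarray(t_batch, dtype=np.float64)
    two_b = t_batch.shape[0]
    if two_b == 0:
        raise ValueError("empty batch")
    sims = cosine_matrix(t_batch, t_batch)
    w = np.zeros((two_b, two_b + bank_size))
    for i in range(two_b):
        w[i, pair_of[i]] = 1.0
        cand = [j for j in range(two_b) if j != i and j != pair_of[i] and sims[i, j] > theta]
        cand.sort(key=lambda j: (-sims[i, j], j))
        for j in cand[:k]:
            w[i, j] = (1.0 + sims[i, j]) / 2.0
    z = w.sum(axis=1)
    return PositiveWeightMatrix(W=w / z[:, None], Z=z, theta=theta, k=k, pair_of=np.asarray(pair_of))


def one_hot_weights(pair_of: np.ndarray, bank_size: int = 0) -> PositiveWeightMatrix:
    """Vanilla pairing: full weight on the paired augmentation."""
    pair_of = np.asarray(pair_of)
    two_b = len(pair_of)
    w = np.zeros((two_b, two_b + bank_size))
    w[np.arange(two_b), pair_of] = 1.0
    return PositiveWeightMatrix(W=w, Z=np.ones(two_b), theta=np.inf, k=0, pair_of=pair_of)


def supcon_weights(labels: Sequence, pair_of: np.ndarray, bank_size: int = 0) -> PositiveWeightMatrix:
    """Label-driven positives: uniform weight over same-label views (j != i)."""
    pair_of = np.asarray(pair_of)
    two_b = len(pair_of)
    if len(labels) != two_b or any(l is None for l in labels):
        raise ValueError("supervised mode requires a label for every view")
    labels = np.asarray(labels)
    w = np.zeros((two_b, two_b + bank_size))
    for i in range(two_b):
        same = (labels == labels[i])
        same[i] = False
        w[i, :two_b][same] = 1.0
        w[i, pair_of[i]] = 1.0  # paired view always a positive
    z = w.sum(axis=1)
    return PositiveWeightMatrix(W=w / z[:, None], Z=z, theta=np.inf, k=0, pair_of=pair_of)


def multi_positive_nt_xent(
    z: ArrayLike,
    bank: Optional[np.ndarray],
    weights: PositiveWeightMatrix,
    tau: float = 0.2,
) -> Tensor:
    """Multi-positive NT-Xent over 2B anchors with bank negatives.

    `z` must be unit-norm rows (2B, d); `bank` is (M, d) or None.  The
    denominator runs over the 2B - 1 other batch embeddings plus all
    bank entries (log-sum-exp stabilized).  Differentiable through `z`.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    zt = _as_tensor(z)
    two_b = zt.shape[0]
    m = 0 if bank is None or len(bank) == 0 else len(bank)
    if weights.W.shape != (two_b, two_b + m):
        raise ValueError(
            f"weight matrix shape {weights.W.shape} inconsistent with "
            f"batch {two_b} + bank {m}"
        )
    sims = zt @ zt.T
    if m:
        sims = concat([sims, zt @ Tensor(np.asarray(bank, dtype=np.float64).T)], axis=1)
    # stabilization constant (detached) and self-pair mask
    row_max = sims.data.max(axis=1, keepdims=True)
    mask = np.ones((two_b, two_b + m))
    np.fill_diagonal(mask[:, :two_b], 0.0)
    expd = ((sims - Tensor(row_max)) * (1.0 / tau)).exp() * Tensor(mask)
    log_denom = expd.sum(axis=1, keepdims=True).log()
    log_ratio = (sims - Tensor(row_max)) * (1.0 / tau) - log_denom
    loss = -(Tensor(weights.W) * log_ratio).sum() * (1.0 / two_b)
    return loss


def vanilla_mode(z: ArrayLike, tau: float = 0.2,
                 pair_of: Optional[np.ndarray] = None) -> Tensor:
    """Vanilla SimCLR NT-Xent: one-hot pairing, no bank, no teacher."""
    zt = _as_tensor(z)
    if pair_of is None:
        pair_of = standard_pairing(zt.shape[0])
    return multi_positive_nt_xent(zt, None, one_hot_weights(pair_of), tau)


class FeatureBank:
    """Fixed-capacity FIFO queue of (unit-norm) teacher embeddings."""

    def __init__(self, capacity: int, dim: int):
        self.capacity = int(capacity)
        self.dim = int(dim)
        self._buf = np.zeros((0, dim))

    def push(self, t_batch: np.ndarray) -> "FeatureBank":
        t_batch = np.asarray(t_batch, dtype=np.float64)
        self._buf = np.concatenate([self._buf, t_batch], axis=0)
        if len(self._buf) > self.capacity:
            self._buf = self._buf[len(self._buf) - self.capacity :]
        return self

    @property
    def data(self) -> np.ndarray:
        return self._buf

    def __len__(self) -> int:
        return len(self._buf)


def ema_update(teacher_params: List[np.ndarray], student_params: List[np.ndarray],
               momentum: float) -> List[np.ndarray]:
    """theta_t <- m * theta_t + (1 - m) * theta_s, elementwise."""
    if not (0.0 <= momentum <= 1.0):
        raise ValueError("momentum must lie in [0, 1]")
    out = []
    for tp, sp in zip(teacher_params, student_params):
        if tp.shape != sp.shape:
            raise ValueError(f"shape mismatch {tp.shape} vs {sp.shape}")
        out.append(momentum * tp + (1.0 - momentum) * sp)
    return out


def _mean_cosine(a: Tensor, b: Tensor) -> Tensor:
    return (l2_normalize(a) * l2_normalize(b)).sum(axis=1).mean()


def simsiam_loss(global_proj: Sequence[Tensor], local_proj: Sequence[Tensor],
                 predictor: Callable[[Tensor], Tensor]) -> Tensor:
    """Symmetric negative cosine with stop-gradient targets.

    Pairs global view g_i with local view l_i; targets are detached so
    no gradient flows through the target branch.
    """
    terms = []
    for g, l in zip(global_proj, local_proj):
        t1 = _mean_cosine(predictor(g), l.detach())
        t2 = _mean_cosine(predictor(l), g.detach())
        terms.append((t1 + t2) * -0.5)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def vicreg_loss(
    z_a: ArrayLike,
    z_b: ArrayLike,
    var_target: float = 1.0,
    eps: float = 1e-4,
    lambda_v: float = 1.0,
    lambda_i: float = 1.0,
    lambda_c: float = 0.04,
) -> Tensor:
    """Variance-invariance-covariance regularization (both branches)."""
    za, zb = _as_tensor(z_a), _as_tensor(z_b)
    n, d = za.shape
    if n < 2:
        raise ValueError("VICReg needs at least 2 rows")
    inv = ((za - zb) ** 2.0).mean()

    def var_term(z: Tensor) -> Tensor:
        mu = z.mean(axis=0, keepdims=True)
        var = ((z - mu) ** 2.0).mean(axis=0)
        return (Tensor(np.full(d, var_target)) - (var + eps) ** 0.5).relu().mean()

    def cov_term(z: Tensor) -> Tensor:
        mu = z.mean(axis=0, keepdims=True)
        zc = z - mu
        cov = (zc.T @ zc) * (1.0 / (n - 1))
        off = cov * Tensor(1.0 - np.eye(d))
        return (off ** 2.0).sum() * (1.0 / d)

    v = (var_term(za) + var_term(zb)) * 0.5
    c = (cov_term(za) + cov_term(zb)) * 0.5
    return lambda_i * inv + lambda_v * v + lambda_c * c


@dataclass
class LossBreakdown:
    l_ctr: float
    l_siam: float
    l_vic: float
    total: Union[float, Tensor]
    alpha: float
    beta: float
    gamma: float
    tau: float = 0.2


def composite_loss(
    l_ctr: Union[float, Tensor],
    l_siam: Union[float, Tensor],
    l_vic: Union[float, Tensor],
    alpha: float = 1.0,
    beta: float = 0.5,
    gamma: float = 0.1,
    tau: float = 0.2,
) -> LossBreakdown:
    """Weighted combination total = alpha*ctr + beta*siam + gamma*vic."""
    parts = dict(l_ctr=l_ctr, l_siam=l_siam, l_vic=l_vic)
    vals = {}
    for name, p in parts.items():
        v = float(p.data) if isinstance(p, Tensor) else float(p)
        if not np.isfinite(v):
            raise ValueError(f"loss term {name} is not finite ({v})")
        vals[name] = v
    total = alpha * l_ctr + beta * l_siam + gamma * l_vic
    return LossBreakdown(
        l_ctr=vals["l_ctr"], l_siam=vals["l_siam"], l_vic=vals["l_vic"],
        total=total, alpha=alpha, beta=beta, gamma=gamma, tau=tau,
    )
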