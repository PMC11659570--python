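"""Contrastive and classification losses for multi-label coding.

The loss family covers the three training stages:

* unsupervised InfoNCE over two views of the same document (cosine
  similarity, temperature tau) — used alone for pretraining on incomplete
  raw records;
* a multi-label supervised contrastive loss in which each in-batch pair is
  weighted by a dynamic coefficient beta_ij, the row-normalised dot
  product of the two samples' label vectors, over a Euclidean-distance
  softmax (temperature tau');
* clamped binary cross-entropy over the per-code probabilities.

All functions accept either `Tensor`s (for training) or plain arrays and
return a scalar `Tensor`; batch aggregation is the mean over samples of
the per-sample terms.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, logsumexp

__all__ = [
    "loss_us_con",
    "label_similarity",
    "dynamic_coefficients",
    "loss_ml_con",
    "loss_bce",
    "loss_step2",
    "loss_step3",
]

_EPS_NORM = 1e-12
_EPS_BCE = 1e-7
_NEG_INF = -1e30


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _normalize_rows(z: Tensor) -> Tensor:
    norms = ((z * z).sum(axis=1, keepdims=True) + _EPS_NORM).sqrt()
    return z / norms


def loss_us_con(z: Tensor, pos_view: Tensor, tau: float = 0.05) -> Tensor:
    """In-batch InfoNCE with cosine similarity.

    Sample i's positive is row i of `pos_view`; every other sample's
    positive view is a negative. Returns the batch mean of
    -log softmax_i(sim(z_i, pos_i) / tau).
    """
    z, pos_view = _t(z), _t(pos_view)
    b = z.shape[0]
    if b < 2:
        raise ValueError("contrastive loss needs a batch of at least 2")
    if tau <= 0:
        raise ValueError("temperature must be positive")
    sims = (_normalize_rows(z) @ _normalize_rows(pos_view).T) * (1.0 / tau)
    diag = (sims * Tensor(np.eye(b))).sum(axis=1)
    return (logsumexp(sims, axis=1) - diag).mean()


def label_similarity(y_i, y_j) -> int:
    """Number of shared labels: the dot product of two binary label vectors."""
    y_i, y_j = np.asarray(y_i), np.asarray(y_j)
    if y_i.shape != y_j.shape:
        raise ValueError(f"label vectors differ in length: {y_i.shape} vs {y_j.shape}")
    return int(y_i @ y_j)


def dynamic_coefficients(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalise the pairwise label-similarity matrix, excluding self-pairs.

    Returns (beta, zero_mass) where beta[i, j] is the dynamic coefficient
    of pair (i, j) with beta[i, i] = 0, each positive row summing to 1.
    Rows with no label overlap against the rest of the batch are left
    all-zero (the sample acts only as a negative) and flagged in
    `zero_mass`.
    """
    C = np.asarray(C, dtype=float)
    off = C * (1.0 - np.eye(C.shape[0]))
    row_sums = off.sum(axis=1)
    zero_mass = row_sums == 0
    denom = np.where(zero_mass, 1.0, row_sums)
    return off / denom[:, None], zero_mass


def _pairwise_distances(z: Tensor) -> Tensor:
    sq = (z * z).sum(axis=1, keepdims=True)
    d2 = sq + sq.T - (z @ z.T) * 2.0
    return (d2.clip(0.0, np.inf) + _EPS_NORM).sqrt()


def loss_ml_con(z: Tensor, y: np.ndarray, tau_prime: float = 0.05) -> Tensor:
    """Label-similarity-weighted supervised contrastive loss.

    For each ordered pair (i, j), i != j, adds
    -beta_ij * log softmax_j(-d(z_i, z_j) / tau') where d is Euclidean
    distance and the softmax runs over the batch excluding i. The batch
    aggregate is the mean over i of the per-sample inner sums.
    """
    z = _t(z)
    y = np.asarray(y, dtype=float)
    b = z.shape[0]
    if b < 2:
        raise ValueError("contrastive loss needs a batch of at least 2")
    if tau_prime <= 0:
        raise ValueError("temperature must be positive")
    beta, _ = dynamic_coefficients(y @ y.T)
    logits = _pairwise_distances(z) * (-1.0 / tau_prime)
    masked = logits + Tensor(np.eye(b) * _NEG_INF)  # exclude self from candidates
    lse = logsumexp(masked, axis=1)
    per_pair = (lse.reshape(b, 1) - logits) * Tensor(beta)
    return per_pair.sum() * (1.0 / b)


def loss_bce(y_prob: Tensor, y: np.ndarray) -> Tensor:
    """Per-sample sum over codes of binary cross-entropy, averaged over the batch.

    Probabilities are clamped to [1e-7, 1 - 1e-7] before the logarithms.
    """
    p = _t(y_prob).clip(_EPS_BCE, 1.0 - _EPS_BCE)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    yt = Tensor(y)
    per_sample = -(yt * p.log() + (1.0 - yt) * (1.0 - p).log()).sum(axis=1)
    return per_sample.mean() if per_sample.data.ndim else per_sample


def loss_step2(z, pos_view, y, gamma: float = 0.5, delta: float = 0.02,
               tau_us: float = 0.05, tau_prime: float = 0.05) -> Tensor:
    """Noisy-stage objective: gamma * supervised + delta * unsupervised contrastive."""
    return loss_ml_con(z, y, tau_prime) * gamma + loss_us_con(z, pos_view, tau_us) * delta


def loss_step3(z, pos_view, y, y_prob, theta: float = 1.0, gamma: float = 0.5,
               delta: float = 0.02, tau_us: float = 0.05, tau_prime: float = 0.05) -> Tensor:
    """Refinement objective: theta * BCE + gamma * supervised + delta * unsupervised."""
    return (
        loss_bce(y_prob, y) * theta
        + loss_ml_con(z, y, tau_prime) * gamma
        + loss_us_con(z, pos_view, tau_us) * delta
    )
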