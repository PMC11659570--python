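"""Similarity-based noisy auto-annotation.

A lightweight sentence encoder for short disease-name strings is trained
with the dropout-view InfoNCE objective (two stochastic encodings of the
same name form a positive pair, other in-batch names are negatives).
Standard code names act as per-code prototype texts; each short-text
entry is assigned the single code whose prototype is nearest in cosine
similarity, and the union over entries becomes the record's noisy label
set.

The default encoder is a hashed character-n-gram bag-of-embeddings tower
with feature dropout providing the stochastic views; heavier pretrained
sentence encoders can be plugged in via the same fit/transform surface.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._autodiff import Adam, Tensor, concat, gather_rows
from .losses import loss_us_con
from .records import DatasetPartitions, EMRRecord
from .taxonomy import CodeTaxonomy

__all__ = [
    "NameSimilarityEncoder",
    "PrototypeIndex",
    "build_prototype_index",
    "assign_noisy_labels",
    "partition_corpus",
]


def _char_ngrams(text: str, n_lo: int = 2, n_hi: int = 4) -> list[str]:
    padded = f"<{text}>"
    grams = [w for w in text.split()]
    for n in range(n_lo, n_hi + 1):
        grams.extend(padded[i: i + n] for i in range(len(padded) - n + 1))
    return grams


class NameSimilarityEncoder(BaseEstimator, TransformerMixin):
    """Contrastively trained hashed-n-gram name encoder.

    Parameters
    ----------
    dim : embedding dimension.
    n_features : hashing-trick bucket count for character n-grams.
    tau : InfoNCE temperature.
    dropout : per-feature drop probability generating the two views.
    epochs, batch_size, learning_rate : optimisation settings.
    random_state : seed fixing initialisation, view noise and batching.

    Attributes
    ----------
    W_ : (n_features, dim) embedding table after training.
    loss_curve_ : mean InfoNCE loss per epoch.
    """

    def __init__(self, dim: int = 32, n_features: int = 2048, tau: float = 0.05,
                 dropout: float = 0.2, epochs: int = 5, batch_size: int = 32,
                 learning_rate: float = 0.01, random_state: int = 0):
        self.dim = dim
        self.n_features = n_features
        self.tau = tau
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- feature extraction ---------------------------------------------------
    def _feature_ids(self, text: str) -> np.ndarray:
        grams = _char_ngrams(text)
        if not grams:
            grams = [text or "<empty>"]
        ids = [zlib.crc32(g.encode("utf8")) % self.n_features for g in grams]
        return np.asarray(sorted(set(ids)), dtype=np.intp)

    def _encode_batch(self, id_lists, W: Tensor, rng: np.random.Generator | None) -> Tensor:
        rows = []
        for ids in id_lists:
            if rng is not None and self.dropout > 0:
                keep = rng.random(len(ids)) >= self.dropout
                kept = ids[keep] if keep.any() else ids
            else:
                kept = ids
            rows.append(gather_rows(W, kept).mean(axis=0, keepdims=True))
        return concat(rows, axis=0)

    # -- estimator surface ----------------------------------------------------
    def fit(self, X, y=None):
        """Train on a corpus of name strings with the dropout-view InfoNCE loss."""
        names = list(X)
        if not names:
            raise ValueError("name corpus must be non-empty")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (in-batch negatives required)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        rng = np.random.default_rng(self.random_state)
        W = Tensor(rng.normal(0.0, 0.1, size=(self.n_features, self.dim)), requires_grad=True)
        ids = [self._feature_ids(t) for t in names]
        opt = Adam({"W": W}, lr=self.learning_rate)
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(len(names))
            epoch_losses = []
            for start in range(0, len(names), self.batch_size):
                batch = [ids[j] for j in order[start: start + self.batch_size]]
                if len(batch) < 2:
                    continue
                opt.zero_grad()
                za = self._encode_batch(batch, W, rng)
                zb = self._encode_batch(batch, W, rng)
                loss = loss_us_con(za, zb, self.tau)
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
            self.loss_curve_.append(float(np.mean(epoch_losses)) if epoch_losses else float("nan"))
        self.W_ = W.data
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        """Deterministic embeddings (no dropout), one row per name."""
        if not hasattr(self, "W_"):
            raise ValueError("encoder is not fitted")
        out = np.empty((len(X), self.dim))
        for i, text in enumerate(X):
            out[i] = self.W_[self._feature_ids(text)].mean(axis=0)
        return out

    @staticmethod
    def _base_path(path) -> str:
        base = str(path)
        return base[:-4] if base.endswith(".npz") else base

    def save(self, path) -> None:
        """Checkpoint: embedding table (.npz) with a JSON hyperparameter sidecar."""
        import json

        base = self._base_path(path)
        np.savez(base + ".npz", W=self.W_)
        with open(base + ".meta.json", "w") as fh:
            json.dump(self.get_params(), fh)

    @classmethod
    def load(cls, path) -> "NameSimilarityEncoder":
        import json

        base = cls._base_path(path)
        with open(base + ".meta.json") as fh:
            enc = cls(**json.load(fh))
        enc.W_ = np.load(base + ".npz")["W"]
        return enc

    def untrained_transform(self, X) -> np.ndarray:
        """Embeddings from the seed initialisation, for before/after comparisons."""
        rng = np.random.default_rng(self.random_state)
        W0 = rng.normal(0.0, 0.1, size=(self.n_features, self.dim))
        return np.stack([W0[self._feature_ids(t)].mean(axis=0) for t in X])


@dataclass
class PrototypeIndex:
    """One prototype embedding per leaf code, from its standard name."""

    prototypes: np.ndarray  # (n_leaves, dim), rows aligned with leaf_order
    leaf_order: list[str] = field(default_factory=list)

    def __post_init__(self):
        norms = np.linalg.norm(self.prototypes, axis=1, keepdims=True)
        self._unit = self.prototypes / np.where(norms == 0, 1.0, norms)

    def nearest(self, embeddings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Argmax-cosine code index and its cosine for each embedding row."""
        norms = np.linalg.norm(embeddings, axis=1, keepdims=True)
        unit = embeddings / np.where(norms == 0, 1.0, norms)
        sims = unit @ self._unit.T
        idx = sims.argmax(axis=1)
        return idx, sims[np.arange(len(idx)), idx]


def build_prototype_index(taxonomy: CodeTaxonomy, encoder: NameSimilarityEncoder) -> PrototypeIndex:
    names = [taxonomy.codes[cid].standard_name for cid in taxonomy.leaf_order]
    return PrototypeIndex(encoder.transform(names), list(taxonomy.leaf_order))


def assign_noisy_labels(
    record: EMRRecord,
    encoder: NameSimilarityEncoder,
    index: PrototypeIndex,
    confidence_floor: float = 0.0,
):
    """Map each short-text entry to its nearest prototype code.

    Returns (label set, per-entry assignments). Each assignment is a dict
    with the entry text, assigned code, cosine confidence, and a
    low-confidence flag; entries below the floor are flagged but still
    assigned. A record with empty short text yields (None, []) — the
    caller routes it to the incomplete-raw pool.
    """
    if not record.short_text:
        return None, []
    emb = encoder.transform(record.short_text)
    idx, conf = index.nearest(emb)
    assignments = [
        {
            "entry": record.short_text[i],
            "code": index.leaf_order[int(idx[i])],
            "confidence": float(conf[i]),
            "low_confidence": bool(conf[i] < confidence_floor),
        }
        for i in range(len(record.short_text))
    ]
    labels = {a["code"] for a in assignments}
    return labels, assignments


def partition_corpus(
    records: list[EMRRecord],
    encoder: NameSimilarityEncoder,
    index: PrototypeIndex,
    confidence_floor: float = 0.0,
) -> DatasetPartitions:
    """Route records into incomplete-raw vs noisy-labelled pools.

    Records without short text go to the raw pool; all others receive
    noisy labels and a record-level confidence (mean entry cosine). The
    clean pool starts empty and is filled by the annotation loop.
    """
    parts = DatasetPartitions()
    for rec in records:
        labels, assignments = assign_noisy_labels(rec, encoder, index, confidence_floor)
        if labels is None:
            parts.raw_pool.append(rec)
        else:
            parts.noisy_pool.append(rec)
            parts.noisy_labels[rec.record_id] = labels
            parts.confidences[rec.record_id] = float(
                np.mean([a["confidence"] for a in assignments])
            )
    parts.validate()
    return parts
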