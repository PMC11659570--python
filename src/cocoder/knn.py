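"""kNN-optimised inference over a clean-example datastore.

The datastore holds one (document representation, verified label vector)
pair per clean-labelled record. At inference the query representation
retrieves its k nearest entries by Euclidean distance; the retrieved
labels are combined with softmax weights over negative distances
(temperature tau), and the resulting kNN prediction is interpolated with
the model's own probabilities:  y_hat = lambda * y_knn + (1 - lambda) * y_mo.

Decision-support operations — threshold filtering, attention heatmap
export and similar-reference retrieval — live here too, as library
functions rather than a GUI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .records import EMRRecord
from .taxonomy import CodeTaxonomy

__all__ = [
    "Datastore",
    "InferenceConfig",
    "PredictionResult",
    "build_datastore",
    "knn_predict",
    "combine",
    "threshold_filter",
    "similar_references",
    "KNNInterpolator",
    "predict_records",
]


@dataclass
class InferenceConfig:
    k: int = 3
    tau_knn: float = 1.0
    lam: float = 0.3
    threshold: float = 0.5

    def validate(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.tau_knn <= 0:
            raise ValueError("tau_knn must be positive")


@dataclass
class Datastore:
    H: np.ndarray                 # (n, d) clean-record representations
    Y: np.ndarray                 # (n, L) verified label vectors
    record_ids: list[str]
    encoder_fingerprint: str = ""

    def __post_init__(self):
        if len(self.H) == 0:
            raise ValueError("datastore must be non-empty")
        if len(self.H) != len(self.Y) or len(self.H) != len(self.record_ids):
            raise ValueError("datastore fields must be row-aligned")

    def __len__(self):
        return len(self.record_ids)


@dataclass
class PredictionResult:
    record_id: str
    y_mo: np.ndarray
    y_knn: np.ndarray
    y_hat: np.ndarray
    neighbours: list[dict] = field(default_factory=list)
    emitted_codes: list[str] = field(default_factory=list)
    heatmap: dict | None = None


def build_datastore(clean_pool: list[EMRRecord], clean_labels: dict[str, set[str]],
                    coder, taxonomy: CodeTaxonomy) -> Datastore:
    """Embed every clean record with the trained coder and store its gold labels."""
    if not clean_pool:
        raise ValueError("clean pool is empty")
    H = coder.embed(clean_pool)
    Y = np.stack([taxonomy.vectorize(clean_labels[r.record_id]) for r in clean_pool])
    return Datastore(H, Y, [r.record_id for r in clean_pool],
                     coder.encoder_.fingerprint())


def _topk(query: np.ndarray, store: Datastore, k: int):
    d = np.linalg.norm(store.H - query[None, :], axis=1)
    k = min(k, len(store))
    order = sorted(range(len(store)), key=lambda i: (d[i], store.record_ids[i]))[:k]
    return np.asarray(order, dtype=np.intp), d


def knn_predict(query: np.ndarray, store: Datastore, config: InferenceConfig):
    """Softmax-weighted label average of the k nearest datastore entries.

    Weights alpha_i are the softmax of -distance / tau over the retrieved
    set only; y_knn = sum_i alpha_i y_i lies in [0, 1] per code.
    """
    config.validate()
    idx, d = _topk(query, store, config.k)
    logits = -d[idx] / config.tau_knn
    logits -= logits.max()
    alpha = np.exp(logits)
    alpha /= alpha.sum()
    y_knn = alpha @ store.Y[idx]
    neighbours = [
        {
            "record_id": store.record_ids[int(i)],
            "distance": float(d[int(i)]),
            "alpha": float(a),
            "labels": np.flatnonzero(store.Y[int(i)]).tolist(),
        }
        for i, a in zip(idx, alpha)
    ]
    return y_knn, neighbours


def combine(y_knn: np.ndarray, y_mo: np.ndarray, lam: float) -> np.ndarray:
    """Convex interpolation of the kNN and model probabilities."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    y_knn, y_mo = np.asarray(y_knn, float), np.asarray(y_mo, float)
    if y_knn.shape != y_mo.shape:
        raise ValueError("probability vectors must have equal length")
    return lam * y_knn + (1.0 - lam) * y_mo


def threshold_filter(y_hat: np.ndarray, threshold: float, leaf_order: list[str]) -> list[str]:
    """Codes at or above the confidence threshold, most probable first."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    y_hat = np.asarray(y_hat, float)
    picked = [i for i in range(len(y_hat)) if y_hat[i] >= threshold and y_hat[i] > 0]
    picked.sort(key=lambda i: (-y_hat[i], leaf_order[i]))
    return [leaf_order[i] for i in picked]


def similar_references(query_record: EMRRecord, store: Datastore, coder,
                       k: int = 3, tau_knn: float = 1.0) -> list[dict]:
    """The k nearest clean records with distances, weights and label sets."""
    query = coder.embed([query_record])[0]
    _, neighbours = knn_predict(query, store, InferenceConfig(k=k, tau_knn=tau_knn))
    return neighbours


class KNNInterpolator(BaseEstimator):
    """Estimator wrapper: fit stores the datastore, predict_proba interpolates.

    `fit(H, Y)` takes clean-record representations and binary label rows;
    `predict_proba(Hq, y_mo)` returns the interpolated probabilities for
    query representations given the model-only probabilities.
    """

    def __init__(self, k: int = 3, tau_knn: float = 1.0, lam: float = 0.3):
        self.k = k
        self.tau_knn = tau_knn
        self.lam = lam

    def fit(self, H, Y, record_ids=None):
        record_ids = record_ids or [str(i) for i in range(len(H))]
        self.store_ = Datastore(np.asarray(H, float), np.asarray(Y), list(record_ids))
        return self

    def predict_proba(self, Hq, y_mo) -> np.ndarray:
        cfg = InferenceConfig(k=self.k, tau_knn=self.tau_knn, lam=self.lam)
        out = np.empty_like(np.asarray(y_mo, float))
        for i, q in enumerate(np.asarray(Hq, float)):
            y_knn, _ = knn_predict(q, self.store_, cfg)
            out[i] = combine(y_knn, y_mo[i], self.lam)
        return out


def predict_records(records, coder, store: Datastore | None, taxonomy: CodeTaxonomy,
                    config: InferenceConfig, with_heatmap: bool = False):
    """Full per-record inference: model, kNN, interpolation, emission, heatmap."""
    config.validate()
    if store is not None and store.encoder_fingerprint and \
            store.encoder_fingerprint != coder.encoder_.fingerprint():
        raise ValueError("datastore was built with a different encoder version")
    results = []
    for rec in records:
        emb = coder.encoder_.embed_document(rec)
        y_mo = 1.0 / (1.0 + np.exp(-emb.label_logits))
        if store is not None:
            y_knn, neighbours = knn_predict(emb.h_G, store, config)
        else:
            y_knn, neighbours = np.zeros_like(y_mo), []
        y_hat = combine(y_knn, y_mo, config.lam if store is not None else 0.0)
        results.append(PredictionResult(
            record_id=rec.record_id,
            y_mo=y_mo,
            y_knn=y_knn,
            y_hat=y_hat,
            neighbours=neighbours,
            emitted_codes=threshold_filter(y_hat, config.threshold, taxonomy.leaf_order),
            heatmap=emb.heatmap(taxonomy.leaf_order) if with_heatmap else None,
        ))
    return results
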