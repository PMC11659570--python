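"""Three-step contrastive training over the incomplete/noisy/clean pools.

Step 1 pretrains the document encoder with the unsupervised InfoNCE loss
on every available text (incomplete raw records included). Step 2 trains
on the noisy-labelled pool with the label-similarity-weighted contrastive
loss plus a small unsupervised term (gamma, delta). Step 3 refines on the
clean-labelled pool, adding binary cross-entropy through the per-label
attention head (theta). Each step resumes from the previous step's
parameters; any step can be disabled to reproduce the ablation variants
(clean-only, no-pretraining, ...).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._autodiff import Adam, Tensor
from .graph_encoder import DocumentEncoder, EncoderConfig
from .losses import loss_bce, loss_ml_con, loss_us_con
from .records import DatasetPartitions, EMRRecord
from .taxonomy import CodeTaxonomy

__all__ = ["ThreeStepCoder", "train_three_steps"]


def _micro_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = float(((y_pred == 1) & (y_true == 1)).sum())
    fp = float(((y_pred == 1) & (y_true == 0)).sum())
    fn = float(((y_pred == 0) & (y_true == 1)).sum())
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def _unit_rows(z: Tensor) -> Tensor:
    """Project representations onto the unit sphere.

    The distance-based contrastive loss is otherwise minimised by letting
    embedding norms diverge (negatives are pushed to infinite distance);
    normalising the representations bounds pairwise distances in [0, 2].
    """
    return z / ((z * z).sum(axis=1, keepdims=True) + 1e-12).sqrt()


def build_vocab(records: list[EMRRecord], min_count: int = 1) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in records:
        for tok in rec.long_text:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = {}
    for tok in sorted(counts):
        if counts[tok] >= min_count:
            vocab[tok] = len(vocab) + 1  # id 0 reserved for OOV
    return vocab


class ThreeStepCoder(BaseEstimator, ClassifierMixin):
    """Multi-label coding model trained with the three-step contrastive recipe.

    Parameters mirror the published training settings: loss weights
    theta=1, gamma=0.5, delta=0.02; Adam with learning rate 0.001 and
    weight decay 0.001; batch size 64; co-occurrence window 3 and 3 graph
    layers. Temperatures for the two contrastive terms default to 0.05.
    Epoch counts are per step and deliberately configurable so desk-scale
    corpora can train in minutes.

    Fitted attributes: ``encoder_`` (the document encoder with trained
    parameters), ``leaf_order_`` (label coordinate system),
    ``training_log_`` (list of per-epoch loss dicts).
    """

    def __init__(self, embedding_dim: int = 24, graph_window: int = 3,
                 n_graph_layers: int = 3, chunk_length: int = 512,
                 dropout: float = 0.1, theta: float = 1.0, gamma: float = 0.5,
                 delta: float = 0.02, tau_us: float = 0.05, tau_ml: float = 0.05,
                 epochs_step1: int = 1, epochs_step2: int = 2, epochs_step3: int = 6,
                 batch_size: int = 64, learning_rate: float = 1e-3,
                 weight_decay: float = 1e-3, max_grad_norm: float = 5.0,
                 steps: tuple = (1, 2, 3),
                 include_raw_in_step2: bool = False, random_state: int = 0):
        self.embedding_dim = embedding_dim
        self.graph_window = graph_window
        self.n_graph_layers = n_graph_layers
        self.chunk_length = chunk_length
        self.dropout = dropout
        self.theta = theta
        self.gamma = gamma
        self.delta = delta
        self.tau_us = tau_us
        self.tau_ml = tau_ml
        self.epochs_step1 = epochs_step1
        self.epochs_step2 = epochs_step2
        self.epochs_step3 = epochs_step3
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.max_grad_norm = max_grad_norm
        self.steps = steps
        self.include_raw_in_step2 = include_raw_in_step2
        self.random_state = random_state

    # -- internals ------------------------------------------------------------
    def _init_encoder(self, records: list[EMRRecord], n_labels: int) -> DocumentEncoder:
        return self._init_encoder_from_vocab(build_vocab(records), n_labels)

    def _label_matrix(self, records, labels_by_id, taxonomy: CodeTaxonomy) -> np.ndarray:
        # records absent from the mapping (raw pool in step 2) get an all-zero
        # row: zero label overlap means they act purely as negatives.
        return np.stack([
            taxonomy.vectorize(labels_by_id.get(r.record_id, set())) for r in records
        ])

    def _run_step(self, step: int, records, labels_by_id, taxonomy, epochs, rng,
                  validation=None):
        if epochs <= 0 or not records:
            return
        best = (None, -1.0)  # (param snapshot, val micro-F1)
        # each stage gets a fresh optimiser: moment estimates from one
        # objective are not meaningful curvature for the next
        opt = Adam(self.encoder_.params, lr=self.learning_rate,
                   weight_decay=self.weight_decay)
        enc = self.encoder_
        for epoch in range(epochs):
            order = rng.permutation(len(records))
            losses = []
            for start in range(0, len(records), self.batch_size):
                batch = [records[j] for j in order[start: start + self.batch_size]]
                if len(batch) < 2:
                    continue
                opt.zero_grad()
                z, cls_view, logits = enc.forward_batch(batch, rng)
                us = loss_us_con(z, cls_view, self.tau_us)
                if step == 1:
                    loss = us
                else:
                    y = self._label_matrix(batch, labels_by_id, taxonomy)
                    loss = loss_ml_con(_unit_rows(z), y, self.tau_ml) * self.gamma + us * self.delta
                    if step == 3:
                        loss = loss + loss_bce(logits.sigmoid(), y) * self.theta
                loss.backward()
                opt.clip_grad_norm(self.max_grad_norm)
                opt.step()
                losses.append(float(loss.data))
            entry = {
                "step": step, "epoch": epoch, "loss": float(np.mean(losses)) if losses else 0.0,
            }
            if validation is not None:
                val_records, val_y = validation
                val_f1 = _micro_f1(val_y, self.predict_proba(val_records) >= 0.5)
                entry["val_micro_f1"] = val_f1
                if val_f1 > best[1]:
                    best = ({k: v.data.copy() for k, v in enc.params.items()}, val_f1)
            self.training_log_.append(entry)
        if best[0] is not None:
            for k, v in enc.params.items():
                v.data = best[0][k]

    # -- fitting --------------------------------------------------------------
    def fit_partitions(self, partitions: DatasetPartitions, taxonomy: CodeTaxonomy,
                       steps: tuple | None = None, validation=None):
        """Run the enabled steps over the three pools.

        ``validation``: optional (records, binary label matrix) pair; when
        given, step 3 keeps the epoch snapshot with the best validation
        micro-F1 instead of the last epoch's parameters.
        """
        if steps is None:
            steps = tuple(self.steps)
        if 3 in steps and not partitions.clean_pool:
            raise ValueError("step 3 requires a non-empty clean-labelled pool")
        all_records = partitions.raw_pool + partitions.noisy_pool + partitions.clean_pool
        if not all_records:
            raise ValueError("no records to train on")
        self.leaf_order_ = list(taxonomy.leaf_order)
        self.encoder_ = self._init_encoder(all_records, len(self.leaf_order_))
        self.training_log_ = []
        rng = np.random.default_rng(self.random_state + 1)

        clean_by_id = dict(partitions.clean_labels)
        for rec in partitions.clean_pool:
            clean_by_id.setdefault(rec.record_id, set(rec.gold_labels or ()))

        if 1 in steps:
            self._run_step(1, all_records, None, taxonomy, self.epochs_step1, rng)
        if 2 in steps:
            pool = list(partitions.noisy_pool)
            if self.include_raw_in_step2:
                pool = pool + list(partitions.raw_pool)
            self._run_step(2, pool, partitions.noisy_labels, taxonomy,
                           self.epochs_step2, rng)
        if 3 in steps:
            self._run_step(3, partitions.clean_pool, clean_by_id, taxonomy,
                           self.epochs_step3, rng, validation=validation)
        return self

    def fit(self, X, y=None, taxonomy: CodeTaxonomy | None = None):
        """Plain supervised fit (step-3 objective) on records with verified labels.

        ``X`` is a list of records; labels come from each record's
        gold_labels (``y`` may alternatively supply sets of codes).
        """
        if taxonomy is None:
            raise ValueError("fit requires taxonomy= for the label coordinate system")
        parts = DatasetPartitions(clean_pool=list(X))
        for i, rec in enumerate(parts.clean_pool):
            labels = set(y[i]) if y is not None else set(rec.gold_labels or ())
            parts.clean_labels[rec.record_id] = labels
        return self.fit_partitions(parts, taxonomy, steps=(3,))

    # -- inference ------------------------------------------------------------
    def _eval_batches(self, records: list[EMRRecord], chunk: int = 256):
        for start in range(0, len(records), chunk):
            yield self.encoder_.forward_batch(records[start: start + chunk], rng=None)

    def embed(self, records: list[EMRRecord]) -> np.ndarray:
        """Document representations h_G, one row per record."""
        return np.concatenate([h.data for h, _, _ in self._eval_batches(records)])

    def decision_function(self, records: list[EMRRecord]) -> np.ndarray:
        return np.concatenate([l.data for _, _, l in self._eval_batches(records)])

    def predict_proba(self, records: list[EMRRecord]) -> np.ndarray:
        """Model-only probabilities: logistic of the per-code logits."""
        return 1.0 / (1.0 + np.exp(-self.decision_function(records)))

    def predict(self, records: list[EMRRecord], threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(records) >= threshold).astype(np.int8)

    def explain(self, record: EMRRecord) -> dict:
        """Per-code attention heatmap over token positions."""
        emb = self.encoder_.embed_document(record)
        return emb.heatmap(self.leaf_order_)

    # -- persistence ----------------------------------------------------------
    def save(self, out_dir) -> None:
        """Checkpoint: params.npz plus a JSON sidecar of hyperparameters."""
        import json
        import os

        os.makedirs(out_dir, exist_ok=True)
        np.savez(os.path.join(out_dir, "params.npz"),
                 **{k: v.data for k, v in self.encoder_.params.items()})
        with open(os.path.join(out_dir, "meta.json"), "w") as fh:
            json.dump({
                "params": self.get_params(),
                "vocab": self.encoder_.vocab,
                "leaf_order": self.leaf_order_,
                "training_log": self.training_log_,
            }, fh)

    @classmethod
    def load(cls, in_dir) -> "ThreeStepCoder":
        import json
        import os

        with open(os.path.join(in_dir, "meta.json")) as fh:
            meta = json.load(fh)
        hyper = dict(meta["params"])
        hyper["steps"] = tuple(hyper.get("steps", (1, 2, 3)))
        coder = cls(**hyper)
        coder.leaf_order_ = list(meta["leaf_order"])
        coder.training_log_ = meta["training_log"]
        coder.encoder_ = coder._init_encoder_from_vocab(
            meta["vocab"], len(coder.leaf_order_))
        weights = np.load(os.path.join(in_dir, "params.npz"))
        for k, v in coder.encoder_.params.items():
            v.data = weights[k]
        return coder

    def _init_encoder_from_vocab(self, vocab: dict, n_labels: int) -> DocumentEncoder:
        cfg = EncoderConfig(
            embedding_dim=self.embedding_dim, graph_window=self.graph_window,
            n_graph_layers=self.n_graph_layers, chunk_length=self.chunk_length,
            dropout=self.dropout, seed=self.random_state,
        )
        return DocumentEncoder(vocab, n_labels, cfg)


def train_three_steps(partitions: DatasetPartitions, taxonomy: CodeTaxonomy,
                      **params) -> tuple[ThreeStepCoder, list[dict]]:
    """Functional wrapper: fit a ThreeStepCoder and return it with its log."""
    coder = ThreeStepCoder(**params)
    coder.fit_partitions(partitions, taxonomy)
    return coder, coder.training_log_
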