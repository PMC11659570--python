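"""Graph-augmented document encoder with per-label attention.

A document's tokens are embedded (in sliding chunks) by a pluggable base
token encoder — the default is a trainable embedding table — then mapped
onto a word co-occurrence graph: one node per distinct token, an edge
whenever two tokens appear together inside a fixed-size sliding window.
A gated graph network propagates information between co-occurring words;
a soft-attention readout (sigmoid gate x tanh content, then mean plus
max pooling over nodes) yields the document vector; and a per-label
attention head scores every token position per code, producing both the
code logits and an explanation heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import (Tensor, concat, gather_axis1, gather_rows, slice_last,
                        softmax)
from .records import EMRRecord

__all__ = ["EncoderConfig", "TokenGraph", "DocumentEmbedding", "DocumentEncoder",
           "build_cooccurrence_graph"]


@dataclass
class EncoderConfig:
    embedding_dim: int = 24
    graph_window: int = 3
    n_graph_layers: int = 3
    chunk_length: int = 512
    dropout: float = 0.1
    seed: int = 0

    def validate(self):
        if self.graph_window < 2:
            raise ValueError("graph_window must be >= 2")
        if self.n_graph_layers < 1:
            raise ValueError("n_graph_layers must be >= 1")
        if self.embedding_dim < 1 or self.chunk_length < 1:
            raise ValueError("embedding_dim and chunk_length must be positive")


@dataclass
class TokenGraph:
    tokens: list[str]                 # distinct tokens, first-occurrence order
    node_of_position: np.ndarray      # (T,) node index of each token position
    edges: list[tuple[int, int]]      # undirected, u < v, no self-loops

    @property
    def n_nodes(self) -> int:
        return len(self.tokens)

    def adjacency(self, normalised: bool = True) -> np.ndarray:
        A = np.zeros((self.n_nodes, self.n_nodes))
        for u, v in self.edges:
            A[u, v] = A[v, u] = 1.0
        if normalised:
            deg = A.sum(axis=1, keepdims=True)
            A = A / np.where(deg == 0, 1.0, deg)
        return A

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


def build_cooccurrence_graph(tokens: list[str], window: int) -> TokenGraph:
    """Edge (u, v) iff distinct tokens u, v co-occur in some length-`window` span."""
    if not tokens:
        raise ValueError("token list must be non-empty")
    if window < 2:
        raise ValueError("window must be >= 2")
    index: dict[str, int] = {}
    node_of_position = np.empty(len(tokens), dtype=np.intp)
    for i, tok in enumerate(tokens):
        if tok not in index:
            index[tok] = len(index)
        node_of_position[i] = index[tok]
    edges: set[tuple[int, int]] = set()
    for start in range(max(len(tokens) - window + 1, 1)):
        span = node_of_position[start: start + window]
        for a in range(len(span)):
            for b in range(a + 1, len(span)):
                u, v = int(span[a]), int(span[b])
                if u != v:
                    edges.add((min(u, v), max(u, v)))
    return TokenGraph(list(index), node_of_position, sorted(edges))


@dataclass
class DocumentEmbedding:
    h_G: np.ndarray                   # graph-level document vector
    node_states: np.ndarray           # (V, d) post-propagation node states
    label_logits: np.ndarray          # (L,) raw per-code scores
    label_attention: np.ndarray       # (L, T) rows sum to 1
    tokens: list[str] = field(default_factory=list)

    def heatmap(self, leaf_order: list[str]) -> dict:
        return {
            code: [
                (int(p), self.tokens[p], float(self.label_attention[li, p]))
                for p in range(self.label_attention.shape[1])
            ]
            for li, code in enumerate(leaf_order)
        }


class DocumentEncoder:
    """The trainable feature extractor (parameters + forward pass).

    Not an estimator itself: training orchestration lives in
    `cocoder.training.ThreeStepCoder`, which owns one of these.
    """

    def __init__(self, vocab: dict[str, int], n_labels: int, config: EncoderConfig):
        config.validate()
        self.config = config
        self.vocab = dict(vocab)  # token -> id; id 0 is the OOV bucket
        self.n_labels = n_labels
        d = config.embedding_dim
        rng = np.random.default_rng(config.seed)

        def p(*shape, scale=None):
            scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        self.params: dict[str, Tensor] = {
            "E": p(len(self.vocab) + 1, d, scale=0.1),
            "W_msg": p(d, d), "b_msg": Tensor(np.zeros(d), requires_grad=True),
            # update and reset gates fused into one projection, split after
            "W_zr": p(2 * d, 2 * d), "b_zr": Tensor(np.zeros(2 * d), requires_grad=True),
            "W_h": p(2 * d, d), "b_h": Tensor(np.zeros(d), requires_grad=True),
            "W_f1": p(d, d), "b_f1": Tensor(np.zeros(d), requires_grad=True),
            "W_f2": p(d, d), "b_f2": Tensor(np.zeros(d), requires_grad=True),
            "U_attn": p(d, n_labels),
            "W_out": p(d, n_labels), "b_out": Tensor(np.zeros(n_labels), requires_grad=True),
        }
        self._cache: dict[str, tuple] = {}

    # -- plumbing -------------------------------------------------------------
    def fingerprint(self) -> str:
        h = 0
        for k in sorted(self.params):
            h ^= hash((k, self.params[k].data.round(8).tobytes()))
        return f"{h & 0xFFFFFFFFFFFF:012x}"

    def token_ids(self, tokens: list[str]) -> np.ndarray:
        return np.asarray([self.vocab.get(t, 0) for t in tokens], dtype=np.intp)

    def _doc_cache(self, record: EMRRecord):
        """Per-document static structure: chunked ids, graph, adjacency."""
        tokens = record.long_text
        hit = self._cache.get(record.record_id)
        if hit is not None and hit[4] == tokens:
            return hit
        if not tokens:
            raise ValueError(f"record {record.record_id!r} has empty long_text")
        # chunked base encoding: the embedding-table encoder is context-free,
        # so chunk boundaries do not alter features; the chunk walk is kept so
        # contextual base encoders slot in unchanged.
        ids = np.concatenate([
            self.token_ids(tokens[s: s + self.config.chunk_length])
            for s in range(0, len(tokens), self.config.chunk_length)
        ])
        graph = build_cooccurrence_graph(tokens, self.config.graph_window)
        node_ids = ids[[int(np.argmax(graph.node_of_position == v))
                        for v in range(graph.n_nodes)]]
        entry = (ids, graph, graph.adjacency(), node_ids, list(tokens))
        if len(self._cache) < 100_000:
            self._cache[record.record_id] = entry
        return entry

    # -- forward pieces -------------------------------------------------------
    def propagate(self, H: Tensor, A: np.ndarray) -> Tensor:
        """Gated (GRU-style) message passing; isolated nodes see a zero message."""
        P = self.params
        d = self.config.embedding_dim
        At = Tensor(A)
        for _ in range(self.config.n_graph_layers):
            m = At @ H @ P["W_msg"] + P["b_msg"]
            gates = (concat([m, H], axis=1) @ P["W_zr"] + P["b_zr"]).sigmoid()
            zgate = slice_last(gates, 0, d)
            rgate = slice_last(gates, d, 2 * d)
            cand = (concat([m, H * rgate], axis=1) @ P["W_h"] + P["b_h"]).tanh()
            H = H * (1.0 - zgate) + cand * zgate
            if not np.isfinite(H.data).all():
                raise FloatingPointError("non-finite node states during propagation")
        return H

    def readout(self, H: Tensor) -> Tensor:
        """Soft-attention gate, then mean + max pooling over nodes."""
        P = self.params
        gated = (H @ P["W_f1"] + P["b_f1"]).sigmoid() * (H @ P["W_f2"] + P["b_f2"]).tanh()
        return gated.mean(axis=0) + gated.max(axis=0)

    def label_head(self, H: Tensor, node_of_position: np.ndarray) -> tuple[Tensor, Tensor]:
        """Per-code attention over token positions and the resulting logits."""
        P = self.params
        states = gather_rows(H, node_of_position)            # (T, d)
        scores = states @ P["U_attn"]                        # (T, L)
        attn = softmax(scores, axis=0)                       # columns sum to 1
        context = attn.T @ states                            # (L, d)
        logits = (context * P["W_out"].T).sum(axis=1) + P["b_out"]
        return logits, attn.T

    def _forward(self, record: EMRRecord, rng: np.random.Generator | None):
        ids, graph, A, node_ids, _ = self._doc_cache(record)
        H0 = gather_rows(self.params["E"], node_ids)
        H = self.propagate(H0, A)
        h_G = self.readout(H)
        logits, attn = self.label_head(H, graph.node_of_position)
        # pooled alternate view (dropout over positions) for the InfoNCE positive
        pos_emb = gather_rows(self.params["E"], ids)
        if rng is not None and self.config.dropout > 0:
            keep = (rng.random((len(ids), 1)) >= self.config.dropout).astype(float)
            pos_emb = pos_emb * Tensor(keep / (1.0 - self.config.dropout))
        cls_view = pos_emb.mean(axis=0)
        return h_G, cls_view, logits, attn, H, graph

    # -- public inference -----------------------------------------------------
    def embed_document(self, record: EMRRecord) -> DocumentEmbedding:
        h_G, _, logits, attn, H, graph = self._forward(record, rng=None)
        return DocumentEmbedding(
            h_G=h_G.data.copy(),
            node_states=H.data.copy(),
            label_logits=logits.data.copy(),
            label_attention=attn.data.copy(),
            tokens=list(record.long_text),
        )

    # -- batched (padded) forward --------------------------------------------
    def _batch_arrays(self, records: list[EMRRecord]):
        """Pad per-document structure into batch arrays (cached per id set)."""
        docs = [self._doc_cache(r) for r in records]
        B = len(docs)
        Vmax = max(len(d[3]) for d in docs)
        Tmax = max(len(d[0]) for d in docs)
        node_ids = np.zeros((B, Vmax), dtype=np.intp)
        A = np.zeros((B, Vmax, Vmax))
        pos_idx = np.zeros((B, Tmax), dtype=np.intp)
        ids = np.zeros((B, Tmax), dtype=np.intp)
        node_mask = np.zeros((B, Vmax, 1))
        pos_mask = np.zeros((B, Tmax, 1))
        n_nodes = np.empty(B)
        n_pos = np.empty(B)
        for b, (doc_ids, graph, adj, doc_node_ids, _) in enumerate(docs):
            V, T = len(doc_node_ids), len(doc_ids)
            node_ids[b, :V] = doc_node_ids
            A[b, :V, :V] = adj
            pos_idx[b, :T] = graph.node_of_position
            ids[b, :T] = doc_ids
            node_mask[b, :V] = 1.0
            pos_mask[b, :T] = 1.0
            n_nodes[b], n_pos[b] = V, T
        return node_ids, A, pos_idx, ids, node_mask, pos_mask, n_nodes, n_pos

    def forward_batch(self, records: list[EMRRecord], rng: np.random.Generator | None):
        """Stacked (h_G, cls_view, logits) tensors for a padded minibatch.

        Numerically matches the per-document forward pass to floating-point
        reassociation error; padded nodes/positions are masked out of the
        readout pooling and the attention softmax.
        """
        node_ids, A, pos_idx, ids, node_mask, pos_mask, n_nodes, n_pos = \
            self._batch_arrays(records)
        P = self.params

        d = self.config.embedding_dim
        H = gather_rows(P["E"], node_ids)                       # (B, V, d)
        At = Tensor(A)
        for _ in range(self.config.n_graph_layers):
            m = At @ H @ P["W_msg"] + P["b_msg"]
            gates = (concat([m, H], axis=2) @ P["W_zr"] + P["b_zr"]).sigmoid()
            zgate = slice_last(gates, 0, d)
            rgate = slice_last(gates, d, 2 * d)
            cand = (concat([m, H * rgate], axis=2) @ P["W_h"] + P["b_h"]).tanh()
            H = H * (1.0 - zgate) + cand * zgate
        if not np.isfinite(H.data).all():
            raise FloatingPointError("non-finite node states during propagation")

        gated = (H @ P["W_f1"] + P["b_f1"]).sigmoid() * (H @ P["W_f2"] + P["b_f2"]).tanh()
        nm = Tensor(node_mask)
        mean_part = (gated * nm).sum(axis=1) * Tensor(1.0 / n_nodes[:, None])
        max_part = (gated * nm + Tensor((node_mask - 1.0) * 1e9)).max(axis=1)
        h_G = mean_part + max_part                               # (B, d)

        states = gather_axis1(H, pos_idx)                        # (B, T, d)
        scores = states @ P["U_attn"] + Tensor((pos_mask - 1.0) * 1e30)
        attn = softmax(scores, axis=1)                           # (B, T, L)
        context = attn.swapaxes(1, 2) @ states                   # (B, L, d)
        logits = (context * P["W_out"].T).sum(axis=2) + P["b_out"]

        pos_emb = gather_rows(P["E"], ids) * Tensor(pos_mask)
        if rng is not None and self.config.dropout > 0:
            keep = (rng.random(pos_mask.shape) >= self.config.dropout).astype(float)
            pos_emb = pos_emb * Tensor(keep / (1.0 - self.config.dropout))
        cls_view = pos_emb.sum(axis=1) * Tensor(1.0 / n_pos[:, None])
        return h_G, cls_view, logits
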