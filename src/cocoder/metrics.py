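"""Multi-label evaluation: AUC, F1, Recall@k, chapter-level aggregation.

Macro metrics average per-code scores over codes with at least one test
positive (few-shot codes with zero support are excluded and counted);
micro metrics pool confusion counts over all codes. Recall@k is the
fraction of a sample's true codes found among its k highest-scoring
predictions, averaged over samples with at least one true code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, roc_auc_score

from .taxonomy import CodeTaxonomy

__all__ = ["MetricReport", "compute_metrics", "chapter_aggregate"]


@dataclass
class MetricReport:
    macro_auc: float
    micro_auc: float
    macro_f1: float
    micro_f1: float
    recall_at: dict[int, float]
    n_test: int
    threshold: float
    n_codes_excluded_macro: int = 0
    per_chapter_micro_f1: dict[str, float | None] = field(default_factory=dict)
    confusion: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["recall_at"] = {str(k): v for k, v in self.recall_at.items()}
        return d


def _recall_at_k(Y: np.ndarray, S: np.ndarray, k: int) -> float:
    vals = []
    for i in range(len(Y)):
        true = np.flatnonzero(Y[i])
        if len(true) == 0:
            continue
        top = np.argsort(-S[i], kind="stable")[:k]
        vals.append(len(set(true) & set(top)) / len(true))
    return float(np.mean(vals)) if vals else float("nan")


def compute_metrics(y_true, y_score, threshold: float = 0.5, ks=(5,)) -> MetricReport:
    """Score a probability matrix against binary gold labels."""
    Y = np.asarray(y_true)
    S = np.asarray(y_score, float)
    if Y.shape != S.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {S.shape}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    P = (S >= threshold).astype(np.int8)

    support = Y.sum(axis=0)
    with_pos = np.flatnonzero(support > 0)
    n_excluded = Y.shape[1] - len(with_pos)

    micro_f1 = float(f1_score(Y.ravel(), P.ravel(), zero_division=0.0))
    # per-code mean rather than sklearn's multilabel macro: a single-column
    # indicator would otherwise be reinterpreted as a binary class vector
    macro_f1 = (
        float(np.mean([f1_score(Y[:, j], P[:, j], zero_division=0.0) for j in with_pos]))
        if len(with_pos) else float("nan")
    )

    # AUC needs both classes present per code
    auc_codes = [j for j in with_pos if support[j] < Y.shape[0]]
    macro_auc = (
        float(np.mean([roc_auc_score(Y[:, j], S[:, j]) for j in auc_codes]))
        if auc_codes else float("nan")
    )
    flat_y = Y.ravel()
    micro_auc = (
        float(roc_auc_score(flat_y, S.ravel()))
        if 0 < flat_y.sum() < flat_y.size else float("nan")
    )

    tp = int(((P == 1) & (Y == 1)).sum())
    fp = int(((P == 1) & (Y == 0)).sum())
    fn = int(((P == 0) & (Y == 1)).sum())
    return MetricReport(
        macro_auc=macro_auc,
        micro_auc=micro_auc,
        macro_f1=macro_f1,
        micro_f1=micro_f1,
        recall_at={k: _recall_at_k(Y, S, k) for k in ks},
        n_test=int(Y.shape[0]),
        threshold=threshold,
        n_codes_excluded_macro=int(n_excluded),
        confusion={"tp": tp, "fp": fp, "fn": fn},
    )


def chapter_aggregate(y_true, y_pred, taxonomy: CodeTaxonomy) -> dict[str, float | None]:
    """Micro-F1 per chapter, confusion counts pooled within each chapter's codes.

    Chapters with zero test positives and zero predictions map to None
    (not applicable).
    """
    Y = np.asarray(y_true)
    P = np.asarray(y_pred)
    if Y.shape != P.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {P.shape}")
    out: dict[str, float | None] = {}
    chapter_cols: dict[str, list[int]] = {}
    for j, code in enumerate(taxonomy.leaf_order):
        chapter_cols.setdefault(taxonomy.chapter_of(code), []).append(j)
    for chap in taxonomy.chapters:
        cols = chapter_cols.get(chap, [])
        if not cols:
            out[chap] = None
            continue
        y, p = Y[:, cols], P[:, cols]
        tp = int(((p == 1) & (y == 1)).sum())
        fp = int(((p == 1) & (y == 0)).sum())
        fn = int(((p == 0) & (y == 1)).sum())
        if tp + fp + fn == 0:
            out[chap] = None
        else:
            out[chap] = 2 * tp / (2 * tp + fp + fn)
    return out
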