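"""Dynamic and iterative collaborative annotation allocation.

Selects patches of candidate records from the noisy-labelled pool for
(simulated) manual coding so that every code accumulates at least ``s``
clean samples with minimal workload. The initial patch greedily covers
every code with at least ``init_min_per_code`` candidates (by noisy
labels); subsequent patches prioritise records carrying the most
under-covered codes. Manual coding is simulated by an oracle that reveals
the gold labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import DatasetPartitions

__all__ = [
    "AllocatorConfig",
    "CoverageState",
    "initial_patch",
    "next_patch",
    "oracle_annotate",
    "run_annotation_loop",
]


@dataclass
class AllocatorConfig:
    s: int = 35
    patch_size: int = 50
    init_min_per_code: int = 2
    confidence_threshold: float = 0.0
    max_patches: int = 10_000
    max_annotations: int | None = None  # hard manual-annotation budget
    seed: int = 0

    def validate(self):
        if self.s < 1 or self.patch_size < 1 or self.init_min_per_code < 1:
            raise ValueError("s, patch_size and init_min_per_code must be >= 1")
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must be in [0, 1]")


@dataclass
class CoverageState:
    clean_counts: dict[str, int] = field(default_factory=dict)
    annotated_ids: set[str] = field(default_factory=set)
    patch_history: list[list[str]] = field(default_factory=list)

    def recount(self, clean_labels: dict[str, set[str]]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for labels in clean_labels.values():
            for c in labels:
                counts[c] = counts.get(c, 0) + 1
        return counts


def _eligible(partitions: DatasetPartitions, state: CoverageState, config: AllocatorConfig):
    out = []
    for rec in partitions.noisy_pool:
        rid = rec.record_id
        if rid in state.annotated_ids:
            continue
        if partitions.confidences.get(rid, 1.0) < config.confidence_threshold:
            continue
        out.append(rec)
    return out


def _rank_key(rid: str, priority: int, confidence: float, jitter: float):
    # higher priority first, then higher confidence, then seeded random, then id
    return (-priority, -confidence, jitter, rid)


def initial_patch(partitions: DatasetPartitions, config: AllocatorConfig) -> tuple[list[str], dict[str, int]]:
    """Greedy cover: every code seen in the noisy pool gets >= init_min_per_code records.

    Returns (selected record_ids, deficiency per code) where a deficiency
    entry reports how many candidates short of the target a code is.
    """
    config.validate()
    if not partitions.noisy_pool:
        raise ValueError("noisy pool is empty")
    rng = np.random.default_rng(config.seed)
    state = CoverageState()
    candidates = _eligible(partitions, state, config)
    jitter = {r.record_id: rng.random() for r in candidates}
    codes = sorted({c for r in candidates for c in partitions.noisy_labels[r.record_id]})
    need = {c: config.init_min_per_code for c in codes}
    selected: list[str] = []
    selected_set: set[str] = set()
    while any(v > 0 for v in need.values()):
        best = None
        for rec in candidates:
            rid = rec.record_id
            if rid in selected_set:
                continue
            gain = sum(1 for c in partitions.noisy_labels[rid] if need.get(c, 0) > 0)
            if gain == 0:
                continue
            key = _rank_key(rid, gain, partitions.confidences.get(rid, 0.0), jitter[rid])
            if best is None or key < best[0]:
                best = (key, rid)
        if best is None:
            break  # remaining demand unattainable from the pool
        rid = best[1]
        selected.append(rid)
        selected_set.add(rid)
        for c in partitions.noisy_labels[rid]:
            if need.get(c, 0) > 0:
                need[c] -= 1
    deficiency = {c: v for c, v in need.items() if v > 0}
    return selected, deficiency


def next_patch(state: CoverageState, partitions: DatasetPartitions,
               config: AllocatorConfig, rng: np.random.Generator) -> list[str]:
    """Select up to patch_size unannotated records carrying under-covered codes.

    Priority: number of under-covered codes carried (by noisy labels),
    then auto-annotation confidence, then seeded random.
    """
    under = {c for c, n in state.clean_counts.items() if n < config.s}
    under |= {
        c
        for r in partitions.noisy_pool
        if r.record_id not in state.annotated_ids
        for c in partitions.noisy_labels[r.record_id]
        if state.clean_counts.get(c, 0) < config.s
    }
    ranked = []
    for rec in _eligible(partitions, state, config):
        rid = rec.record_id
        carried = sum(1 for c in partitions.noisy_labels[rid] if c in under)
        if carried == 0:
            continue
        ranked.append((_rank_key(rid, carried, partitions.confidences.get(rid, 0.0), rng.random()), rid))
    ranked.sort()
    return [rid for _, rid in ranked[: config.patch_size]]


def oracle_annotate(record_ids: list[str], partitions: DatasetPartitions) -> list[dict]:
    """Simulated manual coding: move records to the clean pool with gold labels.

    Returns a per-record correction audit listing codes the oracle removed
    from / added to the noisy label set.
    """
    by_id = {r.record_id: r for r in partitions.noisy_pool}
    audit = []
    for rid in record_ids:
        rec = by_id[rid]
        if rec.gold_labels is None:
            raise ValueError(f"record {rid!r} has no gold labels to simulate coding")
        noisy = partitions.noisy_labels.get(rid, set())
        gold = set(rec.gold_labels)
        audit.append({
            "record_id": rid,
            "removed": sorted(noisy - gold),
            "added": sorted(gold - noisy),
        })
        partitions.clean_labels[rid] = gold
        partitions.clean_pool.append(rec)
    moved = set(record_ids)
    partitions.noisy_pool = [r for r in partitions.noisy_pool if r.record_id not in moved]
    return audit


def run_annotation_loop(partitions: DatasetPartitions, config: AllocatorConfig):
    """Alternate patch selection and oracle coding until per-code coverage >= s.

    Coverage is counted on verified (clean) labels. Stops on full coverage
    of every code reachable from the pool, on candidate exhaustion (with a
    deficiency report), or at max_patches (warning status).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    state = CoverageState()

    universe = sorted(
        {c for labels in partitions.noisy_labels.values() for c in labels}
        | {c for labels in partitions.clean_labels.values() for c in labels}
    )
    budget = config.max_annotations if config.max_annotations is not None else np.inf

    first, init_deficiency = initial_patch(partitions, config)
    if len(first) > budget:
        first = first[: int(budget)]
    for audit_entry in oracle_annotate(first, partitions):
        state.annotated_ids.add(audit_entry["record_id"])
    state.patch_history.append(first)
    state.clean_counts = state.recount(partitions.clean_labels)

    status = "complete"
    while True:
        uncovered = [c for c in universe if state.clean_counts.get(c, 0) < config.s]
        if not uncovered:
            break
        if len(state.patch_history) >= config.max_patches:
            status = "max_patches"
            break
        remaining = budget - len(state.annotated_ids)
        if remaining <= 0:
            status = "budget"
            break
        patch = next_patch(state, partitions, config, rng)
        if not patch:
            status = "exhausted"
            break
        if len(patch) > remaining:
            patch = patch[: int(remaining)]
        for audit_entry in oracle_annotate(patch, partitions):
            state.annotated_ids.add(audit_entry["record_id"])
        state.patch_history.append(patch)
        state.clean_counts = state.recount(partitions.clean_labels)

    report = {
        "status": status,
        "workload": len(state.annotated_ids),
        "n_patches": len(state.patch_history),
        "clean_counts": dict(sorted(state.clean_counts.items())),
        "initial_deficiency": init_deficiency,
        "uncovered": sorted(
            c for c in universe if state.clean_counts.get(c, 0) < config.s
        ),
    }
    return partitions, state, report
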