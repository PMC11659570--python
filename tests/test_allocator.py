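"""Annotation-allocation loop: coverage guarantees, workload monotonicity,
pool conservation, budget caps."""

import numpy as np
import pytest

from cocoder.allocator import (AllocatorConfig, CoverageState, initial_patch,
                               next_patch, oracle_annotate, run_annotation_loop)
from cocoder.records import DatasetPartitions, EMRRecord
from cocoder.simulate import GeneratorConfig, generate_corpus, generate_taxonomy


def make_pool(n_codes=20, n_records=200, seed=0, noisy_equals_gold=True):
    cfg = GeneratorConfig(n_codes=n_codes, n_records=n_records, doc_length_mean=6,
                          background_vocab_size=10, incomplete_fraction=0.0,
                          codes_per_doc_mean=3.0, seed=seed)
    tax = generate_taxonomy(cfg)
    records = generate_corpus(tax, cfg)
    rng = np.random.default_rng(seed + 1)
    parts = DatasetPartitions(noisy_pool=records)
    for r in records:
        labels = set(r.gold_labels)
        if not noisy_equals_gold and rng.random() < 0.3 and len(labels) > 1:
            labels.pop()  # drop one code: a noisy-label error
        parts.noisy_labels[r.record_id] = labels
        parts.confidences[r.record_id] = float(rng.random())
    return tax, parts


def recount(parts):
    counts = {}
    for labels in parts.clean_labels.values():
        for c in labels:
            counts[c] = counts.get(c, 0) + 1
    return counts


def test_initial_patch_covers_every_code_twice():
    _, parts = make_pool()
    selected, deficiency = initial_patch(parts, AllocatorConfig(init_min_per_code=2, seed=1))
    counts = {}
    for rid in selected:
        for c in parts.noisy_labels[rid]:
            counts[c] = counts.get(c, 0) + 1
    pool_support = {}
    for labels in parts.noisy_labels.values():
        for c in labels:
            pool_support[c] = pool_support.get(c, 0) + 1
    for code, support in pool_support.items():
        assert counts.get(code, 0) >= min(2, support)
    assert not deficiency


def test_initial_patch_reports_deficient_singleton_code():
    parts = DatasetPartitions(
        noisy_pool=[EMRRecord("a", ["x"], ["t"]), EMRRecord("b", ["y"], ["t"])],
        noisy_labels={"a": {"C1"}, "b": {"C1", "C2"}},
        confidences={"a": 0.9, "b": 0.8},
    )
    selected, deficiency = initial_patch(parts, AllocatorConfig(init_min_per_code=2, seed=0))
    assert deficiency == {"C2": 1}
    assert "b" in selected  # the only carrier of C2 is selected


def test_initial_patch_deterministic():
    _, parts = make_pool(seed=4)
    cfg = AllocatorConfig(seed=7)
    assert initial_patch(parts, cfg) == initial_patch(parts, cfg)


def test_next_patch_prioritises_under_covered_carrier():
    parts = DatasetPartitions(
        noisy_pool=[EMRRecord("a", ["x"], ["t"]), EMRRecord("b", ["y"], ["t"])],
        noisy_labels={"a": {"C9"}, "b": {"C1"}},
        confidences={"a": 0.1, "b": 0.99},
    )
    state = CoverageState(clean_counts={"C9": 0, "C1": 5}, annotated_ids=set())
    cfg = AllocatorConfig(s=5, patch_size=1, seed=0)
    patch = next_patch(state, parts, cfg, np.random.default_rng(0))
    assert patch == ["a"]  # carries the only under-covered code despite low confidence


def test_oracle_annotate_moves_records_and_audits_corrections():
    parts = DatasetPartitions(
        noisy_pool=[EMRRecord("a", ["x"], ["t"], gold_labels={"C1", "C2"}),
                    EMRRecord("b", ["y"], ["t"], gold_labels={"C3"})],
        noisy_labels={"a": {"C1", "C2"}, "b": {"C4"}},
    )
    audit = oracle_annotate(["a", "b"], parts)
    assert audit[0] == {"record_id": "a", "removed": [], "added": []}
    assert audit[1] == {"record_id": "b", "removed": ["C4"], "added": ["C3"]}
    assert not parts.noisy_pool
    assert parts.clean_labels == {"a": {"C1", "C2"}, "b": {"C3"}}
    parts.validate()


def test_loop_reaches_coverage_and_conserves_records():
    tax, parts = make_pool(n_codes=15, n_records=300, seed=2, noisy_equals_gold=False)
    n_before = parts.n_records
    parts, state, report = run_annotation_loop(parts, AllocatorConfig(s=3, seed=2))
    assert report["status"] == "complete"
    assert parts.n_records == n_before
    assert not (set(r.record_id for r in parts.clean_pool)
                & set(r.record_id for r in parts.noisy_pool))
    counts = recount(parts)
    # coverage counted on verified labels: every code with enough gold support
    gold_support = {}
    for r in parts.clean_pool + parts.noisy_pool:
        for c in r.gold_labels:
            gold_support[c] = gold_support.get(c, 0) + 1
    for code in report["clean_counts"]:
        if gold_support.get(code, 0) >= 3 and code not in report["uncovered"]:
            assert counts.get(code, 0) >= 3


def test_clean_pool_error_rate_zero_after_annotation():
    _, parts = make_pool(seed=3, noisy_equals_gold=False)
    parts, _, _ = run_annotation_loop(parts, AllocatorConfig(s=2, seed=3))
    for rec in parts.clean_pool:
        assert parts.clean_labels[rec.record_id] == rec.gold_labels


def test_unattainable_s_terminates_with_deficiency():
    _, parts = make_pool(n_codes=10, n_records=40, seed=5)
    parts, _, report = run_annotation_loop(parts, AllocatorConfig(s=1000, seed=5))
    assert report["status"] == "exhausted"
    assert report["uncovered"]
    assert report["workload"] == 40  # everything was annotated before giving up


def test_workload_monotone_in_s():
    workloads = []
    for s in (2, 5, 10):
        _, parts = make_pool(n_codes=12, n_records=400, seed=6)
        _, _, report = run_annotation_loop(parts, AllocatorConfig(s=s, seed=6))
        workloads.append(report["workload"])
    assert workloads == sorted(workloads)


def test_annotation_budget_cap_is_hard():
    _, parts = make_pool(n_codes=12, n_records=400, seed=8)
    parts, _, report = run_annotation_loop(
        parts, AllocatorConfig(s=50, max_annotations=37, seed=8))
    assert report["workload"] == 37
    assert report["status"] in ("budget", "complete")


def test_unique_code_per_record_forces_minimum_workload():
    n = 8
    parts = DatasetPartitions(
        noisy_pool=[EMRRecord(f"r{i}", ["x"], ["t"], gold_labels={f"C{i}"})
                    for i in range(n)],
        noisy_labels={f"r{i}": {f"C{i}"} for i in range(n)},
    )
    parts, _, report = run_annotation_loop(parts, AllocatorConfig(s=1, seed=0))
    assert report["workload"] == n


def test_empty_pool_rejected():
    with pytest.raises(ValueError):
        initial_patch(DatasetPartitions(), AllocatorConfig())
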