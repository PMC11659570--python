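"""EMR-like record schema, JSONL IO, and the three training pools.

A record mirrors one hospital admission: a structured short-text section
(a list of clinician-written disease/procedure name strings, possibly
empty for incomplete records), an unstructured long free-text section
(token sequence), optional gold code labels, and section-presence flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

__all__ = ["EMRRecord", "DatasetPartitions", "read_records", "write_records",
           "save_partitions", "load_partitions"]


@dataclass
class EMRRecord:
    record_id: str
    short_text: list[str]
    long_text: list[str]
    gold_labels: set[str] | None = None
    section_flags: dict[str, bool] = field(
        default_factory=lambda: {"specialist_condition": True, "auxiliary_examination": True}
    )

    def __post_init__(self):
        if not self.long_text:
            raise ValueError(f"record {self.record_id!r}: long_text must be non-empty")

    @property
    def is_incomplete(self) -> bool:
        return len(self.short_text) == 0

    def copy(self) -> "EMRRecord":
        return replace(
            self,
            short_text=list(self.short_text),
            long_text=list(self.long_text),
            gold_labels=set(self.gold_labels) if self.gold_labels is not None else None,
            section_flags=dict(self.section_flags),
        )

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "short_text": list(self.short_text),
            "long_text": list(self.long_text),
            "gold_labels": sorted(self.gold_labels) if self.gold_labels is not None else None,
            "section_flags": dict(self.section_flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EMRRecord":
        gold = d.get("gold_labels")
        return cls(
            record_id=d["record_id"],
            short_text=list(d["short_text"]),
            long_text=list(d["long_text"]),
            gold_labels=set(gold) if gold is not None else None,
            section_flags=dict(d.get("section_flags", {})),
        )


def read_records(path) -> list[EMRRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(EMRRecord.from_dict(json.loads(line)))
    return out


def write_records(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(r.to_dict()) + "\n")


@dataclass
class DatasetPartitions:
    """The three training pools: incomplete-raw, noisy-labelled, clean-labelled.

    `noisy_labels` maps record_id -> set of auto-assigned codes;
    `clean_labels` maps record_id -> verified codes. Pools are disjoint by
    construction and a record moves from noisy to clean when annotated.
    """

    raw_pool: list[EMRRecord] = field(default_factory=list)
    noisy_pool: list[EMRRecord] = field(default_factory=list)
    clean_pool: list[EMRRecord] = field(default_factory=list)
    noisy_labels: dict[str, set[str]] = field(default_factory=dict)
    clean_labels: dict[str, set[str]] = field(default_factory=dict)
    confidences: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        ids = [r.record_id for pool in (self.raw_pool, self.noisy_pool, self.clean_pool) for r in pool]
        if len(ids) != len(set(ids)):
            raise ValueError("pools are not disjoint")

    @property
    def n_records(self) -> int:
        return len(self.raw_pool) + len(self.noisy_pool) + len(self.clean_pool)


def save_partitions(partitions: DatasetPartitions, out_dir) -> None:
    """Write the three pools and their label maps under a directory."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    write_records(partitions.raw_pool, os.path.join(out_dir, "raw.jsonl"))
    write_records(partitions.noisy_pool, os.path.join(out_dir, "noisy.jsonl"))
    write_records(partitions.clean_pool, os.path.join(out_dir, "clean.jsonl"))
    with open(os.path.join(out_dir, "labels.json"), "w") as fh:
        json.dump({
            "noisy_labels": {k: sorted(v) for k, v in partitions.noisy_labels.items()},
            "clean_labels": {k: sorted(v) for k, v in partitions.clean_labels.items()},
            "confidences": partitions.confidences,
        }, fh, indent=1)


def load_partitions(in_dir) -> DatasetPartitions:
    import os

    with open(os.path.join(in_dir, "labels.json")) as fh:
        labels = json.load(fh)
    parts = DatasetPartitions(
        raw_pool=read_records(os.path.join(in_dir, "raw.jsonl")),
        noisy_pool=read_records(os.path.join(in_dir, "noisy.jsonl")),
        clean_pool=read_records(os.path.join(in_dir, "clean.jsonl")),
        noisy_labels={k: set(v) for k, v in labels["noisy_labels"].items()},
        clean_labels={k: set(v) for k, v in labels["clean_labels"].items()},
        confidences=dict(labels["confidences"]),
    )
    parts.validate()
    return parts
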