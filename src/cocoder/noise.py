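"""Raw-data quality-control simulator: controlled corruption of short text.

Injects the three error families observed in clinician-written structured
short text, exploiting the taxonomy hierarchy:

* ``vague``   — replace a disease name with an informal name of one of its
  upper-level (ancestor) codes;
* ``wrong``   — replace it with an informal name of a same-level (sibling)
  code;
* ``missing`` — delete the name entry.

The corruption never touches the long free text or the gold labels; the
gold standard is retained to simulate manual coding later. Noise ratio is
defined per short-text name entry, giving exact count control:
round(noise_ratio x total entries) entries are corrupted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import EMRRecord
from .taxonomy import CodeTaxonomy

__all__ = ["NoiseConfig", "CorruptionRecord", "corrupt_dataset", "noise_sweep"]

ERROR_TYPES = ("vague", "wrong", "missing")


@dataclass
class NoiseConfig:
    noise_ratio: float = 0.3
    type_mix: tuple = (1 / 3, 1 / 3, 1 / 3)  # (vague, wrong, missing)
    seed: int = 0

    def validate(self):
        if not 0.0 <= self.noise_ratio <= 1.0:
            raise ValueError(f"noise_ratio must be in [0, 1], got {self.noise_ratio}")
        if len(self.type_mix) != 3 or abs(sum(self.type_mix) - 1.0) > 1e-9 or min(self.type_mix) < 0:
            raise ValueError(f"type_mix must be 3 non-negative probabilities summing to 1")


@dataclass
class CorruptionRecord:
    record_id: str
    entry_index: int
    error_type: str
    original_code: str
    replacement_code: str | None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _name_to_code(taxonomy: CodeTaxonomy) -> dict[str, str]:
    """Exact-name lookup over leaf standard names and variants (gold alignment)."""
    lookup: dict[str, str] = {}
    for cid in taxonomy.leaf_order:
        code = taxonomy.codes[cid]
        lookup.setdefault(code.standard_name, cid)
        for v in code.informal_variants:
            lookup.setdefault(v, cid)
    return lookup


def corrupt_dataset(
    records: list[EMRRecord],
    taxonomy: CodeTaxonomy,
    config: NoiseConfig,
) -> tuple[list[EMRRecord], list[CorruptionRecord]]:
    """Corrupt exactly round(noise_ratio x N_entries) short-text entries.

    Entries are selected uniformly at random over all complete records;
    each selected entry's error type is drawn from ``type_mix``. When the
    drawn type is infeasible for that entry (no ancestor or sibling carries
    informal variants), the type is resampled among the feasible ones so
    the exact corruption count is preserved.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lookup = _name_to_code(taxonomy)

    entries = []  # (record index, entry index)
    for ri, rec in enumerate(records):
        for ei in range(len(rec.short_text)):
            entries.append((ri, ei))
    n_target = int(round(config.noise_ratio * len(entries)))
    if n_target > 0 and not entries:
        raise ValueError("cannot corrupt: no short-text entries present")

    out = [rec.copy() for rec in records]
    audit: list[CorruptionRecord] = []
    if n_target == 0:
        return out, audit

    chosen = rng.choice(len(entries), size=n_target, replace=False)
    deletions: dict[int, list[int]] = {}
    for flat in sorted(chosen.tolist()):
        ri, ei = entries[flat]
        rec = out[ri]
        name = rec.short_text[ei]
        code_id = lookup.get(name)
        if code_id is None:
            raise ValueError(
                f"record {rec.record_id!r} entry {ei} ({name!r}) has no gold code alignment"
            )
        vague_pool = [a for a in taxonomy.ancestors_of(code_id)
                      if taxonomy.codes[a].informal_variants]
        wrong_pool = [s for s in taxonomy.siblings_of(code_id)
                      if taxonomy.codes[s].informal_variants]
        feasible = {
            "vague": bool(vague_pool),
            "wrong": bool(wrong_pool),
            "missing": True,
        }
        mix = np.array(config.type_mix, dtype=float)
        err = ERROR_TYPES[int(rng.choice(3, p=mix))]
        if not feasible[err]:
            ok = np.array([feasible[t] for t in ERROR_TYPES], dtype=float) * mix
            if ok.sum() == 0:
                ok = np.array([feasible[t] for t in ERROR_TYPES], dtype=float)
            err = ERROR_TYPES[int(rng.choice(3, p=ok / ok.sum()))]

        if err == "missing":
            deletions.setdefault(ri, []).append(ei)
            audit.append(CorruptionRecord(rec.record_id, ei, "missing", code_id, None))
        else:
            pool = vague_pool if err == "vague" else wrong_pool
            repl = pool[int(rng.integers(len(pool)))]
            variants = taxonomy.codes[repl].informal_variants
            rec.short_text[ei] = variants[int(rng.integers(len(variants)))]
            audit.append(CorruptionRecord(rec.record_id, ei, err, code_id, repl))

    for ri, idxs in deletions.items():
        for ei in sorted(idxs, reverse=True):
            del out[ri].short_text[ei]
    return out, audit


def noise_sweep(records, taxonomy, ratios, seed: int = 0, type_mix=(1 / 3, 1 / 3, 1 / 3)):
    """One corrupted copy of the corpus per requested ratio, sub-seeded independently."""
    out = []
    for i, ratio in enumerate(ratios):
        cfg = NoiseConfig(noise_ratio=ratio, type_mix=tuple(type_mix),
                          seed=(seed * 9973 + 101 * i + 7) % (2 ** 31))
        corrupted, audit = corrupt_dataset(records, taxonomy, cfg)
        out.append({"ratio": ratio, "records": corrupted, "audit": audit, "config": cfg})
    return out
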