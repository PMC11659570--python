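"""Hierarchical code taxonomy and multi-label vectorisation.

The taxonomy is a three-tier hierarchy (chapter -> group -> leaf) in the
style of diagnosis-code systems: only leaf codes are assignable labels;
upper levels exist for vague-noise injection and chapter-level reporting.
Each code carries a canonical standard name plus informally written name
variants, the substrate for noisy auto-annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Code",
    "CodeTaxonomy",
    "TaxonomyError",
    "load_taxonomy",
    "save_taxonomy",
    "ancestors_of",
    "vectorize_labels",
    "unvectorize_labels",
]


class TaxonomyError(ValueError):
    """Structural problem in a code taxonomy (cycle, duplicate, unknown code)."""


@dataclass
class Code:
    code_id: str
    standard_name: str
    parent_id: str | None
    chapter_id: str
    informal_variants: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "code_id": self.code_id,
            "standard_name": self.standard_name,
            "parent_id": self.parent_id,
            "chapter_id": self.chapter_id,
            "informal_variants": list(self.informal_variants),
        }


class CodeTaxonomy:
    """Code collection with parent/sibling/chapter indices and a fixed leaf order.

    The leaf order (lexicographic on code_id) defines the label-vector
    coordinate system used everywhere downstream.
    """

    def __init__(self, codes: list[Code]):
        self.codes: dict[str, Code] = {}
        for c in codes:
            if c.code_id in self.codes:
                raise TaxonomyError(f"duplicate code_id {c.code_id!r}")
            if not c.standard_name:
                raise TaxonomyError(f"code {c.code_id!r} has empty standard_name")
            self.codes[c.code_id] = c
        self._validate_parents()
        children: dict[str | None, list[str]] = {}
        for c in self.codes.values():
            children.setdefault(c.parent_id, []).append(c.code_id)
        self._children = {k: sorted(v) for k, v in children.items()}
        self.leaf_order: list[str] = sorted(
            cid for cid in self.codes if cid not in self._children
        )
        self.leaf_set = set(self.leaf_order)
        self.leaf_index = {cid: i for i, cid in enumerate(self.leaf_order)}

    def _validate_parents(self):
        for cid, c in self.codes.items():
            seen = {cid}
            cur = c.parent_id
            while cur is not None:
                if cur not in self.codes:
                    raise TaxonomyError(f"code {cid!r} references unknown parent {cur!r}")
                if cur in seen:
                    raise TaxonomyError(f"cycle in parent chain at code {cur!r}")
                seen.add(cur)
                cur = self.codes[cur].parent_id

    # -- relations ------------------------------------------------------------
    def ancestors_of(self, code_id: str) -> list[str]:
        """Parent chain from the immediate parent up to the chapter root."""
        if code_id not in self.codes:
            raise TaxonomyError(f"unknown code {code_id!r}")
        chain = []
        cur = self.codes[code_id].parent_id
        while cur is not None:
            chain.append(cur)
            cur = self.codes[cur].parent_id
        return chain

    def siblings_of(self, code_id: str) -> list[str]:
        """Codes sharing the same immediate parent, excluding the code itself."""
        if code_id not in self.codes:
            raise TaxonomyError(f"unknown code {code_id!r}")
        parent = self.codes[code_id].parent_id
        return [c for c in self._children.get(parent, []) if c != code_id]

    def chapter_of(self, code_id: str) -> str:
        if code_id not in self.codes:
            raise TaxonomyError(f"unknown code {code_id!r}")
        return self.codes[code_id].chapter_id

    @property
    def chapters(self) -> list[str]:
        return sorted({c.chapter_id for c in self.codes.values()})

    def is_leaf(self, code_id: str) -> bool:
        return code_id in self.leaf_set

    # -- label vectors --------------------------------------------------------
    def vectorize(self, labels) -> np.ndarray:
        y = np.zeros(len(self.leaf_order), dtype=np.int8)
        for lab in labels:
            if lab not in self.leaf_index:
                raise TaxonomyError(f"label {lab!r} is not an assignable leaf code")
            y[self.leaf_index[lab]] = 1
        return y

    def unvectorize(self, y: np.ndarray) -> set[str]:
        return {self.leaf_order[i] for i in np.flatnonzero(np.asarray(y))}

    # -- serialisation --------------------------------------------------------
    def to_dict(self) -> dict:
        return {"codes": [self.codes[cid].to_dict() for cid in sorted(self.codes)]}

    @classmethod
    def from_dict(cls, d: dict) -> "CodeTaxonomy":
        return cls([Code(**c) for c in d["codes"]])


def load_taxonomy(path) -> CodeTaxonomy:
    with open(path) as fh:
        return CodeTaxonomy.from_dict(json.load(fh))


def save_taxonomy(taxonomy: CodeTaxonomy, path) -> None:
    with open(path, "w") as fh:
        json.dump(taxonomy.to_dict(), fh, indent=1)


def ancestors_of(code_id: str, taxonomy: CodeTaxonomy) -> list[str]:
    return taxonomy.ancestors_of(code_id)


def vectorize_labels(labels, taxonomy: CodeTaxonomy) -> np.ndarray:
    return taxonomy.vectorize(labels)


def unvectorize_labels(y: np.ndarray, taxonomy: CodeTaxonomy) -> set[str]:
    return taxonomy.unvectorize(y)
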