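"""Synthetic taxonomy and EMR corpus generation.

Stands in for private hospital EMRs while reproducing the statistical
structure the coding framework assumes: a three-tier code hierarchy with
informal name variants, long-tailed code frequencies, a small mean number
of codes per admission, keyword-bearing long free text with background
vocabulary, and partially incomplete records lacking the structured
short-text section.

Tokens are opaque synthetic strings; the framework is language-agnostic
and operates on token sequences only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import EMRRecord
from .taxonomy import Code, CodeTaxonomy

__all__ = ["GeneratorConfig", "generate_taxonomy", "generate_corpus", "split_dataset"]

_SYLLABLES = [
    "car", "neo", "bron", "gast", "hep", "ren", "derm", "ost", "myo", "vas",
    "pul", "cer", "lip", "thy", "neph", "art", "fibro", "scler", "emia", "itis",
    "oma", "path", "algia", "stasis", "osis",
]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-EMR world.

    Defaults mirror the descriptive statistics of real 50-code hospital
    corpora: ~4.3 codes and ~730 words per admission, long-tailed code
    frequencies, ~20% of records lacking the structured short text, and
    section completeness around 65%/48% for the specialist-condition and
    auxiliary-examination sections.
    """

    n_codes: int = 50
    n_chapters: int = 6
    n_records: int = 2000
    zipf_exponent: float = 1.1
    codes_per_doc_mean: float = 4.3
    doc_length_mean: int = 730
    keywords_per_code: int = 3
    keyword_emission_prob: float = 0.85
    background_vocab_size: int = 500
    incomplete_fraction: float = 0.2
    chapter_affinity: float = 0.5  # P(next label drawn from an already-used chapter)
    section_dropout: dict = field(
        default_factory=lambda: {"specialist_condition": 0.35, "auxiliary_examination": 0.5}
    )
    seed: int = 0

    def validate(self):
        if self.n_codes < self.n_chapters:
            raise ValueError("n_codes must be >= n_chapters")
        for name, p in [
            ("keyword_emission_prob", self.keyword_emission_prob),
            ("incomplete_fraction", self.incomplete_fraction),
            ("chapter_affinity", self.chapter_affinity),
            *[(f"section_dropout[{k}]", v) for k, v in self.section_dropout.items()],
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if min(self.n_codes, self.n_records, self.keywords_per_code, self.doc_length_mean) <= 0:
            raise ValueError("counts must be positive")


def _make_name(rng: np.random.Generator, n_words: int = 2) -> str:
    words = []
    for _ in range(n_words):
        k = rng.integers(2, 4)
        words.append("".join(rng.choice(_SYLLABLES, size=k)))
    return " ".join(words)


def _variants_of(name: str, rng: np.random.Generator, n: int = 3) -> list[str]:
    """Informal writings: truncation, abbreviation, reordering, vernacular suffix."""
    words = name.split()
    out = []
    makers = [
        lambda: " ".join(w[: max(3, len(w) - rng.integers(1, 3))] for w in words),
        lambda: "".join(w[:3] for w in words),
        lambda: " ".join(words[::-1]),
        lambda: name + " " + rng.choice(["dx", "nos", "chr", "acu"]),
        lambda: words[0] if len(words) > 1 else name[: max(3, len(name) - 2)],
    ]
    for i in rng.permutation(len(makers))[: max(n, 2)]:
        v = makers[i]()
        if v and v != name and v not in out:
            out.append(v)
    while len(out) < 2:
        out.append(name[: max(3, len(name) - len(out) - 1)] + "~")
    return out


def generate_taxonomy(config: GeneratorConfig) -> CodeTaxonomy:
    """Build a chapter -> group -> leaf taxonomy with informal name lexicons.

    Every code (including internal groups and chapters, needed as
    vague-noise replacement targets) receives at least two informal
    variants synthesised by perturbing its standard name.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    codes: list[Code] = []
    # distribute leaves over chapters as evenly as possible
    per_chapter = np.full(config.n_chapters, config.n_codes // config.n_chapters)
    per_chapter[: config.n_codes % config.n_chapters] += 1
    for ci in range(config.n_chapters):
        chap_id = f"C{ci:02d}"
        chap_name = _make_name(rng, 2)
        codes.append(Code(chap_id, chap_name, None, chap_id, _variants_of(chap_name, rng)))
        n_leaves = int(per_chapter[ci])
        n_groups = max(1, int(np.ceil(n_leaves / 4)))
        per_group = np.full(n_groups, n_leaves // n_groups)
        per_group[: n_leaves % n_groups] += 1
        for gi in range(n_groups):
            grp_id = f"{chap_id}.G{gi}"
            grp_name = _make_name(rng, 2)
            codes.append(Code(grp_id, grp_name, chap_id, chap_id, _variants_of(grp_name, rng)))
            for li in range(int(per_group[gi])):
                leaf_id = f"{grp_id}.{li:02d}"
                leaf_name = _make_name(rng, 3)
                codes.append(Code(leaf_id, leaf_name, grp_id, chap_id, _variants_of(leaf_name, rng)))
    return CodeTaxonomy(codes)


def _keywords(taxonomy: CodeTaxonomy, k: int) -> dict[str, list[str]]:
    return {cid: [f"kw:{cid}:{j}" for j in range(k)] for cid in taxonomy.leaf_order}


def keyword_map(taxonomy: CodeTaxonomy, config: GeneratorConfig) -> dict[str, list[str]]:
    """The planted keyword tokens of every leaf code (used by faithfulness checks)."""
    return _keywords(taxonomy, config.keywords_per_code)


def generate_corpus(taxonomy: CodeTaxonomy, config: GeneratorConfig) -> list[EMRRecord]:
    """Sample gold-labelled records.

    Label sets: shifted-Poisson count (minimum 1, mean codes_per_doc_mean)
    over a Zipf-tilted code distribution; labels after the first stay in an
    already-used chapter with probability `chapter_affinity`, inducing the
    chapter-level co-occurrence that makes label-similarity weighting
    non-degenerate. Long text: each label keyword is emitted with
    `keyword_emission_prob` (keywords 1 and 2 of a code live in the
    specialist / auxiliary sections and vanish with the section), then
    background tokens pad to a Poisson document length. Short text lists
    one name per label (standard or informal, 50/50) for complete records.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    leaves = taxonomy.leaf_order
    n_leaf = len(leaves)
    # Zipf popularity over a seed-permuted leaf ranking
    rank_perm = rng.permutation(n_leaf)
    pop = 1.0 / np.power(np.arange(1, n_leaf + 1, dtype=float), config.zipf_exponent)
    probs = np.empty(n_leaf)
    probs[rank_perm] = pop / pop.sum()
    chapter_of = np.array([taxonomy.chapter_of(c) for c in leaves])
    background = [f"bg:{i}" for i in range(config.background_vocab_size)]
    kw = _keywords(taxonomy, config.keywords_per_code)

    n_incomplete = int(np.floor(config.incomplete_fraction * config.n_records))
    incomplete_ids = set(rng.choice(config.n_records, size=n_incomplete, replace=False).tolist())

    records = []
    for i in range(config.n_records):
        k = min(1 + rng.poisson(max(config.codes_per_doc_mean - 1.0, 0.0)), n_leaf)
        chosen: list[int] = []
        for _ in range(k):
            p = probs.copy()
            p[chosen] = 0.0
            if chosen and rng.random() < config.chapter_affinity:
                used = {chapter_of[j] for j in chosen}
                mask = np.isin(chapter_of, list(used))
                if p[mask].sum() > 0:
                    p[~mask] = 0.0
            p /= p.sum()
            chosen.append(int(rng.choice(n_leaf, p=p)))
        labels = [leaves[j] for j in chosen]

        flags = {
            sec: bool(rng.random() >= drop) for sec, drop in config.section_dropout.items()
        }
        tokens: list[str] = []
        sections = ["specialist_condition", "auxiliary_examination"]
        for lab in labels:
            for j, token in enumerate(kw[lab]):
                if 1 <= j <= 2 and not flags.get(sections[j - 1], True):
                    continue
                if rng.random() < config.keyword_emission_prob:
                    tokens.append(token)
        if background:
            target = max(rng.poisson(config.doc_length_mean), len(tokens), 1)
            n_bg = target - len(tokens)
            tokens.extend(rng.choice(background, size=n_bg).tolist())
        if not tokens:
            tokens = [kw[labels[0]][0]]  # guarantee non-empty long text
        order = rng.permutation(len(tokens))
        tokens = [tokens[j] for j in order]

        if i in incomplete_ids:
            short = []
        else:
            short = []
            for lab in labels:
                code = taxonomy.codes[lab]
                if rng.random() < 0.5 or not code.informal_variants:
                    short.append(code.standard_name)
                else:
                    short.append(str(rng.choice(code.informal_variants)))
        records.append(
            EMRRecord(
                record_id=f"R{i:06d}",
                short_text=short,
                long_text=tokens,
                gold_labels=set(labels),
                section_flags=flags,
            )
        )
    return records


def split_dataset(records, ratios=(0.6, 0.2, 0.2), seed: int = 0):
    """Deterministic shuffle-split into train/validation/test pools."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n = len(records)
    sizes = [int(np.floor(r * n)) for r in ratios]
    rem = n - sum(sizes)
    fracs = sorted(range(len(ratios)), key=lambda i: -(ratios[i] * n - np.floor(ratios[i] * n)))
    for i in range(rem):
        sizes[fracs[i % len(sizes)]] += 1
    out, start = [], 0
    for s in sizes:
        out.append([records[j] for j in order[start: start + s]])
        start += s
    return tuple(out)
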