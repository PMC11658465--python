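"""Synthetic BioRED-schema corpora for desk-scale experiments.

Documents are templated English-like filler over the six biomedical entity
types (Gene, Disease, Chemical, Variant, Species, CellLine) and the eight
undirected relation labels, with:

* multi-mention entities (alias surfaces sharing one normalized id), so
  coreference is non-trivial;
* a type-pair → allowed-relations constraint schema that generated
  relations always respect;
* relation-revealing cue phrases emitted with probability ``cue_strength``
  (cue phrases are single underscore-joined tokens so small word-level
  tokenizers keep them atomic);
* novelty cue phrases ("we_newly_report_that" vs
  "as_previously_established"), emitted independently of the relation cue.

With ``cue_strength = 1`` the relation and novelty labels are deterministic
functions of the surface text (a separable problem); lower values inject
label noise.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import AnnotatedDocument, EntityMention, NOVEL, NOT_NOVEL, RelationTriple

__all__ = [
    "SynthConfig",
    "BIORED_ENTITY_TYPES",
    "BIORED_RELATION_TYPES",
    "RELATION_CUES",
    "NOVELTY_CUES",
    "default_schema",
    "generate_corpus",
    "learnability_fixture",
]

BIORED_ENTITY_TYPES = ["Gene", "Disease", "Chemical", "Variant", "Species", "CellLine"]

BIORED_RELATION_TYPES = [
    "Association",
    "Positive_Correlation",
    "Negative_Correlation",
    "Bind",
    "Cotreatment",
    "Comparison",
    "Drug_Interaction",
    "Conversion",
]

RELATION_CUES = {
    "Association": "is_associated_with",
    "Positive_Correlation": "positively_correlates_with",
    "Negative_Correlation": "negatively_correlates_with",
    "Bind": "binds_directly_to",
    "Cotreatment": "is_co_administered_with",
    "Comparison": "is_compared_against",
    "Drug_Interaction": "interacts_adversely_with",
    "Conversion": "is_converted_into",
}

NOVELTY_CUES = {NOVEL: "we_newly_report_that", NOT_NOVEL: "as_previously_established"}

_TYPE_PREFIX = {
    "Gene": "g",
    "Disease": "d",
    "Chemical": "c",
    "Variant": "v",
    "Species": "s",
    "CellLine": "l",
}


def default_schema() -> dict[tuple[str, str], frozenset[str]]:
    """Type-pair → allowed-relation schema over the six entity types and
    eight relation labels; symmetric in the type pair by construction."""
    raw = {
        ("Chemical", "Disease"): {"Association", "Positive_Correlation", "Negative_Correlation"},
        ("Chemical", "Gene"): {"Association", "Bind", "Positive_Correlation", "Negative_Correlation"},
        ("Chemical", "Chemical"): {"Cotreatment", "Comparison", "Drug_Interaction", "Conversion"},
        ("Disease", "Gene"): {"Association", "Positive_Correlation", "Negative_Correlation"},
        ("Gene", "Gene"): {"Association", "Bind", "Positive_Correlation", "Negative_Correlation"},
        ("Disease", "Variant"): {"Association", "Positive_Correlation"},
        ("Chemical", "Variant"): {"Association", "Negative_Correlation"},
        ("Gene", "Variant"): {"Association"},
    }
    return {tuple(sorted(k)): frozenset(v) for k, v in raw.items()}


@dataclass
class SynthConfig:
    """Controls for the generator; defaults give a corpus with coreference,
    constraint filtering, and fully informative relation/novelty cues."""

    n_docs: int = 20
    entity_types: list[str] = field(default_factory=lambda: list(BIORED_ENTITY_TYPES))
    entities_per_doc: tuple[int, int] = (2, 4)
    mentions_per_entity: tuple[int, int] = (1, 3)
    schema: dict[tuple[str, str], frozenset[str]] = field(default_factory=default_schema)
    relation_density: float = 0.6
    novelty_probability: float = 0.5
    cue_strength: float = 1.0
    distractor_probability: float = 0.3
    name_pool_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.entities_per_doc
        if not (1 <= lo <= hi):
            raise ValueError("entities_per_doc range must satisfy 1 <= lo <= hi")
        lo, hi = self.mentions_per_entity
        if not (1 <= lo <= hi):
            raise ValueError("mentions_per_entity range must satisfy 1 <= lo <= hi")
        for p in (self.relation_density, self.novelty_probability, self.cue_strength):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.relation_density > 0 and not self.schema:
            raise ValueError("relation_density > 0 requires a non-empty schema")


class _DocBuilder:
    """Accumulates space-joined tokens while recording mention offsets."""

    def __init__(self) -> None:
        self.tokens: list[str] = []
        self.mentions: list[tuple[int, int, str, str, str]] = []  # start,end,surface,type,id
        self._len = 0

    def add(self, token: str) -> tuple[int, int]:
        start = self._len + 1 if self.tokens else 0
        self.tokens.append(token)
        self._len = start + len(token)
        return start, start + len(token)

    def add_mention(self, surface: str, etype: str, eid: str) -> None:
        start, end = self.add(surface)
        self.mentions.append((start, end, surface, etype, eid))

    def text(self) -> str:
        return " ".join(self.tokens)


@dataclass
class _Entity:
    eid: str
    etype: str
    aliases: list[str]


def _sample_entities(cfg: SynthConfig, rng: np.random.Generator) -> list[_Entity]:
    """Entities for one document, drawn from a fixed per-type name pool.

    Names (hence normalized ids) recur across documents, mirroring real
    corpora where the same database identifier appears in many articles.
    """
    n = int(rng.integers(cfg.entities_per_doc[0], cfg.entities_per_doc[1] + 1))
    entities: list[_Entity] = []
    used: set[str] = set()
    for _ in range(n):
        etype = cfg.entity_types[int(rng.integers(len(cfg.entity_types)))]
        prefix = _TYPE_PREFIX.get(etype, "x")
        for _attempt in range(100):
            stem = f"{prefix}{int(rng.integers(cfg.name_pool_size)):03d}"
            if stem not in used:
                break
        used.add(stem)
        n_alias = int(rng.integers(cfg.mentions_per_entity[0], cfg.mentions_per_entity[1] + 1))
        aliases = [stem] + [f"{stem}v{j}" for j in range(1, n_alias)]
        entities.append(_Entity(eid=stem.upper(), etype=etype, aliases=aliases))
    return entities


def generate_corpus(cfg: SynthConfig) -> list[AnnotatedDocument]:
    """Generate ``cfg.n_docs`` annotated documents; deterministic in the seed."""
    rng = np.random.default_rng(cfg.seed)
    docs: list[AnnotatedDocument] = []
    for d in range(cfg.n_docs):
        doc_id = f"SYN{cfg.seed}D{d:04d}"
        entities = _sample_entities(cfg, rng)

        relations: list[RelationTriple] = []
        for i in range(len(entities)):
            for j in range(i + 1, len(entities)):
                a, b = entities[i], entities[j]
                allowed = cfg.schema.get(tuple(sorted((a.etype, b.etype))), frozenset())
                if not allowed or rng.random() >= cfg.relation_density:
                    continue
                rel = sorted(allowed)[int(rng.integers(len(allowed)))]
                nov = NOVEL if rng.random() < cfg.novelty_probability else NOT_NOVEL
                relations.append(RelationTriple(a.eid, b.eid, rel, nov))

        builder = _DocBuilder()
        # title: mentions the first entity
        for tok in ["A", "study", "of"]:
            builder.add(tok)
        builder.add_mention(entities[0].aliases[0], entities[0].etype, entities[0].eid)
        builder.add(".")
        title_len = len(builder.text())

        # one introduction sentence per alias of each entity
        for ent in entities:
            for alias in ent.aliases:
                builder.add_mention(alias, ent.etype, ent.eid)
                for tok in ["is", "a", ent.etype.lower(), "examined", "here", "."]:
                    builder.add(tok)

        by_id = {e.eid: e for e in entities}
        for rel in relations:
            a, b = by_id[rel.entity_id_a], by_id[rel.entity_id_b]
            if rng.random() < cfg.cue_strength:
                builder.add_mention(_pick(a.aliases, rng), a.etype, a.eid)
                builder.add(RELATION_CUES[rel.relation_type])
                builder.add_mention(_pick(b.aliases, rng), b.etype, b.eid)
                builder.add(".")
            if rng.random() < cfg.cue_strength:
                builder.add(NOVELTY_CUES[rel.novelty])
                builder.add_mention(_pick(a.aliases, rng), a.etype, a.eid)
                builder.add("and")
                builder.add_mention(_pick(b.aliases, rng), b.etype, b.eid)
                builder.add("interact")
                builder.add(".")

        # unrelated-pair distractor sentences: co-occurrence without a cue
        related = {r.pair for r in relations}
        for i in range(len(entities)):
            for j in range(i + 1, len(entities)):
                a, b = entities[i], entities[j]
                if tuple(sorted((a.eid, b.eid))) in related:
                    continue
                if rng.random() < cfg.distractor_probability:
                    builder.add_mention(_pick(a.aliases, rng), a.etype, a.eid)
                    for tok in ["was", "measured", "alongside"]:
                        builder.add(tok)
                    builder.add_mention(_pick(b.aliases, rng), b.etype, b.eid)
                    builder.add(".")

        text = builder.text()
        title, abstract = text[:title_len], text[title_len + 1 :]
        mentions = [
            EntityMention(f"{doc_id}:{k+1}", s, e, surf, etype, eid)
            for k, (s, e, surf, etype, eid) in enumerate(builder.mentions)
        ]
        doc = AnnotatedDocument(doc_id, title, abstract, mentions, relations)
        doc.validate()
        docs.append(doc)
    return docs


def _pick(items: Sequence[str], rng: np.random.Generator) -> str:
    return items[int(rng.integers(len(items)))]


def learnability_fixture(
    difficulty: str = "separable", seed: int = 2024
) -> tuple[list[AnnotatedDocument], list[AnnotatedDocument]]:
    """(train, dev) corpora for end-to-end learnability checks.

    ``separable`` emits relation and novelty cues always (labels are
    deterministic functions of the surface text); ``noisy`` drops cues with
    probability 0.3.
    """
    if difficulty not in ("separable", "noisy"):
        raise ValueError("difficulty must be 'separable' or 'noisy'")
    cue = 1.0 if difficulty == "separable" else 0.7
    # Desk-scale study conditions: single focal pair per document over the
    # four relation-bearing entity types, so the tiny encoder can reach the
    # cue-reading ceiling within minutes on one CPU core.
    base = dict(
        entity_types=["Gene", "Disease", "Chemical", "Variant"],
        entities_per_doc=(2, 2),
        mentions_per_entity=(1, 2),
        relation_density=0.7,
        novelty_probability=0.5,
        cue_strength=cue,
    )
    train = generate_corpus(SynthConfig(n_docs=600, seed=seed, **base))
    dev = generate_corpus(SynthConfig(n_docs=60, seed=seed + 1, **base))
    return train, dev
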