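"""Per-entity-pair sample construction.

Every unordered entity pair of a document becomes one training/inference
sample: all mentions of the two focal entities are wrapped in atomic entity
markers, the marked text is tokenized with a classifier token in front and a
separator at the end, and the sample carries labels for the four tasks —

* CR (coreference): for each unordered pair of focal mentions, whether they
  normalize to the same entity id;
* EPT (entity-pair typing): the unordered pair of entity types;
* RE (relation extraction): the gold relation type, or ``None``;
* TNT (triplet novelty typing): the gold novelty flag, or ``None``.

Pairs whose entity-type pair never carries a relation in the training data
are filtered out via the schema's constraint map.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import AnnotatedDocument, EntityMention, NOVEL, NOT_NOVEL

__all__ = [
    "NONE_LABEL",
    "OPEN_MARKER",
    "CLOSE_MARKER",
    "LabelSchema",
    "EncoderConfig",
    "PairSample",
    "build_constraint_map",
    "enumerate_pairs",
    "insert_markers",
    "tokenize_sample",
    "make_labels",
    "build_samples",
    "build_vocab",
    "word_tokenize",
]

NONE_LABEL = "None"
OPEN_MARKER = "@\\E"
CLOSE_MARKER = "E/@"

PAD, CLS, SEP, UNK = "[PAD]", "[CLS]", "[SEP]", "[UNK]"

_PUNCT_RE = re.compile(r"[\.,;:!?()\[\]]")


def _type_pair(t1: str, t2: str) -> tuple[str, str]:
    return (t1, t2) if t1 <= t2 else (t2, t1)


@dataclass
class LabelSchema:
    """Label spaces for the four tasks plus the type-pair constraint map.

    ``constraint_map`` maps an unordered entity-type pair to the set of
    relation types ever observed for it; lookups are symmetric.
    """

    entity_types: list[str]
    relation_types: list[str]
    constraint_map: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, rels in self.constraint_map.items():
            bad = set(rels) - set(self.relation_types)
            if bad:
                raise ValueError(f"constraint for {pair} uses unknown relations {bad}")

    # class inventories ------------------------------------------------------

    @property
    def re_classes(self) -> list[str]:
        return list(self.relation_types) + [NONE_LABEL]

    @property
    def tnt_classes(self) -> list[str]:
        return [NOVEL, NOT_NOVEL, NONE_LABEL]

    @property
    def ept_classes(self) -> list[tuple[str, str]]:
        ts = self.entity_types
        return [_type_pair(ts[i], ts[j]) for i in range(len(ts)) for j in range(i, len(ts))]

    def re_index(self, label: str) -> int:
        return self.re_classes.index(label)

    def tnt_index(self, label: str) -> int:
        return self.tnt_classes.index(label)

    def ept_index(self, type_pair: tuple[str, str]) -> int:
        return self.ept_classes.index(_type_pair(*type_pair))

    def allowed_relations(self, t1: str, t2: str) -> frozenset[str]:
        return self.constraint_map.get(_type_pair(t1, t2), frozenset())

    def to_dict(self) -> dict:
        return {
            "entity_types": self.entity_types,
            "relation_types": self.relation_types,
            "constraint_map": {
                "|".join(k): sorted(v) for k, v in self.constraint_map.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LabelSchema":
        cmap = {
            tuple(k.split("|")): frozenset(v)
            for k, v in d.get("constraint_map", {}).items()
        }
        return cls(list(d["entity_types"]), list(d["relation_types"]), cmap)


@dataclass
class EncoderConfig:
    """Tokenizer + encoder geometry shared by every model in a run.

    ``vocab`` maps token string -> id and must register the classifier,
    separator, padding, unknown, and the two entity-marker strings as atomic
    special tokens (they are never split by the tokenizer).
    """

    vocab: dict[str, int]
    max_length: int = 512
    hidden_size: int = 64
    n_layers: int = 2
    n_heads: int = 2
    ffn_size: int = 256
    open_marker: str = OPEN_MARKER
    close_marker: str = CLOSE_MARKER
    lowercase: bool = True

    @property
    def special_tokens(self) -> list[str]:
        return [PAD, CLS, SEP, UNK, self.open_marker, self.close_marker]

    @property
    def pad_id(self) -> int:
        return self.vocab[PAD]

    @property
    def cls_id(self) -> int:
        return self.vocab[CLS]

    @property
    def sep_id(self) -> int:
        return self.vocab[SEP]

    @property
    def open_marker_id(self) -> int:
        return self.vocab[self.open_marker]

    def token_id(self, token: str) -> int:
        if token in self.vocab:
            return self.vocab[token]
        key = token.lower() if self.lowercase else token
        return self.vocab.get(key, self.vocab[UNK])


@dataclass
class PairSample:
    """One (document, focal entity pair) unit ready for the model."""

    doc_id: str
    focal_pair: tuple[str, str]
    token_ids: list[int]
    open_marker_positions: dict[str, int]
    mention_entity: dict[str, str]
    cr_pairs: list[tuple[str, str, int]]
    ept_label: tuple[str, str]
    re_label: str
    tnt_label: str
    degenerate: bool = False


def word_tokenize(text: str, specials: Sequence[str] = ()) -> list[str]:
    """Whitespace tokenization with punctuation split off; tokens equal to a
    registered special string are kept atomic."""
    special_set = set(specials)
    out: list[str] = []
    for chunk in text.split():
        if chunk in special_set:
            out.append(chunk)
            continue
        pos = 0
        for m in _PUNCT_RE.finditer(chunk):
            if m.start() > pos:
                out.append(chunk[pos : m.start()])
            out.append(m.group())
            pos = m.end()
        if pos < len(chunk):
            out.append(chunk[pos:])
    return out


def build_vocab(
    docs: Iterable[AnnotatedDocument],
    open_marker: str = OPEN_MARKER,
    close_marker: str = CLOSE_MARKER,
    lowercase: bool = True,
) -> dict[str, int]:
    """Word-level vocabulary over a training corpus plus the special tokens."""
    specials = [PAD, CLS, SEP, UNK, open_marker, close_marker]
    vocab = {tok: i for i, tok in enumerate(specials)}
    for doc in docs:
        for tok in word_tokenize(doc.text, specials):
            key = tok.lower() if lowercase else tok
            if key not in vocab:
                vocab[key] = len(vocab)
    return vocab


def build_constraint_map(
    train_docs: Iterable[AnnotatedDocument],
) -> dict[tuple[str, str], frozenset[str]]:
    """Observed relation types per unordered entity-type pair, from gold
    training relations only."""
    cmap: dict[tuple[str, str], set[str]] = {}
    for doc in train_docs:
        types = {m.entity_id: m.entity_type for m in doc.mentions}
        for rel in doc.relations:
            for eid in (rel.entity_id_a, rel.entity_id_b):
                if eid not in types:
                    raise ValueError(
                        f"doc {doc.doc_id}: relation endpoint {eid!r} has no "
                        "resolvable entity type"
                    )
            key = _type_pair(types[rel.entity_id_a], types[rel.entity_id_b])
            cmap.setdefault(key, set()).add(rel.relation_type)
    return {k: frozenset(v) for k, v in cmap.items()}


def enumerate_pairs(
    doc: AnnotatedDocument,
    constraint_map: dict[tuple[str, str], frozenset[str]] | None = None,
    keep_unconstrained: bool = False,
) -> list[tuple[str, str]]:
    """All unordered entity-id pairs of a document, optionally dropping pairs
    whose type pair never carries a relation."""
    eids = doc.entity_ids
    types = {m.entity_id: m.entity_type for m in doc.mentions}
    pairs: list[tuple[str, str]] = []
    for i in range(len(eids)):
        for j in range(i + 1, len(eids)):
            a, b = eids[i], eids[j]
            if not keep_unconstrained and constraint_map is not None:
                if _type_pair(types[a], types[b]) not in constraint_map:
                    continue
            pairs.append((a, b) if a <= b else (b, a))
    return pairs


def insert_markers(
    doc: AnnotatedDocument,
    focal_pair: tuple[str, str],
    open_marker: str = OPEN_MARKER,
    close_marker: str = CLOSE_MARKER,
) -> tuple[str, list[str]]:
    """Wrap every mention of the two focal entities in entity markers.

    Returns the marked text and the focal mention ids in document order —
    the i-th opening-marker occurrence in the marked text belongs to the
    i-th id in the list.
    """
    focal = [m for m in doc.mentions if m.entity_id in focal_pair]
    focal.sort(key=lambda m: (m.start, m.end))
    for prev, cur in zip(focal, focal[1:]):
        if cur.start < prev.end:
            raise ValueError(
                f"doc {doc.doc_id}: overlapping focal mentions "
                f"{prev.mention_id!r} and {cur.mention_id!r}"
            )
    text = doc.text
    pieces: list[str] = []
    cursor = 0
    order: list[str] = []
    for m in focal:
        pieces.append(text[cursor : m.start])
        pieces.append(f"{open_marker} {text[m.start:m.end]} {close_marker}")
        cursor = m.end
        order.append(m.mention_id)
    pieces.append(text[cursor:])
    return "".join(pieces), order


def tokenize_sample(
    marked_text: str,
    open_mention_order: Sequence[str],
    config: EncoderConfig,
) -> tuple[list[int], dict[str, int]]:
    """Tokenize marked text to ids with [CLS]/[SEP] framing and truncation.

    The sequence is truncated to ``config.max_length`` keeping the prefix,
    with the separator always last.  Marker positions are reported in token
    coordinates of the final sequence; a focal mention survives only if both
    its opening and closing markers fit inside the truncated window.
    """
    tokens = word_tokenize(marked_text, config.special_tokens)
    body_budget = config.max_length - 2
    kept = tokens[:body_budget]
    ids = [config.cls_id] + [config.token_id(t) for t in kept] + [config.sep_id]

    positions: dict[str, int] = {}
    open_seen = 0
    pending: tuple[str, int] | None = None
    for idx, tok in enumerate(kept):
        if tok == config.open_marker:
            if open_seen < len(open_mention_order):
                pending = (open_mention_order[open_seen], idx + 1)  # +1 for [CLS]
            open_seen += 1
        elif tok == config.close_marker and pending is not None:
            positions[pending[0]] = pending[1]
            pending = None
    return ids, positions


def make_labels(
    doc: AnnotatedDocument,
    focal_pair: tuple[str, str],
    schema: LabelSchema,
    marked_mentions: Sequence[EntityMention] | None = None,
) -> tuple[list[tuple[str, str, int]], tuple[str, str], str, str]:
    """CR pair labels, entity-type pair, relation label and novelty label for
    one focal pair.  ``re_label`` is ``None`` iff ``tnt_label`` is ``None``."""
    if marked_mentions is None:
        marked_mentions = [m for m in doc.mentions if m.entity_id in focal_pair]
    ms = sorted(marked_mentions, key=lambda m: (m.start, m.end))
    cr_pairs = [
        (
            ms[i].mention_id,
            ms[j].mention_id,
            1 if ms[i].entity_id == ms[j].entity_id else 0,
        )
        for i in range(len(ms))
        for j in range(i + 1, len(ms))
    ]
    ept_label = _type_pair(
        doc.entity_type_of(focal_pair[0]), doc.entity_type_of(focal_pair[1])
    )
    key = tuple(sorted(focal_pair))
    re_label, tnt_label = NONE_LABEL, NONE_LABEL
    for rel in doc.relations:
        if rel.pair == key:
            re_label, tnt_label = rel.relation_type, rel.novelty
            break
    return cr_pairs, ept_label, re_label, tnt_label


def build_samples(
    doc: AnnotatedDocument,
    schema: LabelSchema,
    config: EncoderConfig,
    keep_unconstrained: bool = False,
) -> list[PairSample]:
    """Construct every pair sample of a document."""
    samples: list[PairSample] = []
    mention_by_id = {m.mention_id: m for m in doc.mentions}
    for pair in enumerate_pairs(doc, schema.constraint_map, keep_unconstrained):
        marked, order = insert_markers(doc, pair, config.open_marker, config.close_marker)
        token_ids, positions = tokenize_sample(marked, order, config)
        surviving = [mention_by_id[mid] for mid in positions]
        cr_pairs, ept, re_label, tnt_label = make_labels(doc, pair, schema, surviving)
        entity_of = {m.mention_id: m.entity_id for m in surviving}
        covered = {entity_of[mid] for mid in positions}
        samples.append(
            PairSample(
                doc_id=doc.doc_id,
                focal_pair=pair,
                token_ids=token_ids,
                open_marker_positions=positions,
                mention_entity=entity_of,
                cr_pairs=cr_pairs,
                ept_label=ept,
                re_label=re_label,
                tnt_label=tnt_label,
                degenerate=covered != set(pair),
            )
        )
    return samples
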