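"""BioRED-style corpus handling in the PubTator line format.

A corpus is a sequence of blank-line-separated blocks::

    PMID|t|<title>
    PMID|a|<abstract>
    PMID<TAB>start<TAB>end<TAB>surface<TAB>entity_type<TAB>entity_id
    PMID<TAB>relation_type<TAB>entity_id1<TAB>entity_id2<TAB>novelty

Mention offsets are 0-based half-open character positions over the
concatenation ``title + " " + abstract`` (the single-space separator is the
PubTator convention).  Relations are undirected: a triple equals its
endpoint-swapped twin, and each unordered entity pair carries at most one
relation.  Novelty distinguishes relations newly asserted by the document
(``Novel``) from background knowledge (``No``).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

__all__ = [
    "EntityMention",
    "RelationTriple",
    "AnnotatedDocument",
    "CorpusStatistics",
    "PubTatorParseError",
    "read_pubtator",
    "write_pubtator",
    "reorganize_splits",
    "corpus_statistics",
]

NOVEL = "Novel"
NOT_NOVEL = "No"

_NOVELTY_ALIASES = {"novel": NOVEL, "no": NOT_NOVEL, "none": NOT_NOVEL}


class PubTatorParseError(ValueError):
    """Raised when a PubTator stream violates the dialect or its invariants."""


@dataclass(frozen=True)
class EntityMention:
    """One surface occurrence of a normalized entity.

    ``start``/``end`` index into the document's concatenated
    ``title + " " + abstract`` text; slicing that text with ``[start:end)``
    must reproduce ``surface`` exactly.
    """

    mention_id: str
    start: int
    end: int
    surface: str
    entity_type: str
    entity_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"mention {self.mention_id!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )


@dataclass(frozen=True, eq=False)
class RelationTriple:
    """An undirected relation between two normalized entities, with novelty."""

    entity_id_a: str
    entity_id_b: str
    relation_type: str
    novelty: str

    def __post_init__(self) -> None:
        if self.entity_id_a == self.entity_id_b:
            raise ValueError(f"self-relation on entity {self.entity_id_a!r}")

    @property
    def pair(self) -> tuple[str, str]:
        """Canonical (sorted) unordered endpoint pair."""
        a, b = self.entity_id_a, self.entity_id_b
        return (a, b) if a <= b else (b, a)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RelationTriple):
            return NotImplemented
        return (
            self.pair == other.pair
            and self.relation_type == other.relation_type
            and self.novelty == other.novelty
        )

    def __hash__(self) -> int:
        return hash((self.pair, self.relation_type, self.novelty))


@dataclass
class AnnotatedDocument:
    """A title+abstract with mention, entity and relation annotations."""

    doc_id: str
    title: str
    abstract: str
    mentions: list[EntityMention] = field(default_factory=list)
    relations: list[RelationTriple] = field(default_factory=list)

    @property
    def text(self) -> str:
        return self.title + " " + self.abstract

    @property
    def entity_ids(self) -> list[str]:
        """Distinct normalized entity ids, in first-mention order."""
        seen: dict[str, None] = {}
        for m in self.mentions:
            seen.setdefault(m.entity_id, None)
        return list(seen)

    def entity_type_of(self, entity_id: str) -> str:
        for m in self.mentions:
            if m.entity_id == entity_id:
                return m.entity_type
        raise KeyError(f"entity {entity_id!r} has no mention in {self.doc_id}")

    def mentions_of(self, entity_id: str) -> list[EntityMention]:
        return [m for m in self.mentions if m.entity_id == entity_id]

    def validate(self) -> None:
        """Check offset consistency and relation well-formedness."""
        text = self.text
        for m in self.mentions:
            if m.end > len(text):
                raise PubTatorParseError(
                    f"doc {self.doc_id}: mention {m.mention_id!r} span "
                    f"[{m.start},{m.end}) exceeds text length {len(text)}"
                )
            if text[m.start : m.end] != m.surface:
                raise PubTatorParseError(
                    f"doc {self.doc_id}: mention {m.mention_id!r} surface "
                    f"{m.surface!r} != text slice {text[m.start:m.end]!r}"
                )
        known = set(self.entity_ids)
        seen_pairs: set[tuple[str, str]] = set()
        for r in self.relations:
            for eid in (r.entity_id_a, r.entity_id_b):
                if eid not in known:
                    raise PubTatorParseError(
                        f"doc {self.doc_id}: relation references entity "
                        f"{eid!r} with no mention"
                    )
            if r.pair in seen_pairs:
                raise PubTatorParseError(
                    f"doc {self.doc_id}: duplicate relation for pair {r.pair}"
                )
            seen_pairs.add(r.pair)


@dataclass(frozen=True)
class CorpusStatistics:
    n_docs: int
    n_mentions: int
    n_entities: int
    n_relations: int
    n_novel_pairs: int

    def __add__(self, other: "CorpusStatistics") -> "CorpusStatistics":
        return CorpusStatistics(
            self.n_docs + other.n_docs,
            self.n_mentions + other.n_mentions,
            self.n_entities + other.n_entities,
            self.n_relations + other.n_relations,
            self.n_novel_pairs + other.n_novel_pairs,
        )


def _normalize_novelty(raw: str, doc_id: str, lineno: int) -> str:
    key = raw.strip().lower()
    if key not in _NOVELTY_ALIASES:
        raise PubTatorParseError(
            f"doc {doc_id}, line {lineno}: unknown novelty value {raw!r}"
        )
    if key == "none":
        warnings.warn(
            f"doc {doc_id}, line {lineno}: novelty 'None' read as '{NOT_NOVEL}'",
            stacklevel=3,
        )
    return _NOVELTY_ALIASES[key]


def read_pubtator(source: TextIO | str) -> list[AnnotatedDocument]:
    """Parse a PubTator stream (or string) into annotated documents.

    Composite normalizations (comma-separated entity ids on one mention
    line) are expanded into one mention record per id.
    """
    if isinstance(source, str):
        source = io.StringIO(source)

    docs: list[AnnotatedDocument] = []
    block: list[tuple[int, str]] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if line.strip() == "":
            if block:
                docs.append(_parse_block(block))
                block = []
        else:
            block.append((lineno, line))
    if block:
        docs.append(_parse_block(block))
    return docs


def _parse_block(block: list[tuple[int, str]]) -> AnnotatedDocument:
    title: str | None = None
    abstract: str | None = None
    doc_id: str | None = None
    mentions: list[EntityMention] = []
    relations: list[RelationTriple] = []
    n_mentions = 0

    for lineno, line in block:
        if "|t|" in line and title is None and "\t" not in line.split("|t|")[0]:
            doc_id, title = line.split("|t|", 1)
            continue
        if "|a|" in line and abstract is None and "\t" not in line.split("|a|")[0]:
            pid, abstract = line.split("|a|", 1)
            if doc_id is not None and pid != doc_id:
                raise PubTatorParseError(
                    f"line {lineno}: abstract PMID {pid!r} != title PMID {doc_id!r}"
                )
            continue
        fields = line.split("\t")
        if len(fields) == 6 and fields[1].isdigit() and fields[2].isdigit():
            pid, start, end, surface, etype, eids = fields
            for eid in eids.split(","):
                n_mentions += 1
                mentions.append(
                    EntityMention(
                        mention_id=f"{pid}:{n_mentions}",
                        start=int(start),
                        end=int(end),
                        surface=surface,
                        entity_type=etype,
                        entity_id=eid.strip(),
                    )
                )
        elif len(fields) == 5:
            pid, rtype, id_a, id_b, novelty = fields
            relations.append(
                RelationTriple(
                    entity_id_a=id_a,
                    entity_id_b=id_b,
                    relation_type=rtype,
                    novelty=_normalize_novelty(novelty, pid, lineno),
                )
            )
        else:
            raise PubTatorParseError(
                f"line {lineno}: unrecognized PubTator line {line!r}"
            )

    if doc_id is None or title is None:
        raise PubTatorParseError("block without a 'PMID|t|' title line")
    doc = AnnotatedDocument(
        doc_id=doc_id,
        title=title,
        abstract=abstract if abstract is not None else "",
        mentions=mentions,
        relations=relations,
    )
    doc.validate()
    return doc


def write_pubtator(docs: Iterable[AnnotatedDocument]) -> str:
    """Serialize documents back to the PubTator dialect read by read_pubtator."""
    blocks: list[str] = []
    for doc in docs:
        lines = [f"{doc.doc_id}|t|{doc.title}", f"{doc.doc_id}|a|{doc.abstract}"]
        for m in doc.mentions:
            lines.append(
                "\t".join(
                    [
                        doc.doc_id,
                        str(m.start),
                        str(m.end),
                        m.surface,
                        m.entity_type,
                        m.entity_id,
                    ]
                )
            )
        for r in doc.relations:
            lines.append(
                "\t".join(
                    [doc.doc_id, r.relation_type, r.entity_id_a, r.entity_id_b, r.novelty]
                )
            )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def reorganize_splits(
    official_train: Sequence[AnnotatedDocument],
    official_dev: Sequence[AnnotatedDocument],
    official_test: Sequence[AnnotatedDocument],
    track_test: Sequence[AnnotatedDocument] = (),
) -> tuple[list[AnnotatedDocument], list[AnnotatedDocument], list[AnnotatedDocument]]:
    """Rebuild the experimental splits from the official corpus releases.

    The official training and validation sets are concatenated into the new
    training set; the official test set becomes the validation set; the
    separately-released track set (when available) is the test set.
    """
    all_ids: set[str] = set()
    for split in (official_train, official_dev, official_test, track_test):
        for doc in split:
            if doc.doc_id in all_ids:
                raise ValueError(f"doc_id {doc.doc_id!r} appears in multiple splits")
            all_ids.add(doc.doc_id)
    train = list(official_train) + list(official_dev)
    dev = list(official_test)
    test = list(track_test)
    return train, dev, test


def corpus_statistics(docs: Iterable[AnnotatedDocument]) -> CorpusStatistics:
    """Count documents, mentions, per-document distinct entities, relations
    and Novel relation pairs."""
    n_docs = n_mentions = n_entities = n_relations = n_novel = 0
    for doc in docs:
        n_docs += 1
        n_mentions += len(doc.mentions)
        n_entities += len(doc.entity_ids)
        n_relations += len(doc.relations)
        n_novel += sum(1 for r in doc.relations if r.novelty == NOVEL)
    return CorpusStatistics(n_docs, n_mentions, n_entities, n_relations, n_novel)
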