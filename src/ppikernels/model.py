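"""In-memory data model for PPI corpora.

A corpus is a tree of documents, sentences, entities and interaction-labeled
entity pairs, mirroring the PPI learning format: sentences carry their raw
text, a tokenization with POS tags and lemmas, a dependency analysis and a
Penn-style bracketed constituent parse.  The unit of classification is the
:class:`CandidateInstance` -- one unordered entity pair within one sentence,
with every token assigned an entity-blinding role.

Character offsets use the 0-based half-open convention internally; the
learning-format ``charOffset`` strings (``"a-b"`` inclusive) are converted on
read and write by :mod:`ppikernels.io`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional

# Entity-blinding role labels.  Tokens of the candidate pair become ENT1/ENT2
# (or ENT_BOTH when one token carries both entities, e.g. "Arp2/3"); tokens of
# other annotated entities become ENT_OTHER; all remaining tokens keep their
# surface form (role None).
ENT1 = "_ENT_1_"
ENT2 = "_ENT_2_"
ENT_BOTH = "_ENT_1_AND_2_"
ENT_OTHER = "_ENT_"

ROLES = (ENT1, ENT2, ENT_BOTH, ENT_OTHER)


class CorpusFormatError(ValueError):
    """Raised for structurally invalid corpora (bad offsets, dangling ids)."""


@dataclass(frozen=True)
class Token:
    index: int
    surface: str
    char_start: int
    char_end: int
    pos: Optional[str] = None
    lemma: Optional[str] = None

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise CorpusFormatError(
                f"token {self.index} ({self.surface!r}): empty character span"
            )

    @property
    def lemma_or_surface(self) -> str:
        """Lemma when annotated, otherwise the lowercased surface form."""
        return self.lemma if self.lemma else self.surface.lower()


@dataclass(frozen=True)
class Entity:
    id: str
    char_ranges: tuple[tuple[int, int], ...]
    text: str

    def __post_init__(self) -> None:
        if not self.char_ranges:
            raise CorpusFormatError(f"entity {self.id}: no character ranges")
        prev_end = -1
        for start, end in self.char_ranges:
            if start >= end:
                raise CorpusFormatError(f"entity {self.id}: empty range {start}-{end}")
            if start < prev_end:
                raise CorpusFormatError(
                    f"entity {self.id}: ranges overlap or are unsorted"
                )
            prev_end = end


@dataclass(frozen=True)
class PairAnnotation:
    e1: str
    e2: str
    interaction: bool

    def __post_init__(self) -> None:
        if self.e1 == self.e2:
            raise CorpusFormatError(f"self-pair on entity {self.e1}")

    @property
    def key(self) -> frozenset[str]:
        """Orderless identity of the pair."""
        return frozenset((self.e1, self.e2))


@dataclass
class Sentence:
    id: str
    text: str
    tokens: list[Token] = field(default_factory=list)
    entities: list[Entity] = field(default_factory=list)
    pairs: list[PairAnnotation] = field(default_factory=list)
    #: (head token index, dependent token index, dependency type)
    dependency_edges: list[tuple[int, int, str]] = field(default_factory=list)
    #: Penn-style bracketed constituent parse, or None when no parse layer
    constituent_tree: Optional[str] = None
    #: False when the sentence lacks a usable parse layer; parse-based
    #: kernels must not be applied to such sentences.
    parse_ok: bool = True

    def entity_by_id(self, entity_id: str) -> Entity:
        for entity in self.entities:
            if entity.id == entity_id:
                return entity
        raise CorpusFormatError(f"sentence {self.id}: unknown entity id {entity_id}")

    def validate(self) -> None:
        n = len(self.text)
        prev_end = -1
        for token in self.tokens:
            if token.char_end > n:
                raise CorpusFormatError(
                    f"sentence {self.id}: token {token.index} exceeds text length"
                )
            if token.char_start < prev_end:
                raise CorpusFormatError(
                    f"sentence {self.id}: tokens overlap or are unsorted"
                )
            prev_end = token.char_end
        for entity in self.entities:
            for start, end in entity.char_ranges:
                if end > n:
                    raise CorpusFormatError(
                        f"sentence {self.id}: entity {entity.id} range outside text"
                    )
        ids = {entity.id for entity in self.entities}
        if len(ids) != len(self.entities):
            raise CorpusFormatError(f"sentence {self.id}: duplicate entity ids")
        for pair in self.pairs:
            for eid in (pair.e1, pair.e2):
                if eid not in ids:
                    raise CorpusFormatError(
                        f"sentence {self.id}: pair references unknown entity {eid}"
                    )
        valid = range(len(self.tokens))
        for head, dep, label in self.dependency_edges:
            if head not in valid or dep not in valid:
                raise CorpusFormatError(
                    f"sentence {self.id}: dependency edge ({head},{dep}) out of range"
                )
            if head == dep:
                raise CorpusFormatError(f"sentence {self.id}: dependency self-loop")
            if not label:
                raise CorpusFormatError(f"sentence {self.id}: empty dependency label")


@dataclass
class Document:
    id: str
    sentences: list[Sentence] = field(default_factory=list)


@dataclass
class Corpus:
    name: str
    documents: list[Document] = field(default_factory=list)

    def iter_sentences(self) -> Iterator[tuple[Document, Sentence]]:
        for document in self.documents:
            for sentence in document.sentences:
                yield document, sentence

    def validate(self) -> None:
        doc_ids = [d.id for d in self.documents]
        if len(set(doc_ids)) != len(doc_ids):
            raise CorpusFormatError(f"corpus {self.name}: duplicate document ids")
        for document in self.documents:
            sent_ids = [s.id for s in document.sentences]
            if len(set(sent_ids)) != len(sent_ids):
                raise CorpusFormatError(
                    f"document {document.id}: duplicate sentence ids"
                )
            for sentence in document.sentences:
                sentence.validate()


@dataclass
class CandidateInstance:
    """One blinded entity pair in one sentence: the unit of classification."""

    id: str
    document_id: str
    sentence_id: str
    pair: PairAnnotation
    label: bool
    #: per-token role, aligned with sentence.tokens; None for non-entity tokens
    roles: tuple[Optional[str], ...]
    e1_tokens: frozenset[int]
    e2_tokens: frozenset[int]
    sentence: Sentence

    def __post_init__(self) -> None:
        if not self.e1_tokens or not self.e2_tokens:
            raise CorpusFormatError(
                f"instance {self.id}: entity with no aligned tokens"
            )
        if self.label != self.pair.interaction:
            raise CorpusFormatError(f"instance {self.id}: label/pair mismatch")

    def token_label(self, index: int) -> str:
        """Blinded label of a token: its role if it is an entity token,
        otherwise the lowercased surface form."""
        role = self.roles[index]
        return role if role is not None else self.sentence.tokens[index].surface.lower()

    @property
    def e1_representative(self) -> int:
        """Path endpoint for the first pair entity: its lowest-index token."""
        return min(self.e1_tokens)

    @property
    def e2_representative(self) -> int:
        return min(self.e2_tokens)


def n_candidate_pairs(n_entities: int) -> int:
    """Number of candidate instances a sentence with ``n_entities`` yields."""
    return n_entities * (n_entities - 1) // 2


def unordered_entity_pairs(entities: list[Entity]) -> Iterator[tuple[Entity, Entity]]:
    yield from itertools.combinations(entities, 2)
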