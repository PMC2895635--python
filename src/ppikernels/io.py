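"""Reading and writing the PPI learning format.

The learning format is the XML interchange format shared by the public PPI
benchmark corpora (AIMed, BioInfer, HPRD50, IEPA, LLL): a ``corpus`` of
``document`` elements, each holding ``sentence`` elements with ``entity`` and
``pair`` annotations plus ``sentenceanalyses`` carrying tokenizations and
parses.  ``charOffset`` strings are inclusive of both endpoints ("0-3" covers
four characters) and may list several comma-separated ranges for
noncontiguous entities; internally everything is 0-based half-open.

The distributed corpus dialects vary slightly in attribute vocabulary, so the
reader resolves attribute names through configurable alias lists
(:class:`ReaderConfig`).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

from lxml import etree

from .model import (
    ENT1,
    ENT2,
    ENT_BOTH,
    ENT_OTHER,
    CandidateInstance,
    Corpus,
    CorpusFormatError,
    Document,
    Entity,
    PairAnnotation,
    Sentence,
    Token,
)

_TRUE_STRINGS = {"true", "1", "yes", "t"}


class AlignmentError(CorpusFormatError):
    """Entity/token offset inconsistency: an entity overlaps no token."""


@dataclass
class ReaderConfig:
    """Attribute-name aliases and layer selection for the reader.

    The learning format allows several alternative tokenizations and parses
    per sentence; ``tokenization`` / ``parse`` select a layer by its
    ``tokenizer`` / ``parser`` attribute, defaulting to the first layer found.
    """

    char_offset_attrs: tuple[str, ...] = ("charOffset", "offset", "charOffsets")
    interaction_attrs: tuple[str, ...] = ("interaction", "label")
    pos_attrs: tuple[str, ...] = ("POS", "pos")
    lemma_attrs: tuple[str, ...] = ("lemma", "base")
    tokenization: str | None = None
    parse: str | None = None


@dataclass
class LoadSummary:
    """Bookkeeping of what the reader kept and dropped.

    Published pair counts for the benchmark corpora differ between groups,
    largely because of how self-pairs and duplicate pairs are filtered; the
    reader therefore counts every dropped record instead of filtering
    silently.
    """

    documents: int = 0
    sentences: int = 0
    pairs_kept: int = 0
    self_pairs_dropped: int = 0
    duplicate_pairs_dropped: int = 0
    sentences_without_parse: int = 0


@dataclass
class CorpusStats:
    documents: int = 0
    sentences: int = 0
    entities: int = 0
    positive_pairs: int = 0
    negative_pairs: int = 0

    @property
    def total_pairs(self) -> int:
        return self.positive_pairs + self.negative_pairs


def _get_attr(element, names: tuple[str, ...], required: bool = False) -> str | None:
    for name in names:
        value = element.get(name)
        if value is not None:
            return value
    if required:
        raise CorpusFormatError(
            f"element <{element.tag}> missing required attribute "
            f"(one of {', '.join(names)})"
        )
    return None


def parse_char_offset(value: str) -> tuple[tuple[int, int], ...]:
    """Convert an inclusive ``"a-b[,c-d...]"`` offset string to half-open ranges."""
    ranges = []
    for part in value.split(","):
        start_s, _, end_s = part.strip().partition("-")
        start, end = int(start_s), int(end_s)
        ranges.append((start, end + 1))
    return tuple(ranges)


def format_char_offset(ranges: tuple[tuple[int, int], ...]) -> str:
    return ",".join(f"{start}-{end - 1}" for start, end in ranges)


def _parse_bool(value: str) -> bool:
    return value.strip().lower() in _TRUE_STRINGS


def _read_sentence(
    sent_el, config: ReaderConfig, summary: LoadSummary
) -> Sentence:
    sid = sent_el.get("id") or ""
    text = sent_el.get("text") or ""
    sentence = Sentence(id=sid, text=text)

    for ent_el in sent_el.findall("entity"):
        offset = _get_attr(ent_el, config.char_offset_attrs, required=True)
        sentence.entities.append(
            Entity(
                id=ent_el.get("id") or "",
                char_ranges=parse_char_offset(offset),
                text=ent_el.get("text") or "",
            )
        )

    entity_ids = {e.id for e in sentence.entities}
    seen_pair_keys: set[frozenset[str]] = set()
    for pair_el in sent_el.findall("pair"):
        e1, e2 = pair_el.get("e1") or "", pair_el.get("e2") or ""
        for eid in (e1, e2):
            if eid not in entity_ids:
                raise CorpusFormatError(
                    f"sentence {sid}: pair references unknown entity {eid}"
                )
        if e1 == e2:
            summary.self_pairs_dropped += 1
            continue
        key = frozenset((e1, e2))
        if key in seen_pair_keys:
            summary.duplicate_pairs_dropped += 1
            continue
        seen_pair_keys.add(key)
        interaction = _parse_bool(
            _get_attr(pair_el, config.interaction_attrs, required=True)
        )
        sentence.pairs.append(PairAnnotation(e1=e1, e2=e2, interaction=interaction))
        summary.pairs_kept += 1

    analyses = sent_el.find("sentenceanalyses")
    tokenization_el = None
    parse_el = None
    if analyses is not None:
        tokenizations = analyses.find("tokenizations")
        if tokenizations is not None:
            candidates = tokenizations.findall("tokenization")
            tokenization_el = _select_layer(candidates, "tokenizer", config.tokenization)
        parses = analyses.find("parses")
        if parses is not None:
            candidates = parses.findall("parse")
            parse_el = _select_layer(candidates, "parser", config.parse)

    if tokenization_el is not None:
        token_id_to_index: dict[str, int] = {}
        for index, tok_el in enumerate(tokenization_el.findall("token")):
            offset = _get_attr(tok_el, config.char_offset_attrs, required=True)
            ranges = parse_char_offset(offset)
            sentence.tokens.append(
                Token(
                    index=index,
                    surface=tok_el.get("text") or "",
                    char_start=ranges[0][0],
                    char_end=ranges[-1][1],
                    pos=_get_attr(tok_el, config.pos_attrs),
                    lemma=_get_attr(tok_el, config.lemma_attrs),
                )
            )
            tid = tok_el.get("id")
            if tid:
                token_id_to_index[tid] = index

        if parse_el is not None:
            sentence.constituent_tree = parse_el.get("bracketing")
            for dep_el in parse_el.findall("dependency"):
                head = _resolve_token_ref(dep_el.get("t1"), token_id_to_index, sid)
                dep = _resolve_token_ref(dep_el.get("t2"), token_id_to_index, sid)
                sentence.dependency_edges.append(
                    (head, dep, dep_el.get("type") or "dep")
                )

    if tokenization_el is None or parse_el is None:
        sentence.parse_ok = False
        summary.sentences_without_parse += 1
        warnings.warn(
            f"sentence {sid}: missing tokenization or parse layer; "
            "unusable for parse-based kernels",
            stacklevel=2,
        )
    return sentence


def _select_layer(candidates, attr: str, wanted: str | None):
    if not candidates:
        return None
    if wanted is None:
        return candidates[0]
    for candidate in candidates:
        if candidate.get(attr) == wanted:
            return candidate
    return None


def _resolve_token_ref(ref: str | None, mapping: dict[str, int], sid: str) -> int:
    if ref is None:
        raise CorpusFormatError(f"sentence {sid}: dependency missing token reference")
    if ref in mapping:
        return mapping[ref]
    # some dialects use bare indices or "t<NUM>" without an id table
    digits = ref.lstrip("wt_")
    if digits.isdigit():
        return int(digits)
    raise CorpusFormatError(f"sentence {sid}: unresolvable token reference {ref!r}")


def read_learning_format(
    source, config: ReaderConfig | None = None
) -> tuple[Corpus, LoadSummary]:
    """Parse learning-format XML into the data model.

    ``source`` may be a filename, a path, or a file-like object.  Pairs are
    deduplicated as unordered pairs and self-pairs are removed; the counts of
    dropped records are reported in the returned :class:`LoadSummary`.
    """
    config = config or ReaderConfig()
    summary = LoadSummary()
    root = etree.parse(source).getroot()
    if root.tag != "corpus":
        raise CorpusFormatError(f"expected <corpus> root, found <{root.tag}>")
    corpus = Corpus(name=root.get("source") or root.get("id") or "corpus")
    for doc_el in root.findall("document"):
        document = Document(id=doc_el.get("id") or "")
        for sent_el in doc_el.findall("sentence"):
            document.sentences.append(_read_sentence(sent_el, config, summary))
        corpus.documents.append(document)
        summary.sentences += len(document.sentences)
    summary.documents = len(corpus.documents)
    corpus.validate()
    return corpus, summary


def write_learning_format(corpus: Corpus, target=None) -> bytes:
    """Serialize a corpus back to learning-format XML.

    Attribute ordering is fixed so repeated writes of the same corpus are
    byte-identical.  Returns the XML bytes; when ``target`` is given the
    bytes are also written there.
    """
    root = etree.Element("corpus", source=corpus.name)
    for document in corpus.documents:
        doc_el = etree.SubElement(root, "document", id=document.id)
        for sentence in document.sentences:
            sent_el = etree.SubElement(
                doc_el, "sentence", id=sentence.id, text=sentence.text
            )
            for entity in sentence.entities:
                etree.SubElement(
                    sent_el,
                    "entity",
                    id=entity.id,
                    charOffset=format_char_offset(entity.char_ranges),
                    text=entity.text,
                )
            for pair in sentence.pairs:
                etree.SubElement(
                    sent_el,
                    "pair",
                    e1=pair.e1,
                    e2=pair.e2,
                    interaction="True" if pair.interaction else "False",
                )
            if sentence.tokens:
                analyses = etree.SubElement(sent_el, "sentenceanalyses")
                tokenizations = etree.SubElement(analyses, "tokenizations")
                tokenization = etree.SubElement(
                    tokenizations, "tokenization", tokenizer="gold"
                )
                for token in sentence.tokens:
                    attrs = {
                        "id": f"t{token.index}",
                        "text": token.surface,
                        "charOffset": format_char_offset(
                            ((token.char_start, token.char_end),)
                        ),
                    }
                    if token.pos is not None:
                        attrs["POS"] = token.pos
                    if token.lemma is not None:
                        attrs["lemma"] = token.lemma
                    etree.SubElement(tokenization, "token", **attrs)
                parses = etree.SubElement(analyses, "parses")
                parse_attrs = {"parser": "gold", "tokenizer": "gold"}
                if sentence.constituent_tree is not None:
                    parse_attrs["bracketing"] = sentence.constituent_tree
                parse = etree.SubElement(parses, "parse", **parse_attrs)
                for i, (head, dep, label) in enumerate(sentence.dependency_edges):
                    etree.SubElement(
                        parse,
                        "dependency",
                        id=f"d{i}",
                        t1=f"t{head}",
                        t2=f"t{dep}",
                        type=label,
                    )
    blob = etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    if target is not None:
        if hasattr(target, "write"):
            target.write(blob)
        else:
            with open(target, "wb") as handle:
                handle.write(blob)
    return blob


def align_entities(sentence: Sentence) -> dict[str, frozenset[int]]:
    """Map each entity to every token whose span intersects any entity range.

    A token "at least partly overlapping" an entity is marked as belonging to
    it, so one token may carry several entities (e.g. "Arp2/3") and one
    entity may spread over several, possibly noncontiguous, tokens.
    """
    mapping: dict[str, frozenset[int]] = {}
    for entity in sentence.entities:
        tokens = set()
        for start, end in entity.char_ranges:
            for token in sentence.tokens:
                if token.char_start < end and start < token.char_end:
                    tokens.add(token.index)
        if not tokens:
            raise AlignmentError(
                f"sentence {sentence.id}: entity {entity.id} overlaps no token"
            )
        mapping[entity.id] = frozenset(tokens)
    return mapping


def blind_and_enumerate(
    sentence: Sentence, document_id: str = "", corpus_name: str = ""
) -> list[CandidateInstance]:
    """Enumerate one blinded candidate instance per unordered entity pair.

    A sentence with n entities yields n(n-1)/2 instances.  Within each
    instance the pair's tokens take the roles ENT1/ENT2 (ENT_BOTH for a token
    shared by both entities), tokens of the remaining entities take
    ENT_OTHER, and all other tokens keep role None.  Pairs without an
    annotation are labeled non-interacting.
    """
    if len(sentence.entities) < 2:
        return []
    alignment = align_entities(sentence)
    labels = {pair.key: pair.interaction for pair in sentence.pairs}
    instances = []
    for ent_a, ent_b in itertools.combinations(sentence.entities, 2):
        e1_tokens = alignment[ent_a.id]
        e2_tokens = alignment[ent_b.id]
        other_tokens: set[int] = set()
        for entity in sentence.entities:
            if entity.id not in (ent_a.id, ent_b.id):
                other_tokens |= alignment[entity.id]
        roles: list[str | None] = [None] * len(sentence.tokens)
        for index in other_tokens:
            roles[index] = ENT_OTHER
        for index in e1_tokens:
            roles[index] = ENT1
        for index in e2_tokens:
            roles[index] = ENT_BOTH if index in e1_tokens else ENT2
        interaction = labels.get(frozenset((ent_a.id, ent_b.id)), False)
        prefix = f"{corpus_name}." if corpus_name else ""
        instances.append(
            CandidateInstance(
                id=f"{prefix}{document_id}.{sentence.id}.{ent_a.id}-{ent_b.id}",
                document_id=f"{prefix}{document_id}",
                sentence_id=f"{prefix}{document_id}.{sentence.id}",
                pair=PairAnnotation(e1=ent_a.id, e2=ent_b.id, interaction=interaction),
                label=interaction,
                roles=tuple(roles),
                e1_tokens=e1_tokens,
                e2_tokens=e2_tokens,
                sentence=sentence,
            )
        )
    return instances


def corpus_instances(corpus: Corpus) -> list[CandidateInstance]:
    """All candidate instances of a corpus, in document/sentence order."""
    instances = []
    for document, sentence in corpus.iter_sentences():
        instances.extend(
            blind_and_enumerate(sentence, document.id, corpus_name=corpus.name)
        )
    return instances


def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Counts after pair filtering; pair totals equal the candidate instances."""
    stats = CorpusStats(documents=len(corpus.documents))
    for document, sentence in corpus.iter_sentences():
        stats.sentences += 1
        stats.entities += len(sentence.entities)
        for instance in blind_and_enumerate(sentence, document.id, corpus.name):
            if instance.label:
                stats.positive_pairs += 1
            else:
                stats.negative_pairs += 1
    return stats
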