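"""Learning-format reading/writing, entity alignment, and blinding."""

import io

import pytest

from ppikernels.io import (
    AlignmentError,
    align_entities,
    blind_and_enumerate,
    corpus_instances,
    corpus_stats,
    read_learning_format,
    write_learning_format,
)
from ppikernels.model import (
    ENT1,
    ENT2,
    ENT_BOTH,
    ENT_OTHER,
    Corpus,
    CorpusFormatError,
    Entity,
    PairAnnotation,
    Sentence,
    Token,
)

MINIMAL = b"""<?xml version="1.0" encoding="UTF-8"?>
<corpus source="mini">
 <document id="d0">
  <sentence id="d0.s0" text="A binds B .">
   <entity id="d0.s0.e0" charOffset="0-0" text="A"/>
   <entity id="d0.s0.e1" charOffset="8-8" text="B"/>
   <pair e1="d0.s0.e0" e2="d0.s0.e1" interaction="True"/>
   <sentenceanalyses>
    <tokenizations><tokenization tokenizer="t">
     <token id="t0" text="A" charOffset="0-0" POS="NN"/>
     <token id="t1" text="binds" charOffset="2-6" POS="VBZ" lemma="bind"/>
     <token id="t2" text="B" charOffset="8-8" POS="NN"/>
     <token id="t3" text="." charOffset="10-10" POS="."/>
    </tokenization></tokenizations>
    <parses><parse parser="p" tokenizer="t"
      bracketing="(S (NP (NN A)) (VP (VBZ binds) (NP (NN B))) (. .))">
     <dependency id="d0" t1="t1" t2="t0" type="nsubj"/>
     <dependency id="d1" t1="t1" t2="t2" type="dobj"/>
     <dependency id="d2" t1="t1" t2="t3" type="punct"/>
    </parse></parses>
   </sentenceanalyses>
  </sentence>
 </document>
</corpus>
"""


def _read(blob: bytes):
    return read_learning_format(io.BytesIO(blob))


class TestReader:
    def test_minimal_corpus_yields_one_positive_candidate(self):
        corpus, summary = _read(MINIMAL)
        instances = corpus_instances(corpus)
        assert len(instances) == 1
        assert instances[0].label is True
        assert summary.pairs_kept == 1
        assert summary.sentences_without_parse == 0

    def test_inclusive_offsets_become_half_open(self):
        corpus, _ = _read(MINIMAL)
        sentence = corpus.documents[0].sentences[0]
        assert sentence.tokens[1].char_start == 2
        assert sentence.tokens[1].char_end == 7  # "binds" is 5 characters
        assert sentence.entities[0].char_ranges == ((0, 1),)

    def test_pair_listed_in_both_orders_is_deduplicated(self):
        blob = MINIMAL.replace(
            b'<pair e1="d0.s0.e0" e2="d0.s0.e1" interaction="True"/>',
            b'<pair e1="d0.s0.e0" e2="d0.s0.e1" interaction="True"/>'
            b'<pair e1="d0.s0.e1" e2="d0.s0.e0" interaction="True"/>',
        )
        corpus, summary = _read(blob)
        assert len(corpus.documents[0].sentences[0].pairs) == 1
        assert summary.duplicate_pairs_dropped == 1

    def test_self_pair_dropped_and_counted(self):
        blob = MINIMAL.replace(
            b'<pair e1="d0.s0.e0" e2="d0.s0.e1" interaction="True"/>',
            b'<pair e1="d0.s0.e0" e2="d0.s0.e1" interaction="True"/>'
            b'<pair e1="d0.s0.e0" e2="d0.s0.e0" interaction="True"/>',
        )
        _, summary = _read(blob)
        assert summary.self_pairs_dropped == 1
        assert summary.pairs_kept == 1

    def test_pair_with_unknown_entity_is_an_error(self):
        blob = MINIMAL.replace(b'e2="d0.s0.e1" interaction', b'e2="nope" interaction')
        with pytest.raises(CorpusFormatError, match="unknown entity"):
            _read(blob)

    def test_entity_range_outside_text_names_sentence(self):
        blob = MINIMAL.replace(b'charOffset="8-8" text="B"', b'charOffset="98-99" text="B"')
        with pytest.raises(CorpusFormatError, match="d0.s0"):
            _read(blob)

    def test_missing_parse_layer_flags_sentence(self):
        blob = MINIMAL.replace(b"<parses>", b"<ignored>").replace(
            b"</parses>", b"</ignored>"
        )
        with pytest.warns(UserWarning, match="missing tokenization or parse"):
            corpus, summary = _read(blob)
        assert summary.sentences_without_parse == 1
        assert corpus.documents[0].sentences[0].parse_ok is False


class TestWriter:
    def test_empty_corpus_is_valid_xml(self):
        blob = write_learning_format(Corpus(name="empty"))
        corpus, _ = _read(blob)
        assert corpus.documents == []

    def test_roundtrip_preserves_data_model(self, small_corpus):
        blob = write_learning_format(small_corpus)
        reread, _ = _read(blob)
        assert reread.name == small_corpus.name
        original = corpus_instances(small_corpus)
        recovered = corpus_instances(reread)
        assert [i.id for i in recovered] == [i.id for i in original]
        assert [i.label for i in recovered] == [i.label for i in original]
        assert [i.roles for i in recovered] == [i.roles for i in original]
        for a, b in zip(small_corpus.documents, reread.documents):
            for sa, sb in zip(a.sentences, b.sentences):
                assert sa.tokens == sb.tokens
                assert sa.dependency_edges == sb.dependency_edges
                assert sa.constituent_tree == sb.constituent_tree

    def test_two_writes_are_byte_identical(self, small_corpus):
        assert write_learning_format(small_corpus) == write_learning_format(
            small_corpus
        )

    def test_noncontiguous_entity_roundtrips(self):
        sentence = Sentence(
            id="d0.s0",
            text="Arp3 and Arp2 complex",
            tokens=[
                Token(0, "Arp3", 0, 4, "NN"),
                Token(1, "and", 5, 8, "CC"),
                Token(2, "Arp2", 9, 13, "NN"),
                Token(3, "complex", 14, 21, "NN"),
            ],
            entities=[
                Entity("d0.s0.e0", ((0, 4), (14, 21)), "Arp3 complex"),
                Entity("d0.s0.e1", ((9, 13),), "Arp2"),
            ],
            pairs=[PairAnnotation("d0.s0.e0", "d0.s0.e1", True)],
        )
        corpus = Corpus(name="nc")
        from ppikernels.model import Document

        corpus.documents.append(Document(id="d0", sentences=[sentence]))
        reread, _ = _read(write_learning_format(corpus))
        entity = reread.documents[0].sentences[0].entities[0]
        assert entity.char_ranges == ((0, 4), (14, 21))


class TestAlignment:
    def _sentence(self):
        # "Arp2/3" holds two entities in one token; "Arp3 ... complex" is
        # noncontiguous
        return Sentence(
            id="s",
            text="The Arp2/3 complex binds actin",
            tokens=[
                Token(0, "The", 0, 3, "DT"),
                Token(1, "Arp2/3", 4, 10, "NN"),
                Token(2, "complex", 11, 18, "NN"),
                Token(3, "binds", 19, 24, "VBZ"),
                Token(4, "actin", 25, 30, "NN"),
            ],
            entities=[
                Entity("e0", ((4, 8),), "Arp2"),  # Arp2
                Entity("e1", ((4, 7), (8, 10)), "Arp3"),  # Arp + /3 noncontiguous
                Entity("e2", ((25, 30),), "actin"),
            ],
            pairs=[PairAnnotation("e0", "e2", True)],
            dependency_edges=[
                (2, 0, "det"),
                (2, 1, "nn"),
                (3, 2, "nsubj"),
                (3, 4, "dobj"),
            ],
        )

    def test_shared_token_maps_to_both_entities(self):
        mapping = align_entities(self._sentence())
        assert mapping["e0"] == frozenset({1})
        assert mapping["e1"] == frozenset({1})

    def test_noncontiguous_entity_is_union_of_overlaps(self):
        sentence = self._sentence()
        sentence.entities[1] = Entity("e1", ((4, 7), (11, 18)), "Arp complex")
        mapping = align_entities(sentence)
        assert mapping["e1"] == frozenset({1, 2})

    def test_exact_token_span_maps_to_that_token(self):
        mapping = align_entities(self._sentence())
        assert mapping["e2"] == frozenset({4})

    def test_entity_overlapping_no_token_is_an_error(self):
        sentence = self._sentence()
        sentence.tokens = sentence.tokens[:4]
        sentence.text = "The Arp2/3 complex binds"
        with pytest.raises(AlignmentError):
            align_entities(sentence)

    def test_overlapping_pair_gets_combined_role(self):
        sentence = self._sentence()
        sentence.pairs = [PairAnnotation("e0", "e1", False)]
        instances = blind_and_enumerate(sentence, "d")
        instance = next(
            i for i in instances if i.pair.key == frozenset({"e0", "e1"})
        )
        assert instance.roles[1] == ENT_BOTH

    def test_pair_combinatorics_and_roles(self):
        instances = blind_and_enumerate(self._sentence(), "d")
        assert len(instances) == 3  # 3 entities -> 3 unordered pairs
        instance = next(
            i for i in instances if i.pair.key == frozenset({"e0", "e2"})
        )
        assert instance.roles[1] == ENT1
        assert instance.roles[4] == ENT2
        assert instance.roles[0] is None
        assert instance.label is True
        unlabeled = next(
            i for i in instances if i.pair.key == frozenset({"e1", "e2"})
        )
        assert unlabeled.label is False


class TestStatsAndInvariants:
    def test_empty_corpus_stats_all_zero(self):
        stats = corpus_stats(Corpus(name="empty"))
        assert (stats.documents, stats.sentences, stats.entities) == (0, 0, 0)
        assert stats.total_pairs == 0

    def test_stats_match_generator_bookkeeping(self):
        from ppikernels.synthetic import GeneratorConfig, generate

        corpus, bookkeeping = generate(GeneratorConfig(seed=7, n_documents=15))
        stats = corpus_stats(corpus)
        assert stats.documents == bookkeeping["documents"]
        assert stats.sentences == bookkeeping["sentences"]
        assert stats.entities == bookkeeping["entities"]
        assert stats.positive_pairs == bookkeeping["positive_pairs"]
        assert stats.negative_pairs == bookkeeping["negative_pairs"]

    def test_instance_conservation(self, small_corpus):
        expected = sum(
            len(s.entities) * (len(s.entities) - 1) // 2
            for _, s in small_corpus.iter_sentences()
        )
        assert len(corpus_instances(small_corpus)) == expected

    def test_blinding_locality(self, small_corpus):
        """Instances of one sentence differ only in role labels."""
        by_sentence = {}
        for instance in corpus_instances(small_corpus):
            by_sentence.setdefault(instance.sentence_id, []).append(instance)
        for group in by_sentence.values():
            first = group[0]
            for other in group[1:]:
                assert other.sentence is first.sentence
                assert len(other.roles) == len(first.roles)
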