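"""Deterministic generator of learning-format corpora with authored parses.

Every sentence is instantiated from a hand-written template that carries a
tokenization (with POS tags and lemmas), a connected Stanford-style
dependency analysis, and a Penn-style bracketed constituent tree, so every
kernel and protocol can be exercised without running a parser.  Positive
pairs are realized by templates that place an interaction-trigger lemma on
the dependency shortest path between the pair; negative pairs have no
trigger on their path.

Three template dialects are available:

* ``alpha`` -- active-voice frames ("E1 binds E2", "the E1 E3 complex
  activates E2", coordination negatives).
* ``beta`` -- passive/nominal frames sharing the same trigger lemmas but
  different function words and parse shapes ("E2 is bound by E1",
  "expression of E1 and E2 was observed"), inducing a measurable
  train/test distribution shift against ``alpha``.
* ``ordered`` -- order-planted frames for parameter-recovery experiments:
  positive and negative sentences have identical length-2 v-walk multisets
  on the dependency shortest path (the multiset is closed under walk
  reversal, which hides the swap), and only the order of trigger vs filler
  along the path -- a 3-node walk -- separates the classes.

Parses are template-authored, not parser-generated: correctness means
structural validity, not linguistic fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Corpus, Document, Entity, PairAnnotation, Sentence, Token

#: (finite verb, passive participle, lemma) triples of interaction triggers
TRIGGERS = [
    ("binds", "bound", "bind"),
    ("activates", "activated", "activate"),
    ("phosphorylates", "phosphorylated", "phosphorylate"),
    ("inhibits", "inhibited", "inhibit"),
    ("regulates", "regulated", "regulate"),
]
TRIGGER_LEMMAS = frozenset(lemma for _, _, lemma in TRIGGERS)

#: non-trigger predicates used by negative templates
NONTRIGGER_VERBS = [
    ("detected", "detect"),
    ("observed", "observe"),
    ("purified", "purify"),
    ("isolated", "isolate"),
]

CONNECTORS = ["domain", "region", "subunit", "terminus"]
FILLERS = ["complex", "motif", "segment", "cluster"]

DIALECTS = ("alpha", "beta", "ordered")


class GenerationError(ValueError):
    """Raised for unsatisfiable generator configurations."""


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpora.

    Defaults emulate the published benchmark corpora: one or two sentences
    per abstract-like document, mostly two but often three entity mentions
    per sentence (so multi-pair sentences and the leakage machinery are
    exercised), and a positive pair fraction of 0.3, in the middle of the
    0.17-0.50 range spanned by the five public corpora.  ``label_noise``
    flips each pair label independently.
    """

    seed: int
    n_documents: int = 200
    sentences_per_document: tuple[int, int] = (1, 2)
    entity_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.6, 3: 0.4}
    )
    positive_fraction: float = 0.3
    dialects: tuple[str, ...] = ("alpha",)
    label_noise: float = 0.0
    name: str = "synthetic"

    def validate(self) -> None:
        if self.seed is None:
            raise GenerationError("a seed is mandatory")
        if not 0 <= self.positive_fraction <= 1:
            raise GenerationError("positive_fraction must lie in [0, 1]")
        if not 0 <= self.label_noise <= 1:
            raise GenerationError("label_noise must lie in [0, 1]")
        for dialect in self.dialects:
            if dialect not in DIALECTS:
                raise GenerationError(f"unknown template dialect {dialect!r}")
        for count, probability in self.entity_distribution.items():
            if count < 2 or probability < 0:
                raise GenerationError("entity distribution support must be >= 2")


@dataclass
class TemplateSentence:
    """Raw material a template returns before ids and offsets are assigned."""

    tokens: list[tuple[str, str, str]]  # (surface, POS, lemma)
    entity_token_indices: list[int]
    dependency_edges: list[tuple[int, int, str]]
    bracketing: str
    #: (entity order index, entity order index) -> interaction
    pair_labels: dict[tuple[int, int], bool]


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------


def _alpha_pos2(rng, names) -> TemplateSentence:
    verb, _, lemma = TRIGGERS[rng.integers(len(TRIGGERS))]
    e1, e2 = names
    return TemplateSentence(
        tokens=[
            (e1, "NN", e1.lower()),
            (verb, "VBZ", lemma),
            (e2, "NN", e2.lower()),
            (".", ".", "."),
        ],
        entity_token_indices=[0, 2],
        dependency_edges=[(1, 0, "nsubj"), (1, 2, "dobj"), (1, 3, "punct")],
        bracketing=f"(S (NP (NN {e1})) (VP (VBZ {verb}) (NP (NN {e2}))) (. .))",
        pair_labels={(0, 1): True},
    )


def _alpha_neg2(rng, names) -> TemplateSentence:
    verb, lemma = NONTRIGGER_VERBS[rng.integers(len(NONTRIGGER_VERBS))]
    e1, e2 = names
    return TemplateSentence(
        tokens=[
            (e1, "NN", e1.lower()),
            ("and", "CC", "and"),
            (e2, "NN", e2.lower()),
            ("were", "VBD", "be"),
            (verb, "VBN", lemma),
            (".", ".", "."),
        ],
        entity_token_indices=[0, 2],
        dependency_edges=[
            (0, 1, "cc"),
            (0, 2, "conj"),
            (4, 0, "nsubjpass"),
            (4, 3, "auxpass"),
            (4, 5, "punct"),
        ],
        bracketing=(
            f"(S (NP (NN {e1}) (CC and) (NN {e2})) "
            f"(VP (VBD were) (VBN {verb})) (. .))"
        ),
        pair_labels={(0, 1): False},
    )


def _alpha_pos3(rng, names) -> TemplateSentence:
    verb, _, lemma = TRIGGERS[rng.integers(len(TRIGGERS))]
    e1, e3, e2 = names
    return TemplateSentence(
        tokens=[
            ("the", "DT", "the"),
            (e1, "NN", e1.lower()),
            (e3, "NN", e3.lower()),
            ("complex", "NN", "complex"),
            (verb, "VBZ", lemma),
            (e2, "NN", e2.lower()),
            (".", ".", "."),
        ],
        entity_token_indices=[1, 2, 5],
        dependency_edges=[
            (3, 0, "det"),
            (3, 1, "nn"),
            (3, 2, "nn"),
            (4, 3, "nsubj"),
            (4, 5, "dobj"),
            (4, 6, "punct"),
        ],
        bracketing=(
            f"(S (NP (DT the) (NN {e1}) (NN {e3}) (NN complex)) "
            f"(VP (VBZ {verb}) (NP (NN {e2}))) (. .))"
        ),
        pair_labels={(0, 1): False, (0, 2): True, (1, 2): True},
    )


def _alpha_neg3(rng, names) -> TemplateSentence:
    verb, lemma = NONTRIGGER_VERBS[rng.integers(len(NONTRIGGER_VERBS))]
    e1, e2, e3 = names
    return TemplateSentence(
        tokens=[
            (e1, "NN", e1.lower()),
            (",", ",", ","),
            (e2, "NN", e2.lower()),
            ("and", "CC", "and"),
            (e3, "NN", e3.lower()),
            ("were", "VBD", "be"),
            (verb, "VBN", lemma),
            (".", ".", "."),
        ],
        entity_token_indices=[0, 2, 4],
        dependency_edges=[
            (0, 1, "punct"),
            (0, 2, "conj"),
            (0, 3, "cc"),
            (0, 4, "conj"),
            (6, 0, "nsubjpass"),
            (6, 5, "auxpass"),
            (6, 7, "punct"),
        ],
        bracketing=(
            f"(S (NP (NN {e1}) (, ,) (NN {e2}) (CC and) (NN {e3})) "
            f"(VP (VBD were) (VBN {verb})) (. .))"
        ),
        pair_labels={(0, 1): False, (0, 2): False, (1, 2): False},
    )


def _beta_pos2(rng, names) -> TemplateSentence:
    _, participle, lemma = TRIGGERS[rng.integers(len(TRIGGERS))]
    ea, eb = names
    return TemplateSentence(
        tokens=[
            (ea, "NN", ea.lower()),
            ("is", "VBZ", "be"),
            (participle, "VBN", lemma),
            ("by", "IN", "by"),
            (eb, "NN", eb.lower()),
            (".", ".", "."),
        ],
        entity_token_indices=[0, 4],
        dependency_edges=[
            (2, 0, "nsubjpass"),
            (2, 1, "auxpass"),
            (2, 3, "prep"),
            (3, 4, "pobj"),
            (2, 5, "punct"),
        ],
        bracketing=(
            f"(S (NP (NN {ea})) (VP (VBZ is) (VP (VBN {participle}) "
            f"(PP (IN by) (NP (NN {eb}))))) (. .))"
        ),
        pair_labels={(0, 1): True},
    )


def _beta_neg2(rng, names) -> TemplateSentence:
    verb, lemma = NONTRIGGER_VERBS[rng.integers(len(NONTRIGGER_VERBS))]
    ea, eb = names
    return TemplateSentence(
        tokens=[
            ("expression", "NN", "expression"),
            ("of", "IN", "of"),
            (ea, "NN", ea.lower()),
            ("and", "CC", "and"),
            (eb, "NN", eb.lower()),
            ("was", "VBD", "be"),
            (verb, "VBN", lemma),
            (".", ".", "."),
        ],
        entity_token_indices=[2, 4],
        dependency_edges=[
            (0, 1, "prep"),
            (1, 2, "pobj"),
            (2, 3, "cc"),
            (2, 4, "conj"),
            (6, 0, "nsubjpass"),
            (6, 5, "auxpass"),
            (6, 7, "punct"),
        ],
        bracketing=(
            f"(S (NP (NP (NN expression)) (PP (IN of) "
            f"(NP (NN {ea}) (CC and) (NN {eb})))) "
            f"(VP (VBD was) (VBN {verb})) (. .))"
        ),
        pair_labels={(0, 1): False},
    )


def _beta_pos3(rng, names) -> TemplateSentence:
    _, participle, lemma = TRIGGERS[rng.integers(len(TRIGGERS))]
    ea, eb, ec = names
    return TemplateSentence(
        tokens=[
            ("the", "DT", "the"),
            (ea, "NN", ea.lower()),
            (eb, "NN", eb.lower()),
            ("heterodimer", "NN", "heterodimer"),
            ("is", "VBZ", "be"),
            (participle, "VBN", lemma),
            ("by", "IN", "by"),
            (ec, "NN", ec.lower()),
            (".", ".", "."),
        ],
        entity_token_indices=[1, 2, 7],
        dependency_edges=[
            (3, 0, "det"),
            (3, 1, "nn"),
            (3, 2, "nn"),
            (5, 3, "nsubjpass"),
            (5, 4, "auxpass"),
            (5, 6, "prep"),
            (6, 7, "pobj"),
            (5, 8, "punct"),
        ],
        bracketing=(
            f"(S (NP (DT the) (NN {ea}) (NN {eb}) (NN heterodimer)) "
            f"(VP (VBZ is) (VP (VBN {participle}) (PP (IN by) (NP (NN {ec}))))) (. .))"
        ),
        pair_labels={(0, 1): False, (0, 2): True, (1, 2): True},
    )


def _beta_neg3(rng, names) -> TemplateSentence:
    verb, lemma = NONTRIGGER_VERBS[rng.integers(len(NONTRIGGER_VERBS))]
    ea, eb, ec = names
    return TemplateSentence(
        tokens=[
            ("levels", "NNS", "level"),
            ("of", "IN", "of"),
            (ea, "NN", ea.lower()),
            (",", ",", ","),
            (eb, "NN", eb.lower()),
            ("and", "CC", "and"),
            (ec, "NN", ec.lower()),
            ("were", "VBD", "be"),
            (verb, "VBN", lemma),
            (".", ".", "."),
        ],
        entity_token_indices=[2, 4, 6],
        dependency_edges=[
            (0, 1, "prep"),
            (1, 2, "pobj"),
            (2, 3, "punct"),
            (2, 4, "conj"),
            (2, 5, "cc"),
            (2, 6, "conj"),
            (8, 0, "nsubjpass"),
            (8, 7, "auxpass"),
            (8, 9, "punct"),
        ],
        bracketing=(
            f"(S (NP (NP (NNS levels)) (PP (IN of) "
            f"(NP (NN {ea}) (, ,) (NN {eb}) (CC and) (NN {ec})))) "
            f"(VP (VBD were) (VBN {verb})) (. .))"
        ),
        pair_labels={(0, 1): False, (0, 2): False, (1, 2): False},
    )


def _ordered(rng, names, positive: bool) -> TemplateSentence:
    """Order-planted chain: E1 - c - X - Y - c - E2 with a uniform edge label.

    The trigger occupies X in positives and Y in negatives, so the length-2
    v-walk multiset of the path (closed under reversal) is identical for the
    two classes and only a 3-node walk reveals the order.
    """
    verb, _, _ = TRIGGERS[rng.integers(len(TRIGGERS))]
    connector = CONNECTORS[rng.integers(len(CONNECTORS))]
    filler = FILLERS[rng.integers(len(FILLERS))]
    x, y = (verb, filler) if positive else (filler, verb)
    x_pos = "VBZ" if positive else "NN"
    y_pos = "NN" if positive else "VBZ"
    e1, e2 = names
    return TemplateSentence(
        tokens=[
            (e1, "NN", e1.lower()),
            (connector, "NN", connector),
            (x, x_pos, x.lower()),
            (y, y_pos, y.lower()),
            (connector, "NN", connector),
            (e2, "NN", e2.lower()),
            (".", ".", "."),
        ],
        entity_token_indices=[0, 5],
        dependency_edges=[
            (1, 0, "dep"),
            (2, 1, "dep"),
            (3, 2, "dep"),
            (4, 3, "dep"),
            (5, 4, "dep"),
            (5, 6, "punct"),
        ],
        bracketing=(
            f"(S (NN {e1}) (NN {connector}) ({x_pos} {x}) ({y_pos} {y}) "
            f"(NN {connector}) (NN {e2}) (. .))"
        ),
        pair_labels={(0, 1): positive},
    )


_TEMPLATES = {
    ("alpha", 2, True): _alpha_pos2,
    ("alpha", 2, False): _alpha_neg2,
    ("alpha", 3, True): _alpha_pos3,
    ("alpha", 3, False): _alpha_neg3,
    ("beta", 2, True): _beta_pos2,
    ("beta", 2, False): _beta_neg2,
    ("beta", 3, True): _beta_pos3,
    ("beta", 3, False): _beta_neg3,
}

#: positive pairs yielded by the positive template at each entity count
_POSITIVES_PER_TEMPLATE = {2: 1, 3: 2}


def _positive_template_rate(config: GeneratorConfig) -> float:
    """Probability of drawing a positive template so that the expected
    positive pair fraction matches the configured target."""
    counts = sorted(config.entity_distribution)
    weights = np.array([config.entity_distribution[c] for c in counts], dtype=float)
    weights = weights / weights.sum()
    expected_pairs = sum(
        w * c * (c - 1) / 2 for w, c in zip(weights, counts)
    )
    expected_positives = sum(
        w * _POSITIVES_PER_TEMPLATE.get(c, 0) for w, c in zip(weights, counts)
    )
    if expected_positives == 0:
        raise GenerationError("no positive templates for the entity distribution")
    rate = config.positive_fraction * expected_pairs / expected_positives
    if rate > 1 + 1e-9:
        raise GenerationError(
            f"positive_fraction {config.positive_fraction} unreachable with the "
            "configured entity distribution"
        )
    return min(rate, 1.0)


def _sentence_from_template(
    template: TemplateSentence, sentence_id: str, noise_flips
) -> Sentence:
    surfaces = [surface for surface, _, _ in template.tokens]
    text = " ".join(surfaces)
    tokens = []
    offset = 0
    for index, (surface, pos, lemma) in enumerate(template.tokens):
        tokens.append(
            Token(
                index=index,
                surface=surface,
                char_start=offset,
                char_end=offset + len(surface),
                pos=pos,
                lemma=lemma,
            )
        )
        offset += len(surface) + 1
    entities = []
    for order, token_index in enumerate(template.entity_token_indices):
        token = tokens[token_index]
        entities.append(
            Entity(
                id=f"{sentence_id}.e{order}",
                char_ranges=((token.char_start, token.char_end),),
                text=token.surface,
            )
        )
    pairs = []
    for (a, b), interaction in sorted(template.pair_labels.items()):
        if noise_flips():
            interaction = not interaction
        pairs.append(
            PairAnnotation(e1=entities[a].id, e2=entities[b].id, interaction=interaction)
        )
    return Sentence(
        id=sentence_id,
        text=text,
        tokens=tokens,
        entities=entities,
        pairs=pairs,
        dependency_edges=list(template.dependency_edges),
        constituent_tree=template.bracketing,
    )


def generate(config: GeneratorConfig) -> tuple[Corpus, dict]:
    """Generate a corpus and its ground-truth bookkeeping.

    Fully deterministic per seed; the bookkeeping counts are accumulated
    while emitting, independently of any later corpus traversal.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    corpus = Corpus(name=config.name)
    bookkeeping = {
        "documents": 0,
        "sentences": 0,
        "entities": 0,
        "positive_pairs": 0,
        "negative_pairs": 0,
    }
    counts = sorted(config.entity_distribution)
    weights = np.array([config.entity_distribution[c] for c in counts], dtype=float)
    weights = weights / weights.sum()
    standard_dialects = [d for d in config.dialects if d != "ordered"]
    positive_rate = (
        _positive_template_rate(config) if standard_dialects else None
    )
    lo, hi = config.sentences_per_document

    name_pool = [f"P{index:03d}" for index in range(400)]

    def noise_flips() -> bool:
        # the draw is consumed regardless of the noise level so corpora
        # generated from one seed differ only in labels across noise levels
        return rng.random() < config.label_noise

    for doc_index in range(config.n_documents):
        document = Document(id=f"d{doc_index}")
        n_sentences = int(rng.integers(lo, hi + 1))
        for sent_index in range(n_sentences):
            dialect = config.dialects[rng.integers(len(config.dialects))]
            sentence_id = f"{document.id}.s{sent_index}"
            if dialect == "ordered":
                positive = rng.random() < config.positive_fraction
                names = [name_pool[i] for i in rng.choice(len(name_pool), 2, replace=False)]
                template = _ordered(rng, names, positive)
            else:
                n_entities = int(counts[rng.choice(len(counts), p=weights)])
                positive = rng.random() < positive_rate
                names = [
                    name_pool[i]
                    for i in rng.choice(len(name_pool), n_entities, replace=False)
                ]
                template = _TEMPLATES[(dialect, n_entities, positive)](rng, names)
            sentence = _sentence_from_template(template, sentence_id, noise_flips)
            document.sentences.append(sentence)
            bookkeeping["sentences"] += 1
            bookkeeping["entities"] += len(sentence.entities)
            for pair in sentence.pairs:
                key = "positive_pairs" if pair.interaction else "negative_pairs"
                bookkeeping[key] += 1
        corpus.documents.append(document)
        bookkeeping["documents"] += 1
    corpus.validate()
    return corpus, bookkeeping


def generate_corpus(config: GeneratorConfig) -> Corpus:
    return generate(config)[0]


def worked_example() -> Sentence:
    """The running example sentence with hand-encoded analyses.

    "SsgG transcription also requires the DNA binding protein GerE", with
    entities SsgG and GerE forming one positive pair; the dependency
    shortest path between them runs through the trigger verb "requires".
    """
    words = [
        ("SsgG", "NN", "ssgg"),
        ("transcription", "NN", "transcription"),
        ("also", "RB", "also"),
        ("requires", "VBZ", "require"),
        ("the", "DT", "the"),
        ("DNA", "NN", "dna"),
        ("binding", "NN", "binding"),
        ("protein", "NN", "protein"),
        ("GerE", "NN", "gere"),
    ]
    template = TemplateSentence(
        tokens=words,
        entity_token_indices=[0, 8],
        dependency_edges=[
            (1, 0, "nn"),
            (3, 1, "nsubj"),
            (3, 2, "advmod"),
            (3, 8, "dobj"),
            (8, 4, "det"),
            (8, 5, "nn"),
            (8, 6, "nn"),
            (8, 7, "nn"),
        ],
        bracketing=(
            "(S (NP (NN SsgG) (NN transcription)) (ADVP (RB also)) "
            "(VP (VBZ requires) (NP (DT the) (NN DNA) (NN binding) "
            "(NN protein) (NN GerE))))"
        ),
        pair_labels={(0, 1): True},
    )
    return _sentence_from_template(template, "w0.s0", lambda: False)
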