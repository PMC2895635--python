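"""Shallow linguistic (SL) kernel.

The only kernel here that ignores the deep parses: it is the sum of a global
and a local context kernel.  The global part represents the sentence by three
bag-of-words term-frequency vectors over the segments *fore-between*,
*between* and *between-after* relative to the candidate entity pair (pair
tokens themselves excluded, other entity tokens blinded); the local part
builds ordered, typed feature vectors from a window of tokens on each side of
each pair entity, using surface features (capitalization, punctuation,
numerals) and shallow linguistic features (POS tag, lemma).  Both parts are
compared by scalar product and, by default, cosine-normalized so that
self-similarity is 1 + 1 = 2.
"""

from __future__ import annotations

import math
from collections import Counter

from ..model import ENT1, ENT2, ENT_BOTH, CandidateInstance
from .base import PairwiseKernel

_PAIR_ROLES = {ENT1, ENT2, ENT_BOTH}
_PAD = "<PAD>"


def _entity_span(token_set: frozenset[int]) -> tuple[int, int]:
    return min(token_set), max(token_set)


class SLKernel(PairwiseKernel):
    """Shallow linguistic kernel: global bag-of-words + local window features.

    Parameters
    ----------
    window:
        Tokens inspected on each side of an entity for the local context.
    use_capitalization, use_punctuation, use_numeral, use_pos, use_lemma,
    use_surface:
        Local feature switches.
    normalize:
        Cosine-normalize the global and local parts separately.
    """

    name = "sl"

    def __init__(
        self,
        window: int = 2,
        use_capitalization: bool = True,
        use_punctuation: bool = True,
        use_numeral: bool = True,
        use_pos: bool = True,
        use_lemma: bool = True,
        use_surface: bool = True,
        normalize: bool = True,
    ):
        self.window = window
        self.use_capitalization = use_capitalization
        self.use_punctuation = use_punctuation
        self.use_numeral = use_numeral
        self.use_pos = use_pos
        self.use_lemma = use_lemma
        self.use_surface = use_surface
        self.normalize = normalize

    # -- global context ----------------------------------------------------

    def _global_vector(self, instance: CandidateInstance) -> Counter:
        """Segment-tagged term frequencies over the three sentence segments.

        The segments are delimited by the positionally first and second pair
        entity: fore-between runs from sentence start to just before the
        second entity, between lies strictly between the two entity spans,
        and between-after runs from just after the first entity to sentence
        end (the three bags deliberately overlap in the between region).
        """
        first_span, second_span = sorted(
            (_entity_span(instance.e1_tokens), _entity_span(instance.e2_tokens))
        )
        vector: Counter = Counter()
        for token in instance.sentence.tokens:
            role = instance.roles[token.index]
            if role in _PAIR_ROLES:
                continue
            label = instance.token_label(token.index)
            i = token.index
            if i < second_span[0]:
                vector[("fore-between", label)] += 1
            if first_span[1] < i < second_span[0]:
                vector[("between", label)] += 1
            if i > first_span[1]:
                vector[("between-after", label)] += 1
        return vector

    # -- local context -----------------------------------------------------

    def _token_features(self, instance: CandidateInstance, index: int) -> list:
        if index < 0 or index >= len(instance.sentence.tokens):
            return [("pad", _PAD)]
        token = instance.sentence.tokens[index]
        role = instance.roles[index]
        surface = role if role is not None else token.surface
        features = []
        if self.use_surface:
            features.append(("surface", surface.lower()))
        if self.use_capitalization:
            if surface.isupper():
                shape = "allcaps"
            elif surface[:1].isupper():
                shape = "initcap"
            else:
                shape = "lower"
            features.append(("cap", shape))
        if self.use_punctuation:
            features.append(("punct", str(not surface[:1].isalnum())))
        if self.use_numeral:
            features.append(("num", str(any(c.isdigit() for c in surface))))
        if self.use_pos:
            features.append(("pos", token.pos or token.surface.lower()))
        if self.use_lemma:
            features.append(("lemma", role if role is not None else token.lemma_or_surface))
        return features

    def _local_vector(self, instance: CandidateInstance) -> Counter:
        """Position-typed window features around both pair entities."""
        vector: Counter = Counter()
        for ent_name, token_set in (("e1", instance.e1_tokens), ("e2", instance.e2_tokens)):
            start, end = _entity_span(token_set)
            for offset in range(1, self.window + 1):
                for side, index in (("left", start - offset), ("right", end + offset)):
                    for feat_name, value in self._token_features(instance, index):
                        vector[(ent_name, side, offset, feat_name, value)] += 1
        return vector

    # -- kernel ------------------------------------------------------------

    def prepare(self, instance: CandidateInstance):
        return self._global_vector(instance), self._local_vector(instance)

    @staticmethod
    def _dot(vx: Counter, vy: Counter) -> float:
        if len(vy) < len(vx):
            vx, vy = vy, vx
        return float(sum(count * vy[key] for key, count in vx.items()))

    def _part(self, vx: Counter, vy: Counter) -> float:
        dot = self._dot(vx, vy)
        if not self.normalize:
            return dot
        norm_x = math.sqrt(self._dot(vx, vx))
        norm_y = math.sqrt(self._dot(vy, vy))
        if norm_x == 0 or norm_y == 0:
            return 0.0
        return dot / (norm_x * norm_y)

    def similarity(self, rep_x, rep_y) -> float:
        global_x, local_x = rep_x
        global_y, local_y = rep_y
        return self._part(global_x, global_y) + self._part(local_x, local_y)
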