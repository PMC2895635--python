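"""Dependency-parse kernels: kBSPS, cosine similarity, and edit distance.

All three compare candidate pairs through the shortest dependency path
between the entity tokens.  kBSPS (k-band shortest path spectrum) widens the
path to its k-band subgraph, enumerates v-walks of lengths q_min..q_max, and
sums a tolerant position-wise matching score t over all walk pairs:

    K(x, y) = sum_{q=q_min}^{q_max} sum_{u in V_q(x)} sum_{v in V_q(y)} t(u, v)

where V_q(p) is the v-walk multiset of the k-band shortest path of pair p.
The tolerant match compares like-shaped walks element by element: an equal
element adds that element type's weight; an unequal element of a tolerated
type adds nothing; an unequal element of an untolerated type zeroes the whole
pair.  By default L (surface word) and E (entity) mismatches are tolerated
while D (dependency type) mismatches are not, with unit weights.

The cosine kernel is the angle between term-frequency vectors of the two
path-label sequences; the edit kernel converts the length-normalized
word-level Levenshtein distance d into exp(-gamma * d).

Instances whose entity tokens are disconnected in the dependency analysis
have similarity 0 to everything (they are retained and fall to the learner's
bias rather than being removed, keeping instance counts protocol-invariant).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from ..model import CandidateInstance
from ..structures import (
    KIND_D,
    VWalk,
    enumerate_vwalks,
    instance_band_subgraph,
    instance_path_labels,
)
from .base import PairwiseKernel


@dataclass(frozen=True)
class TolerantMatchConfig:
    """Per-element-type match weights and mismatch tolerance flags."""

    w_L: float = 1.0
    w_E: float = 1.0
    w_D: float = 1.0
    tol_L: bool = True
    tol_E: bool = True
    tol_D: bool = False

    def __post_init__(self) -> None:
        for weight in (self.w_L, self.w_E, self.w_D):
            if not math.isfinite(weight) or weight < 0:
                raise ValueError("match weights must be finite and non-negative")

    def weight(self, kind: str) -> float:
        return {"L": self.w_L, "E": self.w_E, "D": self.w_D}[kind]

    def tolerated(self, kind: str) -> bool:
        return {"L": self.tol_L, "E": self.tol_E, "D": self.tol_D}[kind]


def tolerant_match(u: VWalk, v: VWalk, cfg: TolerantMatchConfig) -> float:
    """Position-wise tolerant similarity of two like-shaped v-walks."""
    if len(u) != len(v):
        raise ValueError("tolerant_match requires walks of equal length")
    score = 0.0
    for (kind_u, label_u), (kind_v, label_v) in zip(u, v):
        if kind_u != kind_v:
            raise ValueError("tolerant_match requires identical element-type patterns")
        if label_u == label_v:
            score += cfg.weight(kind_u)
        elif not cfg.tolerated(kind_u):
            return 0.0
    return score


def _group_walks(walks: list[VWalk], cfg: TolerantMatchConfig):
    """Group a walk multiset by (type pattern, untolerated-element labels).

    Within a group every pair of walks matches on all untolerated positions,
    so the pairwise score factorizes into a constant (untolerated weights)
    plus, per tolerated position, the dot product of label histograms.  This
    turns the quadratic walk-pair sum into histogram products per group.
    """
    groups: dict = {}
    for walk in walks:
        pattern = tuple(kind for kind, _ in walk)
        hard = tuple(
            label for kind, label in walk if not cfg.tolerated(kind)
        )
        key = (pattern, hard)
        if key not in groups:
            hard_weight = sum(
                cfg.weight(kind) for kind in pattern if not cfg.tolerated(kind)
            )
            soft_positions = [
                i for i, kind in enumerate(pattern) if cfg.tolerated(kind)
            ]
            groups[key] = {
                "count": 0,
                "hard_weight": hard_weight,
                "soft_positions": soft_positions,
                "histograms": [Counter() for _ in soft_positions],
            }
        group = groups[key]
        group["count"] += 1
        for slot, position in enumerate(group["soft_positions"]):
            group["histograms"][slot][walk[position][1]] += 1
    return groups


def _grouped_score(groups_x, groups_y, cfg: TolerantMatchConfig) -> float:
    total = 0.0
    for key, gx in groups_x.items():
        gy = groups_y.get(key)
        if gy is None:
            continue
        pattern = key[0]
        total += gx["count"] * gy["count"] * gx["hard_weight"]
        for slot, position in enumerate(gx["soft_positions"]):
            hx, hy = gx["histograms"][slot], gy["histograms"][slot]
            if len(hy) < len(hx):
                hx, hy = hy, hx
            overlap = sum(count * hy[label] for label, count in hx.items())
            total += cfg.weight(pattern[position]) * overlap
    return total


class KBSPSKernel(PairwiseKernel):
    """k-band shortest path spectrum kernel with tolerant matching.

    Parameters
    ----------
    q_min, q_max:
        Range of v-walk lengths (node counts) entering the spectrum.
    k:
        Band width: nodes within undirected distance k of the shortest path
        are added to the compared subgraph.  k=0 compares the bare path.
    w_L, w_E, w_D, tol_L, tol_E, tol_D:
        Tolerant-matching weights and tolerance flags per element type.
    direction_markers:
        Whether a dependency label traversed against edge direction carries
        a marker, keeping walk orientation significant.
    """

    name = "kbsps"

    def __init__(
        self,
        q_min: int = 2,
        q_max: int = 3,
        k: int = 0,
        w_L: float = 1.0,
        w_E: float = 1.0,
        w_D: float = 1.0,
        tol_L: bool = True,
        tol_E: bool = True,
        tol_D: bool = False,
        direction_markers: bool = True,
    ):
        self.q_min = q_min
        self.q_max = q_max
        self.k = k
        self.w_L = w_L
        self.w_E = w_E
        self.w_D = w_D
        self.tol_L = tol_L
        self.tol_E = tol_E
        self.tol_D = tol_D
        self.direction_markers = direction_markers

    def _validate(self) -> TolerantMatchConfig:
        if not 1 <= self.q_min <= self.q_max:
            raise ValueError("require 1 <= q_min <= q_max")
        if self.k < 0:
            raise ValueError("band width k must be >= 0")
        return TolerantMatchConfig(
            w_L=self.w_L,
            w_E=self.w_E,
            w_D=self.w_D,
            tol_L=self.tol_L,
            tol_E=self.tol_E,
            tol_D=self.tol_D,
        )

    def walks(self, instance: CandidateInstance) -> dict[int, list[VWalk]] | None:
        """v-walk multisets per length q, or None when disconnected."""
        self._validate()
        subgraph = instance_band_subgraph(instance, self.k)
        if subgraph is None:
            return None
        return {
            q: enumerate_vwalks(
                subgraph,
                q,
                include_edge_labels=True,
                direction_markers=self.direction_markers,
            )
            for q in range(self.q_min, self.q_max + 1)
        }

    def prepare(self, instance: CandidateInstance):
        cfg = self._validate()
        walks = self.walks(instance)
        if walks is None:
            return None
        return {q: _group_walks(walk_list, cfg) for q, walk_list in walks.items()}

    def similarity(self, rep_x, rep_y) -> float:
        if rep_x is None or rep_y is None:
            return 0.0
        cfg = self._validate()
        return sum(
            _grouped_score(rep_x[q], rep_y[q], cfg)
            for q in range(self.q_min, self.q_max + 1)
        )


def path_tokens(instance: CandidateInstance) -> list[str]:
    """Shortest-path label sequence: blinding roles for entity tokens,
    lowercased surfaces otherwise; empty when disconnected."""
    return instance_path_labels(instance)


class CosineKernel(PairwiseKernel):
    """Cosine of the term-frequency vectors of the two shortest paths."""

    name = "cosine"

    def prepare(self, instance: CandidateInstance):
        counts = Counter(path_tokens(instance))
        norm = math.sqrt(sum(c * c for c in counts.values()))
        return counts, norm

    def similarity(self, rep_x, rep_y) -> float:
        counts_x, norm_x = rep_x
        counts_y, norm_y = rep_y
        if norm_x == 0 or norm_y == 0:
            return 0.0
        dot = sum(count * counts_y[term] for term, count in counts_x.items())
        return dot / (norm_x * norm_y)


def word_edit_distance(s1: list[str], s2: list[str]) -> float:
    """Word-level Levenshtein distance normalized by the longer length.

    Zero when both sequences are empty; 1 when one is empty and the other is
    not (every token must be inserted).
    """
    n1, n2 = len(s1), len(s2)
    if n1 == 0 and n2 == 0:
        return 0.0
    previous = list(range(n2 + 1))
    for i in range(1, n1 + 1):
        current = [i] + [0] * n2
        for j in range(1, n2 + 1):
            substitution = previous[j - 1] + (s1[i - 1] != s2[j - 1])
            current[j] = min(previous[j] + 1, current[j - 1] + 1, substitution)
        previous = current
    return previous[n2] / max(n1, n2)


class EditKernel(PairwiseKernel):
    """exp(-gamma * normalized word edit distance) between shortest paths."""

    name = "edit"

    def __init__(self, gamma: float = 1.0):
        self.gamma = gamma

    def prepare(self, instance: CandidateInstance):
        return path_tokens(instance)

    def similarity(self, rep_x, rep_y) -> float:
        if not math.isfinite(self.gamma) or self.gamma <= 0:
            raise ValueError("gamma must be finite and positive")
        if not rep_x or not rep_y:
            return 0.0
        return math.exp(-self.gamma * word_edit_distance(rep_x, rep_y))
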