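"""Constituent-tree kernels: spectrum tree (SpT), subtree (ST), subset tree (SST).

All three consume the Penn-style bracketed parse with entity leaves blinded
to their roles.

SpT compares all vertex-walks of a fixed length q (q-grams of edge-connected
tree nodes) by dot product of their count vectors; walk orientation is
significant, so a walk and its reverse are distinct features (both are
enumerated for both compared trees).

ST counts pairs of internal nodes whose complete subtrees (a node with all
its descendants, labels and child order included) are identical.

SST relaxes completeness: a fragment may cut off below any node, but for
every retained node either none or all of its children are kept, so grammar
productions are never broken.  It is computed with the standard co-rooted
recursion

    delta(n1, n2) = 0                        if productions differ
                  = lambda                   if both are preterminal
                  = lambda * prod_i (1 + delta(c_i(n1), c_i(n2)))  otherwise

and K = sum over internal node pairs of delta; lambda in (0, 1] downweights
large fragments (ST-style counting corresponds to lambda = 1).
"""

from __future__ import annotations

from collections import Counter

from ..model import CandidateInstance
from ..structures import TreeNode, enumerate_vwalks, syntax_tree, tree_graph
from .base import PairwiseKernel


class SpTKernel(PairwiseKernel):
    """Spectrum tree kernel over node-label q-walks."""

    name = "spt"

    def __init__(self, q: int = 2):
        self.q = q

    def prepare(self, instance: CandidateInstance):
        if self.q < 1:
            raise ValueError("walk length q must be >= 1")
        graph = tree_graph(syntax_tree(instance))
        walks = enumerate_vwalks(graph, self.q, include_edge_labels=False)
        return Counter(tuple(label for _, label in walk) for walk in walks)

    def similarity(self, rep_x, rep_y) -> float:
        if len(rep_y) < len(rep_x):
            rep_x, rep_y = rep_y, rep_x
        return float(sum(count * rep_y[walk] for walk, count in rep_x.items()))


def _internal_nodes(root: TreeNode) -> list[TreeNode]:
    return [node for node in root.iter_nodes() if not node.is_leaf]


class STKernel(PairwiseKernel):
    """Subtree kernel: identical complete subtrees, counted over internal nodes."""

    name = "st"

    def prepare(self, instance: CandidateInstance):
        return syntax_tree(instance)

    def similarity(self, rep_x: TreeNode, rep_y: TreeNode) -> float:
        memo: dict[tuple[int, int], bool] = {}

        def identical(n1: TreeNode, n2: TreeNode) -> bool:
            key = (id(n1), id(n2))
            if key in memo:
                return memo[key]
            result = (
                n1.label == n2.label
                and len(n1.children) == len(n2.children)
                and all(
                    identical(c1, c2) for c1, c2 in zip(n1.children, n2.children)
                )
            )
            memo[key] = result
            return result

        return float(
            sum(
                identical(n1, n2)
                for n1 in _internal_nodes(rep_x)
                for n2 in _internal_nodes(rep_y)
            )
        )


class SSTKernel(PairwiseKernel):
    """Subset tree kernel with decay ``lam`` (lambda = 1 reproduces undamped
    fragment counting)."""

    name = "sst"

    def __init__(self, lam: float = 0.4):
        self.lam = lam

    def prepare(self, instance: CandidateInstance):
        return syntax_tree(instance)

    def similarity(self, rep_x: TreeNode, rep_y: TreeNode) -> float:
        if not 0 < self.lam <= 1:
            raise ValueError("decay lambda must lie in (0, 1]")
        memo: dict[tuple[int, int], float] = {}

        def delta(n1: TreeNode, n2: TreeNode) -> float:
            key = (id(n1), id(n2))
            if key in memo:
                return memo[key]
            if n1.production() != n2.production():
                value = 0.0
            elif all(c.is_leaf for c in n1.children):
                value = self.lam
            else:
                value = self.lam
                for c1, c2 in zip(n1.children, n2.children):
                    if c1.is_leaf:
                        continue
                    value *= 1.0 + delta(c1, c2)
            memo[key] = value
            return value

        return sum(
            delta(n1, n2)
            for n1 in _internal_nodes(rep_x)
            for n2 in _internal_nodes(rep_y)
        )
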