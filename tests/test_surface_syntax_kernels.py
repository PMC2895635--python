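"""SL kernel and the constituent-tree kernels against independent oracles."""

import itertools
from collections import Counter

import numpy as np
import pytest

from ppikernels.io import blind_and_enumerate
from ppikernels.kernels import SLKernel, SpTKernel, SSTKernel, STKernel
from ppikernels.model import Entity, PairAnnotation, Sentence, Token
from ppikernels.structures import TreeNode, syntax_tree


def _make_instance(words, bracketing=None):
    """Six-token sentence '<E1> <verb> <E2> <w> <w> .' with entity pair."""
    tokens = []
    offset = 0
    for index, (surface, pos, lemma) in enumerate(words):
        tokens.append(Token(index, surface, offset, offset + len(surface), pos, lemma))
        offset += len(surface) + 1
    sentence = Sentence(
        id="s0",
        text=" ".join(w for w, _, _ in words),
        tokens=tokens,
        entities=[
            Entity("e0", ((tokens[0].char_start, tokens[0].char_end),), words[0][0]),
            Entity("e1", ((tokens[2].char_start, tokens[2].char_end),), words[2][0]),
        ],
        pairs=[PairAnnotation("e0", "e1", True)],
        dependency_edges=[(1, 0, "nsubj"), (1, 2, "dobj")],
        constituent_tree=bracketing,
    )
    return blind_and_enumerate(sentence, "d0")[0]


S1 = _make_instance(
    [
        ("A", "NN", "a"),
        ("binds", "VBZ", "bind"),
        ("B", "NN", "b"),
        ("in", "IN", "in"),
        ("vivo", "NN", "vivo"),
        (".", ".", "."),
    ]
)
S2 = _make_instance(
    [
        ("A", "NN", "a"),
        ("inhibits", "VBZ", "inhibit"),
        ("B", "NN", "b"),
        ("in", "IN", "in"),
        ("vivo", "NN", "vivo"),
        (".", ".", "."),
    ]
)


class TestSLKernel:
    def test_identical_instances_score_two_with_normalization(self):
        assert SLKernel()(S1, S1) == pytest.approx(2.0)

    def test_disjoint_instances_score_zero(self):
        # entities far from the sentence edges: the windows contain neither
        # padding nor the other entity, and no word is shared with S1
        words = [
            ("alpha", "XX", "alpha"),
            ("beta", "XX", "beta"),
            ("X9", "XX", "x9"),
            ("gamma", "XX", "gamma"),
            ("delta", "XX", "delta"),
            ("epsilon", "XX", "epsilon"),
            ("Y9", "XX", "y9"),
            ("zeta", "XX", "zeta"),
            ("eta", "XX", "eta"),
        ]
        tokens = []
        offset = 0
        for index, (surface, pos, lemma) in enumerate(words):
            tokens.append(
                Token(index, surface, offset, offset + len(surface), pos, lemma)
            )
            offset += len(surface) + 1
        sentence = Sentence(
            id="s0",
            text=" ".join(w for w, _, _ in words),
            tokens=tokens,
            entities=[
                Entity("e0", ((tokens[2].char_start, tokens[2].char_end),), "X9"),
                Entity("e1", ((tokens[6].char_start, tokens[6].char_end),), "Y9"),
            ],
            pairs=[PairAnnotation("e0", "e1", True)],
        )
        (other,) = blind_and_enumerate(sentence, "d1")
        # global bags share no words; local windows share no feature values
        kernel = SLKernel(
            use_capitalization=False,
            use_punctuation=False,
            use_numeral=False,
            use_pos=False,
        )
        assert kernel(S1, other) == 0.0

    def test_hand_computed_dot_products(self):
        """Frozen values from explicit feature enumeration of S1 vs S2.

        Global bags (pair tokens excluded): the verb lies in all three
        segments, the trailing tokens only in between-after; the verbs
        differ, the other three tokens match -> global dot 3, self dot 6.
        Local windows (window 2): two pad matches left of E1, 4 of 6
        features matching on the differing verbs (twice), full 6-feature
        matches elsewhere -> dot 34, self dot 38.
        """
        unnormalized = SLKernel(normalize=False)
        global_x, local_x = unnormalized.prepare(S1)
        global_y, local_y = unnormalized.prepare(S2)
        assert unnormalized._dot(global_x, global_y) == 3.0
        assert unnormalized._dot(global_x, global_x) == 6.0
        assert unnormalized._dot(local_x, local_y) == 34.0
        assert unnormalized._dot(local_x, local_x) == 38.0
        assert SLKernel()(S1, S2) == pytest.approx(3 / 6 + 34 / 38)

    def test_symmetry(self, fixture_instances):
        kernel = SLKernel()
        for x, y in itertools.islice(
            itertools.combinations(fixture_instances, 2), 10
        ):
            assert kernel(x, y) == pytest.approx(kernel(y, x))


# ---------------------------------------------------------------------------
# tree kernel oracles
# ---------------------------------------------------------------------------


def tree_walk_counts(root: TreeNode, q: int) -> Counter:
    """Independent recursive q-walk enumerator over the node structure."""
    nodes = list(root.iter_nodes())
    index = {id(n): i for i, n in enumerate(nodes)}
    adjacency: dict[int, list[int]] = {i: [] for i in range(len(nodes))}
    for node in nodes:
        for child in node.children:
            adjacency[index[id(node)]].append(index[id(child)])
            adjacency[index[id(child)]].append(index[id(node)])
    labels = [n.label for n in nodes]
    walks: Counter = Counter()

    def recurse(path):
        if len(path) == q:
            walks[tuple(labels[i] for i in path)] += 1
            return
        for neighbor in adjacency[path[-1]]:
            if neighbor not in path:
                recurse(path + [neighbor])

    for start in range(len(nodes)):
        recurse([start])
    return walks


def subtree_serializations(root: TreeNode) -> Counter:
    """Canonical serialization of every internal node's complete subtree."""

    def serialize(node: TreeNode) -> str:
        if node.is_leaf:
            return node.label
        return "(" + node.label + " " + " ".join(map(serialize, node.children)) + ")"

    return Counter(
        serialize(n) for n in root.iter_nodes() if not n.is_leaf
    )


def subset_tree_fragments(root: TreeNode) -> Counter:
    """Exhaustive grammar-respecting fragment enumeration (lambda = 1)."""

    def fragments(node: TreeNode) -> list[str]:
        options = []
        for child in node.children:
            if child.is_leaf:
                options.append([child.label])
            else:
                options.append([f"({child.label})"] + fragments(child))
        return [
            "(" + node.label + " " + " ".join(combo) + ")"
            for combo in itertools.product(*options)
        ]

    counts: Counter = Counter()
    for node in root.iter_nodes():
        if not node.is_leaf:
            counts.update(fragments(node))
    return counts


def random_tree(rng, max_children=3, depth=0) -> TreeNode:
    labels = ["S", "NP", "VP", "PP"]
    words = ["dog", "cat", "runs", "the"]
    if depth >= 2 or rng.random() < 0.3 * depth:
        word = words[rng.integers(len(words))]
        preterminal = ["NN", "VB", "DT"][rng.integers(3)]
        return TreeNode(preterminal, [TreeNode(word, [])])
    n_children = int(rng.integers(1, max_children + 1))
    return TreeNode(
        labels[rng.integers(len(labels))],
        [random_tree(rng, max_children, depth + 1) for _ in range(n_children)],
    )


class TestSpT:
    def test_disjoint_label_sets_score_zero(self):
        x = TreeNode("A", [TreeNode("B", [])])
        y = TreeNode("C", [TreeNode("D", [])])
        assert SpTKernel(q=2).similarity(
            tree_walk_counts(x, 2), tree_walk_counts(y, 2)
        ) == 0

    def test_self_similarity_is_sum_of_squared_counts(self, fixture_instances):
        kernel = SpTKernel(q=2)
        rep = kernel.prepare(fixture_instances[0])
        assert kernel.similarity(rep, rep) == sum(c * c for c in rep.values())

    @pytest.mark.parametrize("q", [2, 3])
    def test_matches_enumeration_oracle(self, q, fixture_instances):
        kernel = SpTKernel(q=q)
        subset = fixture_instances[:6]
        oracle_counts = [tree_walk_counts(syntax_tree(i), q) for i in subset]
        reps = [kernel.prepare(i) for i in subset]
        for i in range(len(subset)):
            assert reps[i] == oracle_counts[i]
            for j in range(i, len(subset)):
                expected = sum(
                    c * oracle_counts[j][w] for w, c in oracle_counts[i].items()
                )
                assert kernel.similarity(reps[i], reps[j]) == expected

    def test_missing_tree_is_an_error(self):
        instance = _make_instance(
            [
                ("A", "NN", "a"),
                ("binds", "VBZ", "bind"),
                ("B", "NN", "b"),
                ("in", "IN", "in"),
                ("vivo", "NN", "vivo"),
                (".", ".", "."),
            ]
        )
        assert instance.sentence.constituent_tree is None
        with pytest.raises(Exception, match="no constituent parse"):
            SpTKernel().prepare(instance)


class TestST:
    def test_disjoint_leaf_labels_score_zero(self):
        x = TreeNode("NP", [TreeNode("NN", [TreeNode("dog", [])])])
        y = TreeNode("NP", [TreeNode("NN", [TreeNode("cat", [])])])
        # NP and NN subtrees differ below, so no complete subtree matches
        assert STKernel().similarity(x, y) == 0

    def test_pairwise_distinct_subtrees_count_internal_nodes(self):
        tree = TreeNode(
            "S",
            [
                TreeNode("NP", [TreeNode("NN", [TreeNode("dog", [])])]),
                TreeNode("VP", [TreeNode("VB", [TreeNode("runs", [])])]),
            ],
        )
        internal = sum(1 for n in tree.iter_nodes() if not n.is_leaf)
        assert STKernel().similarity(tree, tree) == internal

    def test_matches_serialization_oracle_on_random_trees(self):
        rng = np.random.default_rng(17)
        kernel = STKernel()
        for _ in range(15):
            x, y = random_tree(rng), random_tree(rng)
            sx, sy = subtree_serializations(x), subtree_serializations(y)
            expected = sum(c * sy[s] for s, c in sx.items())
            assert kernel.similarity(x, y) == expected


class TestSST:
    def test_equal_preterminal_production(self):
        x = TreeNode("NN", [TreeNode("dog", [])])
        y = TreeNode("NN", [TreeNode("dog", [])])
        assert SSTKernel(lam=1.0).similarity(x, y) == 1.0

    def test_no_common_production_scores_zero(self):
        x = TreeNode("NN", [TreeNode("dog", [])])
        y = TreeNode("NN", [TreeNode("cat", [])])
        assert SSTKernel(lam=1.0).similarity(x, y) == 0.0

    def test_matches_exhaustive_fragment_oracle_at_lambda_one(self):
        rng = np.random.default_rng(29)
        kernel = SSTKernel(lam=1.0)
        for _ in range(15):
            x, y = random_tree(rng), random_tree(rng)
            fx, fy = subset_tree_fragments(x), subset_tree_fragments(y)
            expected = sum(c * fy[f] for f, c in fx.items())
            assert kernel.similarity(x, y) == pytest.approx(expected)

    def test_decay_shrinks_similarity(self):
        rng = np.random.default_rng(3)
        x = random_tree(rng)
        assert SSTKernel(lam=0.4).similarity(x, x) <= SSTKernel(lam=1.0).similarity(
            x, x
        )

    def test_invalid_lambda_is_an_error(self):
        x = TreeNode("NN", [TreeNode("dog", [])])
        with pytest.raises(ValueError):
            SSTKernel(lam=0.0).similarity(x, x)


class TestTreeKernelInvariants:
    def test_sst_dominates_st_at_lambda_one(self, fixture_instances):
        st_kernel, sst_kernel = STKernel(), SSTKernel(lam=1.0)
        subset = fixture_instances[:8]
        trees = [syntax_tree(i) for i in subset]
        for x, y in itertools.combinations_with_replacement(trees, 2):
            assert sst_kernel.similarity(x, y) >= st_kernel.similarity(x, y)

    def test_spt_self_similarity_monotone_under_tree_growth(self):
        base = TreeNode(
            "S",
            [
                TreeNode("NP", [TreeNode("NN", [TreeNode("dog", [])])]),
                TreeNode("VP", [TreeNode("VB", [TreeNode("runs", [])])]),
            ],
        )
        grown = TreeNode(
            "S",
            [
                TreeNode("NP", [TreeNode("NN", [TreeNode("dog", [])])]),
                TreeNode(
                    "VP",
                    [
                        TreeNode("VB", [TreeNode("runs", [])]),
                        TreeNode("RB", [TreeNode("fast", [])]),
                    ],
                ),
            ],
        )
        kernel = SpTKernel(q=2)
        for q in (1, 2, 3):
            kernel = SpTKernel(q=q)
            small = tree_walk_counts(base, q)
            large = tree_walk_counts(grown, q)
            assert kernel.similarity(large, large) >= kernel.similarity(small, small)
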