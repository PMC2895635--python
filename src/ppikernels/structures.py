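"""Dependency graphs, constituent trees, and substructure extraction.

The dependency-based kernels compare candidate pairs through the shortest
dependency path between their entity tokens, optionally widened to the k-band
subgraph (all nodes within undirected distance k of the path), and through
v-walks: alternating node/edge-label sequences whose length counts only the
nodes.  Dependency edges are directed head->dependent, but path finding
treats them as undirected; a walk element traversed against edge direction
carries a direction marker so the orientation information survives at the
substructure level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .model import ROLES, CandidateInstance, CorpusFormatError

# Walk element kinds: D = dependency-type label, E = entity token (any
# blinding role), L = other surface token.
KIND_D = "D"
KIND_E = "E"
KIND_L = "L"

#: marker appended to a dependency label when a walk traverses the edge
#: from dependent to head (against its direction)
AGAINST_MARKER = "^"


class Disconnected:
    """Sentinel: no path exists between the candidate entities."""

    def __repr__(self) -> str:  # pragma: no cover
        return "DISCONNECTED"


DISCONNECTED = Disconnected()

#: a v-walk is a tuple of (kind, label) elements with node and edge elements
#: strictly alternating; its length is its number of node elements
VWalk = tuple[tuple[str, str], ...]


def dependency_graph(instance: CandidateInstance) -> nx.Graph:
    """Undirected token graph of an instance with blinded node labels.

    Node attributes: ``label`` (role or lowercased surface) and ``kind``
    (E for entity tokens, L otherwise).  Edge attributes: ``label`` and
    ``head`` (the head endpoint, preserving the original direction).
    """
    graph = nx.Graph()
    for token in instance.sentence.tokens:
        role = instance.roles[token.index]
        graph.add_node(
            token.index,
            label=instance.token_label(token.index),
            kind=KIND_E if role in ROLES else KIND_L,
        )
    for head, dep, label in instance.sentence.dependency_edges:
        graph.add_edge(head, dep, label=label, head=head)
    return graph


def shortest_path(graph: nx.Graph, a: int, b: int):
    """Minimum-length undirected path from a to b as a node sequence.

    Ties among equal-length paths are broken deterministically: the
    lexicographically smallest token-index sequence is returned (greedy
    smallest-successor walk over the BFS distance field).  Returns
    :data:`DISCONNECTED` when no path exists.
    """
    for node in (a, b):
        if node not in graph:
            raise KeyError(f"node {node} not in graph")
    if a == b:
        return [a]
    dist_to_b = nx.single_source_shortest_path_length(graph, b)
    if a not in dist_to_b:
        return DISCONNECTED
    path = [a]
    current = a
    while current != b:
        current = min(
            n for n in graph[current] if dist_to_b.get(n, -1) == dist_to_b[current] - 1
        )
        path.append(current)
    return path


def k_band(graph: nx.Graph, path: Sequence[int], k: int) -> nx.Graph:
    """Induced subgraph on all nodes within undirected distance <= k of the path.

    k=0 reduces to the induced subgraph on the path nodes themselves.
    """
    if k < 0:
        raise ValueError("band width k must be >= 0")
    for node in path:
        if node not in graph:
            raise KeyError(f"path node {node} not in graph")
    band = set(path)
    frontier = set(path)
    for _ in range(k):
        frontier = {n for f in frontier for n in graph[f]} - band
        if not frontier:
            break
        band |= frontier
    return graph.subgraph(band)


def enumerate_vwalks(
    graph: nx.Graph,
    q: int,
    include_edge_labels: bool = True,
    direction_markers: bool = True,
) -> list[VWalk]:
    """All directed node-repetition-free walks visiting exactly q nodes.

    Walks are enumerated in both orientations (a walk and its reverse are
    distinct) with multiplicities preserved.  On dependency graphs the node
    elements interleave with D elements carrying the edge label, marked with
    :data:`AGAINST_MARKER` when the step runs dependent->head; on syntax-tree
    graphs edge labels are omitted and walks are pure node-label sequences.
    """
    if q < 1:
        raise ValueError("walk length q must be >= 1")
    walks: list[VWalk] = []

    def node_element(node) -> tuple[str, str]:
        data = graph.nodes[node]
        return (data.get("kind", KIND_L), data["label"])

    def extend(walk_nodes: list, elements: list) -> None:
        if len(walk_nodes) == q:
            walks.append(tuple(elements))
            return
        current = walk_nodes[-1]
        for neighbor in sorted(graph[current]):
            if neighbor in walk_nodes:
                continue
            step = list(elements)
            if include_edge_labels:
                edge = graph.edges[current, neighbor]
                label = edge["label"]
                if direction_markers and edge.get("head") == neighbor:
                    label += AGAINST_MARKER
                step.append((KIND_D, label))
            step.append(node_element(neighbor))
            extend(walk_nodes + [neighbor], step)

    for start in sorted(graph.nodes):
        extend([start], [node_element(start)])
    return walks


def vwalk_length(walk: VWalk) -> int:
    """Number of node elements (edges are not counted into the length)."""
    return sum(1 for kind, _ in walk if kind != KIND_D)


def path_endpoints(instance: CandidateInstance) -> tuple[int, int]:
    return instance.e1_representative, instance.e2_representative


def instance_band_subgraph(
    instance: CandidateInstance, k: int = 0
) -> Optional[nx.Graph]:
    """k-band shortest-path subgraph of an instance, or None when the entity
    tokens are disconnected in the dependency analysis."""
    graph = dependency_graph(instance)
    a, b = path_endpoints(instance)
    path = shortest_path(graph, a, b)
    if path is DISCONNECTED:
        return None
    return k_band(graph, path, k)


def instance_path_labels(instance: CandidateInstance) -> list[str]:
    """Node labels along the shortest dependency path, in path order.

    Entity tokens appear as their blinding roles; the list is empty when the
    entities are disconnected.
    """
    graph = dependency_graph(instance)
    a, b = path_endpoints(instance)
    path = shortest_path(graph, a, b)
    if path is DISCONNECTED:
        return []
    return [graph.nodes[n]["label"] for n in path]


# ---------------------------------------------------------------------------
# Constituent trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    label: str
    children: list["TreeNode"]
    #: token index for leaves, None for internal nodes
    token_index: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_nodes(self):
        yield self
        for child in self.children:
            yield from child.iter_nodes()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.iter_nodes() if n.is_leaf]

    def production(self) -> tuple[str, tuple[str, ...]]:
        return (self.label, tuple(c.label for c in self.children))


def parse_bracketed(text: str) -> TreeNode:
    """Parse a Penn-style bracketed string into a tree.

    Leaves are numbered left to right so they can be matched to the sentence
    tokenization.
    """
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    pos = 0
    leaf_counter = 0

    def parse_node() -> TreeNode:
        nonlocal pos, leaf_counter
        if tokens[pos] != "(":
            raise CorpusFormatError(f"malformed bracketing near {tokens[pos]!r}")
        pos += 1
        label = tokens[pos]
        pos += 1
        children: list[TreeNode] = []
        while tokens[pos] != ")":
            if tokens[pos] == "(":
                children.append(parse_node())
            else:
                children.append(
                    TreeNode(label=tokens[pos], children=[], token_index=leaf_counter)
                )
                leaf_counter += 1
                pos += 1
        pos += 1
        return TreeNode(label=label, children=children)

    root = parse_node()
    if pos != len(tokens):
        raise CorpusFormatError("trailing material after bracketed tree")
    return root


def syntax_tree(instance: CandidateInstance) -> TreeNode:
    """Constituent tree of an instance with entity leaves blinded to roles."""
    bracketing = instance.sentence.constituent_tree
    if bracketing is None:
        raise CorpusFormatError(
            f"sentence {instance.sentence_id}: no constituent parse available"
        )
    root = parse_bracketed(bracketing)
    leaves = root.leaves()
    if len(leaves) != len(instance.sentence.tokens):
        raise CorpusFormatError(
            f"sentence {instance.sentence_id}: {len(leaves)} tree leaves for "
            f"{len(instance.sentence.tokens)} tokens"
        )
    for leaf in leaves:
        role = instance.roles[leaf.token_index]
        leaf.label = role if role is not None else leaf.label.lower()
    return root


def tree_graph(root: TreeNode) -> nx.Graph:
    """Undirected node-labeled graph over all tree nodes (for tree v-walks)."""
    graph = nx.Graph()
    counter = 0

    def add(node: TreeNode) -> int:
        nonlocal counter
        node_id = counter
        counter += 1
        graph.add_node(node_id, label=node.label, kind=KIND_L)
        for child in node.children:
            child_id = add(child)
            graph.add_edge(node_id, child_id)
        return node_id

    add(root)
    return graph


def debug_dump(graph: nx.Graph) -> str:
    """DOT-like text rendering of a subgraph, for inspection."""
    lines = ["graph {"]
    for node in sorted(graph.nodes):
        lines.append(f'  {node} [label="{graph.nodes[node]["label"]}"];')
    for u, v, data in sorted(graph.edges(data=True)):
        label = data.get("label", "")
        lines.append(f'  {u} -- {v} [label="{label}"];')
    lines.append("}")
    return "\n".join(lines)
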