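"""UPGMA trees and leveled natural graphs from a distance matrix.

UPGMA (average linkage with size-weighted means) yields a rooted ultrametric
tree: the closest pair of clusters is merged at height d/2, and the merged
cluster's distance to any other is the member-count-weighted mean.  Average
linkage is reducible, so merge heights never decrease and branch lengths
(parent height minus child height) are nonnegative.  Ties between equally
close pairs are broken by the lexicographically smallest pair of cluster
representatives (the smallest leaf label in each cluster) so results are
deterministic.

The natural graph is a nearest-neighbour clustering presented level by
level: at level 1 every item points to its closest item (mutual nearest
pairs become one bidirectional edge) and weakly connected components form
the level-1 clusters; at level k each level-(k-1) cluster points to its
closest cluster under single-linkage distance, and so on until a single
component remains or ``max_level`` is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx
import numpy as np

from .distmat import DistanceMatrix
from .errors import InputError

__all__ = [
    "UpgmaTree",
    "NaturalEdge",
    "NaturalGraph",
    "upgma",
    "to_newick",
    "topology_equal",
    "natural_graph",
    "natural_graph_tsv",
    "natural_graph_dot",
]


@dataclass(frozen=True)
class UpgmaTree:
    """A rooted binary tree node: either a leaf (label) or an internal merge.

    ``height`` is the ultrametric merge height (half the merging distance);
    leaves sit at height 0.
    """

    height: float
    label: str | None = None
    children: tuple["UpgmaTree", "UpgmaTree"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        return self.children[0].leaves() | self.children[1].leaves()

    def walk(self) -> Iterator["UpgmaTree"]:
        yield self
        if not self.is_leaf:
            for child in self.children:
                yield from child.walk()


def upgma(matrix: DistanceMatrix) -> UpgmaTree:
    """Build the UPGMA tree of a distance matrix.

    Merge height is half the merging distance, so two leaves at distance d
    sit under a root of height d/2 and the leaf-to-leaf path length sums
    back to d.
    """
    n = len(matrix)
    if n < 2:
        raise InputError("UPGMA needs at least 2 labels")
    nodes: dict[int, UpgmaTree] = {
        i: UpgmaTree(height=0.0, label=lab) for i, lab in enumerate(matrix.labels)
    }
    reps = {i: lab for i, lab in enumerate(matrix.labels)}  # smallest leaf label
    sizes = {i: 1 for i in range(n)}
    dist = {
        (i, j): float(matrix.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    next_id = n
    while len(nodes) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((reps[kv[0][0]], reps[kv[0][1]])))),
        )
        (i, j), d = best
        if reps[j] < reps[i]:  # children ordered by smallest leaf label
            i, j = j, i
        merged = UpgmaTree(height=d / 2.0, children=(nodes[i], nodes[j]))
        si, sj = sizes[i], sizes[j]
        new_dists = {}
        for k in nodes:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new_dists[k] = (si * dik + sj * djk) / (si + sj)
        for key in [key for key in dist if i in key or j in key]:
            del dist[key]
        del nodes[i], nodes[j], sizes[i], sizes[j], reps[i], reps[j]
        nodes[next_id] = merged
        sizes[next_id] = si + sj
        reps[next_id] = min(merged.leaves())
        for k, v in new_dists.items():
            dist[(min(k, next_id), max(k, next_id))] = v
        next_id += 1
    return next(iter(nodes.values()))


_NEWICK_UNSAFE = set(" \t()[]{}:;,'\"")


def _newick_label(label: str) -> str:
    if any(c in _NEWICK_UNSAFE for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: UpgmaTree) -> str:
    """Serialise with branch lengths = parent height - child height."""

    def render(node: UpgmaTree, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{_newick_label(node.label)}:{length:g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{length:g}"

    if tree.is_leaf:
        return f"{_newick_label(tree.label)}:0;"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    return f"({inner});"


def _bipartitions(tree: UpgmaTree) -> set[frozenset[str]]:
    all_leaves = tree.leaves()
    ref = min(all_leaves)
    parts = set()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        clade = node.leaves()
        side = clade if ref not in clade else all_leaves - clade
        if 0 < len(side) < len(all_leaves):
            parts.add(side)
    return parts


def topology_equal(t1: UpgmaTree, t2: UpgmaTree) -> bool:
    """True iff the two trees induce the same leaf bipartitions (RF distance 0)."""
    if t1.leaves() != t2.leaves():
        raise InputError("trees have different leaf label sets")
    return _bipartitions(t1) == _bipartitions(t2)


@dataclass(frozen=True)
class NaturalEdge:
    """A natural-graph edge between clusters named by their smallest member."""

    level: int
    source: str
    target: str
    bidirectional: bool
    length: float


@dataclass
class NaturalGraph:
    """Levelled nearest-neighbour clustering of a distance matrix.

    ``clusters[k]`` holds the partition *produced by* level ``k + 1`` edges
    (sorted label tuples); ``edges`` carries every directed edge, with
    mutual nearest pairs collapsed into one bidirectional edge whose source
    is the smaller name.
    """

    labels: list[str]
    edges: list[NaturalEdge] = field(default_factory=list)
    clusters: list[list[tuple[str, ...]]] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.clusters)


def _level_edges(
    names: list[str], d: np.ndarray, level: int
) -> list[NaturalEdge]:
    """One nearest-neighbour edge per item; ties to the smallest name."""
    nearest = {}
    for i, name in enumerate(names):
        cands = [(float(d[i, j]), names[j]) for j in range(len(names)) if j != i]
        dist, target = min(cands)
        nearest[name] = (target, dist)
    edges = []
    seen_bi = set()
    for name in sorted(nearest):
        target, dist = nearest[name]
        mutual = nearest[target][0] == name
        if mutual:
            key = tuple(sorted((name, target)))
            if key in seen_bi:
                continue
            seen_bi.add(key)
            edges.append(NaturalEdge(level, key[0], key[1], True, dist))
        else:
            edges.append(NaturalEdge(level, name, target, False, dist))
    return edges


def natural_graph(matrix: DistanceMatrix, max_level: int = 3) -> NaturalGraph:
    """Build the levelled natural graph of a distance matrix."""
    if len(matrix) < 2:
        raise InputError("natural graph needs at least 2 labels")
    if max_level < 1:
        raise InputError("max_level must be >= 1")
    graph = NaturalGraph(labels=list(matrix.labels))
    # current partition: list of member-index tuples, named by smallest label
    clusters: list[tuple[int, ...]] = [(i,) for i in range(len(matrix))]
    values = matrix.values
    for level in range(1, max_level + 1):
        if len(clusters) < 2:
            break
        names = [min(matrix.labels[i] for i in cl) for cl in clusters]
        # single-linkage distance between current clusters
        k = len(clusters)
        d = np.zeros((k, k))
        for a in range(k):
            for b in range(a + 1, k):
                block = values[np.ix_(clusters[a], clusters[b])]
                d[a, b] = d[b, a] = float(block.min())
        edges = _level_edges(names, d, level)
        graph.edges.extend(edges)
        g = nx.Graph()
        g.add_nodes_from(names)
        for e in edges:
            g.add_edge(e.source, e.target)
        name_to_idx = {name: i for i, name in enumerate(names)}
        merged = []
        for comp in nx.connected_components(g):
            members: list[int] = []
            for name in comp:
                members.extend(clusters[name_to_idx[name]])
            merged.append(tuple(sorted(members)))
        clusters = sorted(merged)
        graph.clusters.append(
            [tuple(sorted(matrix.labels[i] for i in cl)) for cl in clusters]
        )
    return graph


def natural_graph_tsv(graph: NaturalGraph) -> str:
    """Edge list as TSV: level, source, target, directed|bi, length."""
    lines = ["level\tsource\ttarget\tkind\tlength"]
    for e in graph.edges:
        kind = "bi" if e.bidirectional else "directed"
        lines.append(f"{e.level}\t{e.source}\t{e.target}\t{kind}\t{e.length:.12g}")
    return "\n".join(lines) + "\n"


def natural_graph_dot(graph: NaturalGraph) -> str:
    """Graphviz DOT rendering with level-annotated edges."""
    lines = ["digraph natural {"]
    for label in graph.labels:
        lines.append(f'    "{label}";')
    for e in graph.edges:
        attrs = f'label="L{e.level} {e.length:.4g}"'
        if e.bidirectional:
            attrs += ", dir=both"
        lines.append(f'    "{e.source}" -> "{e.target}" [{attrs}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
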