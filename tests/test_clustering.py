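import numpy as np
import pytest

from yauhausdorff import (
    DistanceMatrix,
    InputError,
    natural_graph,
    to_newick,
    topology_equal,
    upgma,
)
from yauhausdorff.clustering import (
    UpgmaTree,
    natural_graph_dot,
    natural_graph_tsv,
)


def matrix_of(labels, entries):
    n = len(labels)
    values = np.zeros((n, n))
    for (a, b), d in entries.items():
        i, j = labels.index(a), labels.index(b)
        values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=list(labels), values=values)


class TestUpgma:
    def test_two_leaf_halving(self):
        tree = upgma(matrix_of("XY", {("X", "Y"): 4.0}))
        assert tree.height == 2.0
        assert to_newick(tree) == "(X:2,Y:2);"

    def test_three_leaf_worked_example(self):
        m = matrix_of("ABC", {("A", "B"): 2.0, ("A", "C"): 6.0, ("B", "C"): 6.0})
        tree = upgma(m)
        assert to_newick(tree) == "((A:1,B:1):2,C:3);"

    def test_single_label_rejected(self):
        with pytest.raises(InputError):
            upgma(DistanceMatrix(labels=["only"], values=np.zeros((1, 1))))

    def test_tie_break_is_lexicographic(self):
        # all three pairs at distance 2: the (a, b) pair must merge first
        m = matrix_of(["c", "a", "b"], {("a", "b"): 2.0, ("a", "c"): 2.0, ("b", "c"): 2.0})
        assert to_newick(upgma(m)) == "((a:1,b:1):0,c:1);"

    def test_merge_heights_monotone_on_random_matrices(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            d = rng.uniform(0.5, 10, size=(n, n))
            d = np.triu(d, 1)
            d = d + d.T
            tree = upgma(DistanceMatrix(labels=[f"t{i}" for i in range(n)], values=d))
            for node in tree.walk():
                if not node.is_leaf:
                    assert all(c.height <= node.height + 1e-12 for c in node.children)

    def test_recovers_random_ultrametric_exactly(self):
        rng = np.random.default_rng(32)

        def random_tree(labels, lo, hi):
            if len(labels) == 1:
                return UpgmaTree(height=0.0, label=labels[0])
            height = float(rng.uniform(lo, hi))
            k = int(rng.integers(1, len(labels)))
            sub_hi = height * 0.95
            return UpgmaTree(
                height=height,
                children=(
                    random_tree(labels[:k], lo * 0.2, sub_hi),
                    random_tree(labels[k:], lo * 0.2, sub_hi),
                ),
            )

        def cophenetic(tree, dist):
            if tree.is_leaf:
                return
            left, right = (c.leaves() for c in tree.children)
            for a in left:
                for b in right:
                    dist[frozenset((a, b))] = 2 * tree.height
            for c in tree.children:
                cophenetic(c, dist)

        for _ in range(10):
            labels = [f"s{i}" for i in range(int(rng.integers(3, 8)))]
            truth = random_tree(labels, 2.0, 10.0)
            dist = {}
            cophenetic(truth, dist)
            n = len(labels)
            values = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    values[i, j] = values[j, i] = dist[frozenset((labels[i], labels[j]))]
            recovered = upgma(DistanceMatrix(labels=labels, values=values))
            assert topology_equal(truth, recovered)
            heights_t = sorted(nd.height for nd in truth.walk() if not nd.is_leaf)
            heights_r = sorted(nd.height for nd in recovered.walk() if not nd.is_leaf)
            np.testing.assert_allclose(heights_r, heights_t, atol=1e-9)

    def test_matches_scipy_average_linkage_heights(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(33)
        n = 7
        d = np.triu(rng.uniform(1, 10, size=(n, n)), 1)
        d = d + d.T
        tree = upgma(DistanceMatrix(labels=[f"t{i}" for i in range(n)], values=d))
        ours = sorted(2 * nd.height for nd in tree.walk() if not nd.is_leaf)
        scipys = sorted(linkage(squareform(d), method="average")[:, 2])
        np.testing.assert_allclose(ours, scipys, atol=1e-9)


class TestNewick:
    def test_label_quoting(self):
        tree = upgma(matrix_of(["sp one", "b"], {("sp one", "b"): 2.0}))
        assert to_newick(tree) == "(b:1,'sp one':1);"

    def test_parseable_by_dendropy_with_branch_lengths(self):
        import dendropy

        m = matrix_of("ABC", {("A", "B"): 2.0, ("A", "C"): 6.0, ("B", "C"): 6.0})
        newick = to_newick(upgma(m))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {"A", "B", "C"}
        # root-to-leaf path lengths all equal (ultrametric)
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        np.testing.assert_allclose(depths, 3.0)


class TestTopologyEqual:
    def test_reflexive_and_branch_length_blind(self):
        m1 = matrix_of("ABC", {("A", "B"): 2.0, ("A", "C"): 6.0, ("B", "C"): 6.0})
        m2 = matrix_of("ABC", {("A", "B"): 1.0, ("A", "C"): 9.0, ("B", "C"): 9.0})
        t1, t2 = upgma(m1), upgma(m2)
        assert topology_equal(t1, t1)
        assert topology_equal(t1, t2)

    def test_different_splits_detected(self):
        t_ab = upgma(matrix_of("ABC", {("A", "B"): 2.0, ("A", "C"): 6.0, ("B", "C"): 6.0}))
        t_ac = upgma(matrix_of("ABC", {("A", "C"): 2.0, ("A", "B"): 6.0, ("B", "C"): 6.0}))
        assert not topology_equal(t_ab, t_ac)

    def test_agrees_with_dendropy_rf_distance(self):
        import dendropy

        rng = np.random.default_rng(34)
        labels = [f"s{i}" for i in range(6)]
        trees = []
        for _ in range(4):
            d = np.triu(rng.uniform(1, 10, size=(6, 6)), 1)
            d = d + d.T
            trees.append(upgma(DistanceMatrix(labels=labels, values=d)))
        taxa = dendropy.TaxonNamespace()
        for i in range(len(trees)):
            for j in range(i, len(trees)):
                ours = topology_equal(trees[i], trees[j])
                di = dendropy.Tree.get(data=to_newick(trees[i]), schema="newick", taxon_namespace=taxa)
                dj = dendropy.Tree.get(data=to_newick(trees[j]), schema="newick", taxon_namespace=taxa)
                di.encode_bipartitions()
                dj.encode_bipartitions()
                rf = dendropy.calculate.treecompare.symmetric_difference(di, dj)
                assert ours == (rf == 0)

    def test_differing_leaf_sets_rejected(self):
        t1 = upgma(matrix_of("AB", {("A", "B"): 2.0}))
        t2 = upgma(matrix_of("AC", {("A", "C"): 2.0}))
        with pytest.raises(InputError):
            topology_equal(t1, t2)


class TestNaturalGraph:
    def test_two_nodes_single_bidirectional_edge(self):
        g = natural_graph(matrix_of("AB", {("A", "B"): 3.0}))
        assert len(g.edges) == 1
        e = g.edges[0]
        assert (e.level, e.source, e.target, e.bidirectional, e.length) == (1, "A", "B", True, 3.0)
        assert g.clusters[0] == [("A", "B")]

    def test_two_tight_pairs_bridged_at_level_two(self):
        entries = {("A", "B"): 1.0, ("C", "D"): 1.0}
        for x in "AB":
            for y in "CD":
                entries[(x, y)] = 5.0
        g = natural_graph(matrix_of("ABCD", entries))
        level1 = [e for e in g.edges if e.level == 1]
        level2 = [e for e in g.edges if e.level == 2]
        assert g.clusters[0] == [("A", "B"), ("C", "D")]
        assert len(level1) == 2 and all(e.bidirectional for e in level1)
        assert len(level2) == 1
        assert (level2[0].source, level2[0].target, level2[0].bidirectional) == ("A", "C", True)
        assert level2[0].length == 5.0
        assert g.clusters[1] == [("A", "B", "C", "D")]

    def test_chain_forms_single_component(self):
        g = natural_graph(matrix_of("ABC", {("A", "B"): 1.0, ("B", "C"): 2.0, ("A", "C"): 4.0}))
        by_pair = {(e.source, e.target): e for e in g.edges}
        assert by_pair[("A", "B")].bidirectional  # mutual nearest
        assert ("C", "B") in by_pair and not by_pair[("C", "B")].bidirectional
        assert g.clusters[0] == [("A", "B", "C")]

    def test_level1_edge_lengths_are_row_minima(self):
        rng = np.random.default_rng(35)
        n = 6
        d = np.triu(rng.uniform(1, 10, size=(n, n)), 1)
        d = d + d.T
        labels = [f"t{i}" for i in range(n)]
        g = natural_graph(DistanceMatrix(labels=labels, values=d))
        row_min = {labels[i]: np.min(d[i][d[i] > 0]) for i in range(n)}
        for e in g.edges:
            if e.level == 1:
                assert e.length == pytest.approx(row_min[e.source])
                if e.bidirectional:
                    assert e.length == pytest.approx(row_min[e.target])

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(36)
        n = 5
        d = np.triu(rng.uniform(1, 10, size=(n, n)), 1)
        d = d + d.T
        labels = [f"t{i}" for i in range(n)]
        g1 = natural_graph(DistanceMatrix(labels=labels, values=d))
        perm = rng.permutation(n)
        g2 = natural_graph(
            DistanceMatrix(labels=[labels[i] for i in perm], values=d[np.ix_(perm, perm)])
        )
        as_set = lambda g: {(e.level, e.source, e.target, e.bidirectional, round(e.length, 9)) for e in g.edges}
        assert as_set(g1) == as_set(g2)

    def test_exports_contain_every_edge(self):
        g = natural_graph(matrix_of("ABC", {("A", "B"): 1.0, ("B", "C"): 2.0, ("A", "C"): 4.0}))
        tsv = natural_graph_tsv(g)
        dot = natural_graph_dot(g)
        assert tsv.splitlines()[0] == "level\tsource\ttarget\tkind\tlength"
        assert len(tsv.strip().splitlines()) == 1 + len(g.edges)
        assert dot.startswith("digraph") and '"A" -> "B"' in dot

    def test_invalid_matrix_rejected(self):
        with pytest.raises(InputError):
            natural_graph(DistanceMatrix(labels=["x"], values=np.zeros((1, 1))))
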