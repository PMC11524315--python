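"""Distances, NJ topology recovery, bootstrap and family classification.

The NJ cross-check uses scikit-bio's independent implementation; the
classification oracle re-derives clades from an adjacency graph built
directly from the generating topology, bypassing the tree object.
"""

import itertools
import math

import numpy as np
import pytest

from monolignol.phylogeny import (
    MSA,
    bipartitions,
    bootstrap_support,
    classify_family,
    nj_tree,
    pairwise_distance,
)

# ---------------------------------------------------------------------------
# random-tree machinery


def random_topology(rng, leaves):
    """Random unrooted binary tree as nested tuples (rooted arbitrarily)."""
    nodes = [leaf for leaf in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]


def additive_matrix(rng, topo, leaves):
    """Leaf-to-leaf path-length matrix with random positive branch lengths."""
    parent = {}
    lengths = {}
    counter = itertools.count()

    def build(node):
        name = f"internal{next(counter)}" if isinstance(node, tuple) else node
        if isinstance(node, tuple):
            for child in node:
                cname = build(child)
                parent[cname] = name
                lengths[cname] = float(rng.uniform(0.1, 1.0))
        return name

    root = build(topo)

    def path_to_root(leaf):
        out = {}
        node, dist = leaf, 0.0
        while node != root:
            out[node] = dist
            dist += lengths[node]
            node = parent[node]
        out[root] = dist
        return out

    n = len(leaves)
    d = np.zeros((n, n))
    paths = {leaf: path_to_root(leaf) for leaf in leaves}
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            if i < j:
                shared = set(paths[a]) & set(paths[b])
                lca_dist = min(paths[a][s] + paths[b][s] for s in shared)
                d[i, j] = d[j, i] = lca_dist
    return d


def topo_bipartitions(topo, leaves):
    """Nontrivial splits of the nested-tuple topology, canonicalized the
    same way as monolignol.phylogeny.bipartitions."""
    all_leaves = frozenset(leaves)
    ref = min(all_leaves)
    splits = set()

    def walk(node):
        if not isinstance(node, tuple):
            return frozenset([node])
        below = frozenset().union(*(walk(c) for c in node))
        side = all_leaves - below if ref in below else below
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(side)
        return below

    walk(topo)
    return splits


# ---------------------------------------------------------------------------
# distances


class TestPairwiseDistance:
    def test_identical_rows_zero(self):
        msa = MSA(ids=["a", "b"], rows=["ACGT", "ACGT"])
        assert pairwise_distance(msa)[0, 1] == 0.0

    def test_poisson_closed_form(self):
        # p = 0.5 -> d = -ln(1 - 0.5) = ln 2
        msa = MSA(ids=["a", "b"], rows=["AAAA", "AACC"])
        assert pairwise_distance(msa, "p")[0, 1] == pytest.approx(0.5)
        assert pairwise_distance(msa, "poisson")[0, 1] == pytest.approx(math.log(2))

    def test_pairwise_deletion_hand_count(self):
        # comparable sites 3 (gap column dropped per pair), one mismatch
        msa = MSA(ids=["a", "b"], rows=["AC-T", "AG-T"])
        assert pairwise_distance(msa, "p")[0, 1] == pytest.approx(1 / 3)

    def test_saturated_pair_rejected(self):
        msa = MSA(ids=["a", "b"], rows=["AAAA", "CCCC"])
        with pytest.raises(ValueError, match="a.*b"):
            pairwise_distance(msa, "poisson")

    def test_no_comparable_sites_rejected(self):
        msa = MSA(ids=["a", "b"], rows=["A--A", "-CC-"])
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distance(msa)

    def test_poisson_first_order_agreement_at_low_divergence(self):
        for p in (0.001, 0.005, 0.01):
            d = -math.log1p(-p)
            assert abs(d - p) / p < 0.01


class TestNJ:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(d, ["a", "b", "c"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_four_taxon_split_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> split AB|CD
        d = np.array(
            [
                [0, 3, 5, 3],
                [3, 0, 6, 4],
                [5, 6, 0, 4],
                [3, 4, 4, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(d, ["A", "B", "C", "D"])
        assert bipartitions(tree) == {frozenset({"C", "D"})}

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(np.array([[0, 1.0], [2.0, 0]]), ["a", "b"])
        bad = np.zeros((3, 3))
        bad[0, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            nj_tree(bad, ["a", "b", "c"])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_additive_topology_recovery(self, seed):
        """NJ recovers the generating unrooted topology for additive
        matrices from random trees (n <= 10), and agrees with scikit-bio's
        independent NJ."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(seed)
        for _ in range(50):
            n = int(rng.integers(4, 11))
            leaves = [f"t{k}" for k in range(n)]
            topo = random_topology(rng, leaves)
            d = additive_matrix(rng, topo, leaves)
            tree = nj_tree(d, leaves)
            assert bipartitions(tree) == topo_bipartitions(topo, leaves)
            # same unrooted splits as the independent implementation
            ref_tree = skbio_nj(DistanceMatrix(d, leaves))
            assert bipartitions(tree) == bipartitions(ref_tree)


class TestBootstrap:
    def _two_block_msa(self, n_cols=500):
        # two clean groups diverged at 40% of sites -> one certain split
        n_diff = int(0.4 * n_cols)
        base_a = "A" * n_cols
        base_b = "C" * n_diff + "A" * (n_cols - n_diff)
        return MSA(
            ids=["a1", "a2", "b1", "b2"],
            rows=[
                base_a,
                "G" + base_a[1:],
                base_b,
                base_b[:-1] + "T",
            ],
        )

    def test_clean_split_gets_full_support(self):
        msa = self._two_block_msa()
        _tree, support = bootstrap_support(msa, n_reps=100, seed=0)
        assert support[frozenset({"b1", "b2"})] == 100.0

    def test_single_replicate_support_is_binary(self):
        msa = self._two_block_msa(50)
        _tree, support = bootstrap_support(msa, n_reps=1, seed=3)
        assert set(support.values()) <= {0.0, 100.0}

    def test_same_seed_same_supports(self):
        msa = self._two_block_msa(100)
        s1 = bootstrap_support(msa, n_reps=25, seed=9)[1]
        s2 = bootstrap_support(msa, n_reps=25, seed=9)[1]
        assert s1 == s2

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._two_block_msa(20), n_reps=0, seed=0)


# ---------------------------------------------------------------------------
# classification


def classify_oracle(topo, leaves, group_of):
    """Brute-force class call from an adjacency graph of the topology."""
    import networkx as nx

    g = nx.Graph()
    counter = itertools.count()

    def build(node):
        if not isinstance(node, tuple):
            return node
        name = f"v{next(counter)}"
        for child in node:
            g.add_edge(name, build(child))
        return name

    build(topo)
    groups = {}
    for leaf in leaves:
        groups.setdefault(group_of[leaf], set()).add(leaf)
    leafset = set(leaves)

    def components_without(vertex):
        h = g.copy()
        h.remove_node(vertex)
        return [set(c) & leafset for c in nx.connected_components(h)]

    if set(groups) == {"monocot", "herb_dicot", "woody"}:
        for v in list(g.nodes):
            if v in leafset:
                continue
            comps = [c for c in components_without(v) if c]
            if len(comps) == 3 and {frozenset(c) for c in comps} == {
                frozenset(s) for s in groups.values()
            }:
                return "Ib"
    mono = groups.get("monocot", set())
    if mono and mono != leafset:
        for a, b in list(g.edges):
            h = g.copy()
            h.remove_edge(a, b)
            import networkx as nx2

            sides = [set(c) & leafset for c in nx2.connected_components(h)]
            if mono in sides:
                return "Ia"
    return "II"


def tuples_to_treenode(topo):
    from skbio import TreeNode

    def newick(node):
        if not isinstance(node, tuple):
            return node
        return "(" + ",".join(newick(c) for c in node) + ")"

    return TreeNode.read([newick(topo) + ";"])


class TestClassifyFamily:
    GROUPS = {"m1": "monocot", "m2": "monocot", "h1": "herb_dicot",
              "h2": "herb_dicot", "w1": "woody", "w2": "woody", "w3": "woody"}

    def test_monocots_on_one_side_is_class_Ia(self):
        topo = (("m1", "m2"), ("h1", (("w1", "h2"), ("w2", "w3"))))
        tree = tuples_to_treenode(topo)
        assert classify_family(tree, self.GROUPS) == "Ia"

    def test_three_group_vertex_is_class_Ib(self):
        topo = (("m1", "m2"), (("h1", "h2"), ("w1", ("w2", "w3"))))
        tree = tuples_to_treenode(topo)
        assert classify_family(tree, self.GROUPS) == "Ib"

    def test_interleaved_caterpillar_is_class_II(self):
        topo = ("m1", ("h1", ("w1", ("m2", ("h2", ("w2", "w3"))))))
        tree = tuples_to_treenode(topo)
        assert classify_family(tree, self.GROUPS) == "II"

    def test_missing_label_rejected(self):
        tree = tuples_to_treenode((("m1", "m2"), ("h1", "w1")))
        with pytest.raises(ValueError, match="x1|w1"):
            classify_family(tree, {"m1": "monocot", "m2": "monocot",
                                   "h1": "herb_dicot"})

    def test_agrees_with_graph_oracle_on_random_trees(self):
        """Classification equals the brute-force component-enumeration
        oracle on random labeled topologies with <= 12 leaves."""
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(4, 13))
            leaves = [f"t{k}" for k in range(n)]
            group_of = {
                leaf: ("monocot", "herb_dicot", "woody")[int(rng.integers(3))]
                for leaf in leaves
            }
            topo = random_topology(rng, leaves)
            tree = tuples_to_treenode(topo)
            assert classify_family(tree, group_of) == classify_oracle(
                topo, leaves, group_of
            )

    def test_invariant_to_rerooting_and_leaf_order(self):
        rng = np.random.default_rng(13)
        leaves = list(self.GROUPS)
        for _ in range(20):
            topo = random_topology(rng, leaves)
            tree = tuples_to_treenode(topo)
            expected = classify_family(tree, self.GROUPS)
            for tip_name in ("m1", "w3"):
                rerooted = tree.copy()
                tip = rerooted.find(tip_name)
                assert classify_family(
                    rerooted.root_at(tip.parent), self.GROUPS
                ) == expected
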