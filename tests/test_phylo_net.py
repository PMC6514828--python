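"""Collapse/filter rules, NJ correctness on additive matrices, bootstrap
consensus behaviour and the minimum-spanning network."""

import numpy as np
import pytest

from fadsevo.phylo_net import (
    CollapsedHaplotypes,
    DifferenceMatrix,
    build_network,
    bootstrap_consensus,
    clade_support,
    collapse_and_filter,
    nj_tree,
    pairwise_differences,
)


# --- independent oracle: random additive trees and their exact distances ---


def random_additive_tree(rng, n_taxa):
    """Random unrooted binary tree with integer branch lengths 1..6,
    returned as (taxon names, exact leaf-to-leaf path-length matrix)."""
    # adjacency with edge weights; start from a 3-star, attach leaves to edges
    adj = {0: {}, 1: {}, 2: {}, 3: {}}
    next_node = 4
    for leaf, hub in ((0, 3), (1, 3), (2, 3)):
        w = int(rng.integers(1, 7))
        adj[leaf][hub] = w
        adj[hub][leaf] = w
    leaves = [0, 1, 2]
    while len(leaves) < n_taxa:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w_uv = adj[u].pop(v)
        adj[v].pop(u)
        mid, leaf = next_node, next_node + 1
        next_node += 2
        adj[mid] = {}
        adj[leaf] = {}
        split = int(rng.integers(1, w_uv + 1)) if w_uv > 1 else 1
        for a, b, w in (
            (u, mid, split),
            (mid, v, max(w_uv - split, 1)),
            (mid, leaf, int(rng.integers(1, 7))),
        ):
            adj[a][b] = w
            adj[b][a] = w
        leaves.append(leaf)
    # exact path lengths by BFS over the weighted tree
    dist = np.zeros((len(leaves), len(leaves)))
    for i, src in enumerate(leaves):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in seen:
                    seen[y] = seen[x] + w
                    stack.append(y)
        for j, dst in enumerate(leaves):
            dist[i, j] = seen[dst]
    names = [f"T{k}" for k in range(len(leaves))]
    return names, dist


def tree_path_matrix(tree, names):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(taxa[names[i]], taxa[names[j]])
    return out


class TestCollapse:
    def test_count_filter_with_protected_exception(self):
        ids = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(3)] + ["DEN1"]
        seqs = ["AAA"] * 5 + ["AAT"] * 3 + ["ATT"]
        col = collapse_and_filter(ids, seqs, min_count_exclusive=3, keep_ids=("DEN1",))
        assert col.sequences == ["AAA", "ATT"]
        assert "DEN1" in col.ids  # protected singleton keeps its name

    def test_boundary_count_four_is_retained(self):
        col = collapse_and_filter([f"x{i}" for i in range(4)], ["AAA"] * 4)
        assert col.counts == [4]

    def test_all_identical_collapse_to_one_node(self):
        col = collapse_and_filter([f"x{i}" for i in range(6)], ["ACG"] * 6)
        assert len(col) == 1 and col.counts == [6]

    def test_multiplicities_sum_to_input_before_filtering(self):
        ids = [f"x{i}" for i in range(7)]
        seqs = ["AAA"] * 4 + ["AAT"] * 2 + ["ATT"]
        col = collapse_and_filter(ids, seqs, min_count_exclusive=0)
        assert sum(col.counts) == 7

    def test_everything_filtered_is_an_error(self):
        with pytest.raises(ValueError, match="nothing retained"):
            collapse_and_filter(["a", "b"], ["AAA", "AAT"], min_count_exclusive=3)


class TestDifferences:
    @pytest.mark.parametrize(
        "a,b,expected", [("AAA", "ATA", 1), ("AAA", "AAA", 0), ("AAA", "TTT", 3)]
    )
    def test_hamming_counts(self, a, b, expected):
        col = collapse_and_filter(["x", "y"], [a, b], min_count_exclusive=0)
        dm = pairwise_differences(col)
        if a == b:
            assert len(col) == 1
        else:
            assert dm.matrix[0, 1] == expected

    def test_missing_bases_skipped_pairwise(self):
        col = collapse_and_filter(["x", "y"], ["ANT", "AGA"], min_count_exclusive=0)
        dm = pairwise_differences(col)
        assert dm.matrix[0, 1] == 1  # only the third site is comparable and differs

    def test_matrix_is_symmetric_with_zero_diagonal(self):
        col = collapse_and_filter(list("abc"), ["AAT", "ATT", "TTT"], min_count_exclusive=0)
        m = pairwise_differences(col).matrix
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)


class TestNeighborJoining:
    def test_recovers_random_additive_trees_exactly(self):
        """NJ is exact on additive matrices: topology and branch lengths
        reproduce the generating tree (checked via path-length identity)."""
        rng = np.random.default_rng(17)
        for _ in range(12):
            n_taxa = int(rng.integers(4, 9))
            names, dist = random_additive_tree(rng, n_taxa)
            tree = nj_tree(DifferenceMatrix(names, dist), outgroup=names[0])
            assert np.allclose(tree_path_matrix(tree, names), dist)

    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 3, 5], [3, 0, 6], [5, 6, 0]])
        tree = nj_tree(DifferenceMatrix(["a", "b", "c"], d), outgroup="a")
        assert np.allclose(tree_path_matrix(tree, ["a", "b", "c"]), d)

    def test_zero_matrix_gives_zero_length_star(self):
        d = np.zeros((4, 4))
        tree = nj_tree(DifferenceMatrix(list("abcd"), d), outgroup="a")
        assert tree.length() == 0.0

    def test_missing_outgroup_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(KeyError):
            nj_tree(DifferenceMatrix(list("abc"), d), outgroup="zz")


def two_clade_collapsed(n_per_clade=5, n_sep=20, length=200, seed=0):
    rng = np.random.default_rng(seed)
    anc = np.array(list("ACGT" * (length // 4)))
    c1 = anc.copy()
    c1[:n_sep] = "T"
    c2 = anc.copy()
    c2[2 * n_sep: 3 * n_sep] = "A"
    ids, seqs = ["OUT"], ["".join(anc)]
    for i in range(n_per_clade):
        s = c1.copy()
        s[100 + i] = "G"
        ids.append(f"x{i}")
        seqs.append("".join(s))
    for i in range(n_per_clade):
        s = c2.copy()
        s[150 + i] = "C"
        ids.append(f"y{i}")
        seqs.append("".join(s))
    return collapse_and_filter(ids, seqs, min_count_exclusive=0, keep_ids=("OUT",))


class TestBootstrap:
    def test_clean_clades_get_full_support(self):
        col = two_clade_collapsed()
        consensus, full = bootstrap_consensus(col, "OUT", replicates=100, seed=1)
        clade1 = {f"H{i}" for i in range(1, 6)}
        clade2 = {f"H{i}" for i in range(6, 11)}
        assert clade_support(full, clade1) == 100.0
        assert clade_support(full, clade2) == 100.0

    def test_single_replicate_consensus_has_full_support(self):
        col = two_clade_collapsed()
        consensus, _ = bootstrap_consensus(col, "OUT", replicates=1, seed=2)
        sups = [nd.support for nd in consensus.preorder_internal_node_iter()
                if getattr(nd, "support", None) is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_same_seed_reproduces_supports(self):
        col = two_clade_collapsed()
        _, f1 = bootstrap_consensus(col, "OUT", replicates=30, seed=5)
        _, f2 = bootstrap_consensus(col, "OUT", replicates=30, seed=5)
        s1 = sorted(nd.support for nd in f1.preorder_internal_node_iter())
        s2 = sorted(nd.support for nd in f2.preorder_internal_node_iter())
        assert s1 == s2

    def test_supports_invariant_to_haplotype_input_order(self):
        rng = np.random.default_rng(3)
        col = two_clade_collapsed()
        perm = rng.permutation(len(col.ids))
        shuffled = CollapsedHaplotypes(
            [col.ids[i] for i in perm],
            [col.sequences[i] for i in perm],
            [col.counts[i] for i in perm],
            col.members,
            col.categories,
        )
        _, full_a = bootstrap_consensus(col, "OUT", replicates=50, seed=7)
        _, full_b = bootstrap_consensus(shuffled, "OUT", replicates=50, seed=8)
        # the two defining clades are fully supported regardless of order
        for full, c in ((full_a, col), (full_b, shuffled)):
            for prefix in ("x", "y"):
                clade = {hid for hid, mem in c.members.items() if mem[0].startswith(prefix)}
                assert clade_support(full, clade) == 100.0

    def test_zero_variant_columns_does_not_crash(self):
        col = collapse_and_filter(
            list("abc"), ["AAA", "AAN", "ANA"],
            min_count_exclusive=0, keep_ids=("a", "b", "c"),
        )
        consensus, _ = bootstrap_consensus(col, "a", replicates=5, seed=0)
        assert len(consensus.leaf_nodes()) == 3


class TestNetwork:
    def test_chain_of_single_mutations(self):
        col = collapse_and_filter(
            ["a"] * 5 + ["b"] * 4 + ["c"] * 4,
            ["AAA"] * 5 + ["AAT"] * 4 + ["ATT"] * 4,
        )
        net = build_network(col)
        edges = {tuple(sorted(e)): d["mutations"] for *e, d in net.edges(data=True)}
        assert edges == {("H1", "H2"): 1, ("H2", "H3"): 1}

    def test_two_haplotypes_single_edge(self):
        col = collapse_and_filter(["a"] * 4, ["AAAA"] * 4, min_count_exclusive=0)
        col2 = collapse_and_filter(
            ["a"] * 4 + ["b"] * 4, ["AAAA"] * 4 + ["ATTA"] * 4
        )
        net = build_network(col2)
        assert net.number_of_edges() == 1
        assert list(net.edges(data=True))[0][2]["mutations"] == 2

    def test_equidistant_ties_all_retained(self):
        col = collapse_and_filter(
            ["a"] * 4 + ["b"] * 4 + ["c"] * 4 + ["d"] * 4,
            ["AA"] * 4 + ["GG"] * 4 + ["CT"] * 4 + ["TC"] * 4,
        )
        net = build_network(col)
        assert net.number_of_edges() == 6  # complete graph of tie links

    def test_edge_labels_equal_hamming_distance(self):
        col = two_clade_collapsed()
        dm = pairwise_differences(col)
        net = build_network(col)
        for u, v, data in net.edges(data=True):
            assert data["mutations"] == dm.matrix[dm.index(u), dm.index(v)]

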