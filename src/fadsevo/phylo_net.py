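"""Haplotype collapsing, pairwise-difference matrices, neighbor-joining
trees with bootstrap consensus, and minimum-spanning haplotype networks.

Workflow: identical sequences are collapsed into unique haplotypes with
multiplicities, rare haplotypes (count <= 3 by default) are removed unless
protected (archaic haplotypes and the ancestor/outgroup), pairwise Hamming
differences are computed over mutually non-missing positions, and the
matrix feeds either a Saitou–Nei neighbor-joining tree (bootstrapped by
resampling alignment columns with replacement, summarised as a
majority-rule consensus) or a minimum-spanning network whose edges are
labelled with mutation counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import dendropy
import networkx as nx
import numpy as np

__all__ = [
    "CollapsedHaplotypes",
    "DifferenceMatrix",
    "collapse_and_filter",
    "pairwise_differences",
    "nj_tree",
    "bootstrap_consensus",
    "build_network",
]

MISSING = "N"


@dataclass
class CollapsedHaplotypes:
    """Unique sequences with multiplicities and member bookkeeping."""

    ids: list[str]  # one id per unique retained haplotype (H1, H2, ...)
    sequences: list[str]
    counts: list[int]
    members: dict[str, list[str]]  # unique id -> original haplotype ids
    categories: dict[str, Counter] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ids)

    def matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences], dtype="<U1")


def collapse_and_filter(
    haplotype_ids: list[str],
    sequences: list[str],
    min_count_exclusive: int = 3,
    keep_ids: tuple[str, ...] | list[str] = (),
    categories: list[str] | None = None,
) -> CollapsedHaplotypes:
    """Collapse identical sequences, then drop haplotypes whose multiplicity
    is ``<= min_count_exclusive`` unless a member id is protected.

    Unique haplotypes keep their first-occurrence order and are named H1,
    H2, ... — except that a unique haplotype consisting solely of protected
    members keeps its (first) original id, so outgroup/archaic labels
    survive into trees and networks.  Raises if everything is filtered out.
    """
    if len(haplotype_ids) != len(sequences):
        raise ValueError("ids and sequences must align")
    if not sequences:
        raise ValueError("no haplotypes supplied")
    keep = set(keep_ids)
    order: dict[str, int] = {}
    members: list[list[str]] = []
    cats: list[Counter] = []
    for k, (hid, seq) in enumerate(zip(haplotype_ids, sequences)):
        if seq not in order:
            order[seq] = len(members)
            members.append([])
            cats.append(Counter())
        idx = order[seq]
        members[idx].append(hid)
        if categories is not None:
            cats[idx][categories[k]] += 1

    uniq_seqs = list(order)
    retained = [
        i
        for i, seq in enumerate(uniq_seqs)
        if len(members[i]) > min_count_exclusive or keep.intersection(members[i])
    ]
    if not retained:
        raise ValueError(
            f"all haplotypes have count <= {min_count_exclusive}; nothing retained"
        )
    ids, seqs, counts, mem, cat = [], [], [], {}, {}
    rank = 0
    for i in retained:
        protected_only = keep.issuperset(members[i]) and bool(keep.intersection(members[i]))
        if protected_only:
            name = members[i][0]
        else:
            rank += 1
            name = f"H{rank}"
        ids.append(name)
        seqs.append(uniq_seqs[i])
        counts.append(len(members[i]))
        mem[name] = members[i]
        cat[name] = cats[i]
    return CollapsedHaplotypes(ids, seqs, counts, mem, cat)


@dataclass
class DifferenceMatrix:
    """Symmetric matrix of pairwise Hamming differences."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match ids")

    def index(self, hid: str) -> int:
        try:
            return self.ids.index(hid)
        except ValueError:
            raise KeyError(f"haplotype {hid!r} not in matrix") from None


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    ok = (a != MISSING) & (b != MISSING)
    return int(((a != b) & ok).sum())


def pairwise_differences(collapsed: CollapsedHaplotypes) -> DifferenceMatrix:
    """Hamming counts over mutually non-missing positions, per pair."""
    mat = collapsed.matrix()
    if mat.ndim != 2:
        raise ValueError("sequences must share one length")
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _hamming(mat[i], mat[j])
    return DifferenceMatrix(list(collapsed.ids), d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _clamped_lengths(li: float, lj: float) -> tuple[float, float]:
    # negative branch lengths set to zero, deficit moved to the sibling edge
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(dm: DifferenceMatrix, outgroup: str) -> dendropy.Tree:
    """Saitou–Nei neighbor joining, rooted on the outgroup's edge.

    Ties in the Q criterion are broken by the lowest index pair for
    reproducibility.  Negative branch lengths are clamped to zero with the
    deficit moved to the sibling edge.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need >= 3 haplotypes for a neighbor-joining tree")
    og_index = dm.index(outgroup)  # raises KeyError if absent
    tns = dendropy.TaxonNamespace(dm.ids)
    nodes = []
    for hid in dm.ids:
        node = dendropy.Node(taxon=tns.get_taxon(hid))
        nodes.append(node)
    d = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie break: argmin of flattened array scans row-major
        flat = np.argmin(q)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamped_lengths(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[active[i]])
        nodes[active[i]].edge.length = li
        parent.add_child(nodes[active[j]])
        nodes[active[j]].edge.length = lj
        # distances from the new node to the remaining clusters
        gi, gj = active[i], active[j]
        new_idx = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (gi, gj):
                continue
            dk = (d[gi, k] + d[gj, k] - dij) / 2.0
            d[new_idx, k] = d[k, new_idx] = dk
        active = [k for k in active if k not in (gi, gj)] + [new_idx]

    # final join: split the remaining edge at its midpoint
    a, b = active
    root = dendropy.Node()
    root.add_child(nodes[a])
    nodes[a].edge.length = d[a, b] / 2.0
    root.add_child(nodes[b])
    nodes[b].edge.length = d[a, b] / 2.0
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root

    og_node = tree.find_node_with_taxon_label(outgroup)
    og_len = og_node.edge.length or 0.0
    tree.reroot_at_edge(
        og_node.edge, length1=og_len / 2.0, length2=og_len / 2.0, update_bipartitions=True
    )
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# bootstrap consensus
# ---------------------------------------------------------------------------


def _pattern_difference_components(mat: np.ndarray):
    """Group alignment columns into unique patterns.

    Returns (per-pattern pairwise 0/1 difference matrices, column->pattern
    index), so a column-resampled difference matrix is a weighted sum of a
    few small matrices instead of a full Hamming recount.
    """
    n, L = mat.shape
    _, pattern_idx, _ = np.unique(mat, axis=1, return_inverse=True, return_counts=True)
    n_pat = pattern_idx.max() + 1
    comps = np.zeros((n_pat, n, n))
    first_col = {}
    for c in range(L):
        p = pattern_idx[c]
        if p not in first_col:
            first_col[p] = c
    for p, c in first_col.items():
        col = mat[:, c]
        ok = col != MISSING
        diff = (col[:, None] != col[None, :]) & ok[:, None] & ok[None, :]
        comps[p] = diff
    return comps, pattern_idx


def bootstrap_consensus(
    collapsed: CollapsedHaplotypes,
    outgroup: str,
    replicates: int = 500,
    seed: int = 0,
    min_freq: float = 0.5,
) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Majority-rule bootstrap consensus of NJ trees.

    Each replicate resamples alignment columns (including invariant ones)
    with replacement, recomputes the difference matrix and its NJ tree.
    Returns ``(consensus, full_tree)``: the consensus carries clade support
    as percentages (``node.support``); the full-data NJ tree carries the
    same supports on its internal nodes plus its own branch lengths.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    mat = collapsed.matrix()
    L = mat.shape[1]
    full_dm = pairwise_differences(collapsed)
    full_tree = nj_tree(full_dm, outgroup)
    tns = full_tree.taxon_namespace

    comps, pattern_idx = _pattern_difference_components(mat)
    n_pat = comps.shape[0]
    rng = np.random.default_rng(seed)
    trees = dendropy.TreeList(taxon_namespace=tns)
    clade_counts: Counter = Counter()
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        weights = np.bincount(pattern_idx[cols], minlength=n_pat).astype(float)
        d = np.tensordot(weights, comps, axes=1)
        rep_tree = nj_tree(DifferenceMatrix(list(collapsed.ids), d), outgroup)
        for node in rep_tree.preorder_internal_node_iter():
            clade_counts[frozenset(lf.taxon.label for lf in node.leaf_iter())] += 1
        trees.append(rep_tree)

    consensus = trees.consensus(min_freq=min_freq, support_as_percentages=True)
    consensus.is_rooted = True

    # annotate the full-data tree's clades with bootstrap support
    for node in full_tree.preorder_internal_node_iter():
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        node.support = 100.0 * clade_counts[leaves] / replicates
    return consensus, full_tree


def clade_support(tree: dendropy.Tree, taxa: set[str]) -> float | None:
    """Support (percent) of the clade containing exactly ``taxa``, or None."""
    for node in tree.preorder_internal_node_iter():
        leaves = {lf.taxon.label for lf in node.leaf_iter()}
        if leaves == taxa:
            return getattr(node, "support", None)
    return None


# ---------------------------------------------------------------------------
# minimum-spanning haplotype network
# ---------------------------------------------------------------------------


def build_network(collapsed: CollapsedHaplotypes) -> nx.Graph:
    """Minimum-spanning network on Hamming distances.

    All minimum-spanning-tree edges are kept, plus every non-tree pair
    whose direct distance equals the bottleneck (maximum) edge weight on
    their MST path — alternative links tied with the tree route.  Edge
    attribute ``mutations`` is the Hamming distance; node attributes carry
    multiplicity and category composition.
    """
    if len(collapsed) < 2:
        raise ValueError("need >= 2 retained haplotypes for a network")
    dm = pairwise_differences(collapsed)
    complete = nx.Graph()
    for i, a in enumerate(collapsed.ids):
        complete.add_node(
            a,
            count=collapsed.counts[i],
            categories=dict(collapsed.categories.get(a, {})),
        )
    for i in range(len(collapsed)):
        for j in range(i + 1, len(collapsed)):
            complete.add_edge(
                collapsed.ids[i], collapsed.ids[j], weight=float(dm.matrix[i, j])
            )
    mst = nx.minimum_spanning_tree(complete, weight="weight")
    net = nx.Graph()
    net.add_nodes_from(complete.nodes(data=True))
    for u, v, data in mst.edges(data=True):
        net.add_edge(u, v, mutations=int(data["weight"]))
    # bottleneck distances along the MST
    for u, v, data in complete.edges(data=True):
        if net.has_edge(u, v):
            continue
        path = nx.shortest_path(mst, u, v)
        bottleneck = max(
            mst.edges[a, b]["weight"] for a, b in zip(path, path[1:])
        )
        if data["weight"] == bottleneck:
            net.add_edge(u, v, mutations=int(data["weight"]))
    return net
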