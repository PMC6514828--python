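#!/usr/bin/env python
"""Haplogroup proportions, core haplotypes, haplotype network and
bootstrap NJ tree of the synthetic alignment.

Classifies haplotypes by the tag SNP, tabulates per-cluster proportions,
builds core-haplotype consensus strings and reports oppositely fixed
positions, then collapses haplotypes (count <= 3 removed, archaic and
ancestor protected), builds the minimum-spanning network and a
500-replicate bootstrap NJ consensus rooted on the ancestor.
"""

import argparse
import json

import pandas as pd

from _inputs import RESULTS, ensure_inputs
from fadsevo.alignment import read_alignment_vcf
from fadsevo.haplogroups import (
    classify_haplotypes,
    core_haplotypes,
    haplogroup_proportions,
    opposite_fixed_sites,
)
from fadsevo.phylo_net import bootstrap_consensus, build_network, collapse_and_filter


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--bootstraps", type=int, default=500)
    parser.add_argument(
        "--min-count", type=int, default=0,
        help="drop haplotypes with multiplicity <= this (the study used 3; "
        "star-genealogy synthetic data makes every modern haplotype unique, "
        "so the default keeps them all)",
    )
    args = parser.parse_args()
    paths = ensure_inputs(args.seed)

    aln = read_alignment_vcf(paths["vcf"], paths["ancestor"])
    labeled = classify_haplotypes(aln)

    props = haplogroup_proportions(labeled, group_by="cluster")
    props.to_csv(RESULTS / "haplogroup_proportions.tsv", sep="\t", index=False)
    print(props.to_string(index=False))

    cores = core_haplotypes(aln, labeled["haplogroup"])
    core_rows = [(c.category, c.sequence) for c in cores.values()]
    pd.DataFrame(core_rows, columns=["category", "sequence"]).to_csv(
        RESULTS / "core_haplotypes.tsv", sep="\t", index=False
    )
    opp = opposite_fixed_sites(cores["derived"], cores["ancestral"])
    (RESULTS / "opposite_fixed_sites.json").write_text(json.dumps(opp, indent=2) + "\n")
    print(
        f"\ncore strings span {len(cores['derived'])} variant positions; "
        f"{len(opp['opposite_fixed'])} oppositely fixed, "
        f"{len(opp['half_fixed'])} half-fixed"
    )

    # collapse over the full region; protect archaic lineages and the ancestor
    ids = labeled["haplotype_id"].tolist() + ["ANCESTOR"]
    seqs = aln.sequences() + ["".join(aln.ancestor)]
    keep = tuple(
        labeled.loc[labeled["cluster"].str.startswith("archaic"), "haplotype_id"]
    ) + ("ANCESTOR",)
    col = collapse_and_filter(ids, seqs, min_count_exclusive=args.min_count,
                              keep_ids=keep,
                              categories=labeled["haplogroup"].tolist() + ["outgroup"])
    print(f"\ncollapsed to {len(col)} haplotypes (protected: {sorted(keep)})")

    net = build_network(col)
    edges = [(u, v, d["mutations"]) for u, v, d in net.edges(data=True)]
    pd.DataFrame(edges, columns=["node_a", "node_b", "mutations"]).to_csv(
        RESULTS / "network_edges.tsv", sep="\t", index=False
    )
    nodes = pd.DataFrame(
        [(n, d["count"], json.dumps(d["categories"])) for n, d in net.nodes(data=True)],
        columns=["node", "count", "categories"],
    )
    nodes.to_csv(RESULTS / "network_nodes.tsv", sep="\t", index=False)
    print(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} links")

    consensus, full = bootstrap_consensus(
        col, "ANCESTOR", replicates=args.bootstraps, seed=args.seed
    )
    for node in full.preorder_internal_node_iter():
        node.label = f"{node.support:.0f}"
    (RESULTS / "nj_tree.nwk").write_text(full.as_string(schema="newick"))
    supports = [n.support for n in full.preorder_internal_node_iter()]
    print(
        f"NJ tree with {args.bootstraps} bootstraps: "
        f"median clade support {pd.Series(supports).median():.0f}% -> results/nj_tree.nwk"
    )


if __name__ == "__main__":
    main()
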