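"""Contig similarity network, community clusters, and identity propagation.

Contigs are nodes; an edge joins two contigs whose Mash distance is at or
below the threshold (default 0.05, ~>=95% ANI), with weight 1 - distance.
Communities are found with Louvain modularity optimisation (seeded, on a
canonically ordered graph so runs are reproducible); a pure single-linkage
alternative uses connected components.  Clusters are then categorised:

* viral if at least 25% of member contigs are called viral,
* else bacterial if any member comes from a bacterial reference SAG (and
  is not itself viral), carries a bacterial 16S flag, or fired the
  RefSeq-bacterial-ORF-majority rule,
* else eukaryote.

The cluster category is propagated back to every member.  Viral clusters
receive an LCA label by majority vote over member-contig LCA labels, each
contig label being the modal per-ORF LCA at a minimum 25% frequency
("Viral" when no label reaches it).  Inter-phylum viruses are viral
clusters whose members occur in SAGs of two or more distinct identified
phyla.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "ContigCluster",
    "build_contig_graph",
    "detect_clusters",
    "categorize_cluster",
    "categorize_all",
    "filter_sags",
    "assign_contig_lca",
    "cluster_lca",
    "interphylum_clusters",
]


@dataclass
class ContigCluster:
    cluster_id: str
    members: tuple  # contig_ids, sorted
    category: str = ""  # viral | bacterial | eukaryote
    viral_fraction: float = 0.0
    lca_label: str = ""
    member_sags: tuple = ()
    member_phyla: tuple = ()


def build_contig_graph(records, node_meta: dict, threshold: float = 0.05) -> nx.Graph:
    """Build the similarity graph.

    ``node_meta`` maps every contig_id to a dict with at least ``sag_id``
    and ``source`` ("protist" or "bacterial_reference"); contigs without
    records appear as isolated nodes.  Records above the threshold are
    rejected (the caller filters), as are records naming unknown contigs.
    """
    g = nx.Graph()
    for cid in sorted(node_meta):
        g.add_node(cid, **node_meta[cid])
    for r in records:
        if r.contig_a not in node_meta or r.contig_b not in node_meta:
            missing = r.contig_a if r.contig_a not in node_meta else r.contig_b
            raise KeyError(f"distance record references unknown contig {missing!r}")
        if r.mash_distance > threshold:
            raise ValueError(
                f"record ({r.contig_a},{r.contig_b}) distance {r.mash_distance} "
                f"exceeds threshold {threshold}")
        if r.contig_a == r.contig_b:
            continue
        g.add_edge(r.contig_a, r.contig_b,
                   weight=1.0 - r.mash_distance, distance=r.mash_distance)
    return g


def detect_clusters(g: nx.Graph, seed: int = 1,
                    method: str = "louvain") -> list[ContigCluster]:
    """Partition the graph into clusters.

    ``method="louvain"`` runs seeded Louvain modularity optimisation
    (communities never span connected components); ``"connected-components"``
    reproduces pure single linkage.  Nodes are processed in sorted order so
    the partition is deterministic for a fixed seed.
    """
    if method == "louvain":
        comms = nx.algorithms.community.louvain_communities(
            g, weight="weight", seed=seed)
    elif method == "connected-components":
        comms = list(nx.connected_components(g))
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    comms = sorted((tuple(sorted(c)) for c in comms), key=lambda c: c[0])
    return [ContigCluster(cluster_id=f"CL{i:05d}", members=c)
            for i, c in enumerate(comms)]


def categorize_cluster(cluster: ContigCluster, calls: dict, ref16s: set,
                       node_meta: dict, viral_min_fraction: float = 0.25) -> str:
    """Assign the cluster category and write it back to the cluster."""
    n = len(cluster.members)
    missing = [m for m in cluster.members if m not in calls]
    if missing:
        raise KeyError(f"no contig call for cluster member {missing[0]!r}")
    n_viral = sum(1 for m in cluster.members if calls[m].category == "viral")
    cluster.viral_fraction = n_viral / n
    if cluster.viral_fraction >= viral_min_fraction:
        cluster.category = "viral"
        return "viral"
    for m in cluster.members:
        from_ref = node_meta.get(m, {}).get("source") == "bacterial_reference"
        if (from_ref and calls[m].category != "viral") or m in ref16s \
                or "bacterial_by_orf_majority" in calls[m].basis:
            cluster.category = "bacterial"
            return "bacterial"
    cluster.category = "eukaryote"
    return "eukaryote"


def categorize_all(clusters, calls: dict, ref16s: set, node_meta: dict,
                   viral_min_fraction: float = 0.25) -> dict:
    """Categorise every cluster and propagate the category to members.

    Returns the propagated contig→category map.  Idempotent: categories are
    derived solely from the per-contig calls, reference flags and cluster
    membership.
    """
    propagated: dict[str, str] = {}
    for c in clusters:
        cat = categorize_cluster(c, calls, ref16s, node_meta, viral_min_fraction)
        sags = sorted({node_meta.get(m, {}).get("sag_id", "") for m in c.members})
        c.member_sags = tuple(s for s in sags if s)
        for m in c.members:
            propagated[m] = cat
    return propagated


def filter_sags(sag_contigs: dict, categories: dict) -> list:
    """Retain SAGs with at least one eukaryote-category contig.

    ``sag_contigs`` maps sag_id → list of contig_ids; ``categories`` maps
    contig_id → propagated category.
    """
    kept = []
    for sag_id, contigs in sag_contigs.items():
        if any(categories.get(c) == "eukaryote" for c in contigs):
            kept.append(sag_id)
    return kept


def assign_contig_lca(vog_hits, min_freq: float = 0.25) -> str:
    """Modal per-ORF LCA label at a minimum frequency; "Viral" fallback.

    ``vog_hits`` is a list of (orf_index, lca_label); ORFs without a hit
    should be present with label "none" so they count in the denominator.
    "none" itself is never returned.
    """
    if not vog_hits:
        return "Viral"
    counts = Counter(lab for _, lab in vog_hits)
    counts.pop("none", None)
    if not counts:
        return "Viral"
    label, n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    if n / len(vog_hits) >= min_freq:
        return label
    return "Viral"


def cluster_lca(cluster: ContigCluster, contig_lca: dict) -> str:
    """Cluster-level LCA: modal informative member label, else "Viral"."""
    labels = [contig_lca.get(m, "Viral") for m in cluster.members]
    informative = [l for l in labels if l != "Viral"]
    if not informative:
        cluster.lca_label = "Viral"
    else:
        cluster.lca_label = max(Counter(informative).items(),
                                key=lambda kv: (kv[1], kv[0]))[0]
    return cluster.lca_label


def interphylum_clusters(clusters, sag_taxa: dict):
    """Viral clusters found in SAGs of >=2 distinct identified phyla.

    SAGs with taxon "unidentified" are listed but do not count toward the
    phylum tally.  Returns ``(table, edges)``: one row per inter-phylum
    viral cluster, and the bipartite SAG–virus edge list over all viral
    clusters (for network-style plots).
    """
    rows, edges = [], []
    for c in clusters:
        if c.category != "viral":
            continue
        sags = sorted(set(c.member_sags))
        for s in sags:
            edges.append({"cluster_id": c.cluster_id, "sag_id": s,
                          "taxon": sag_taxa.get(s, "unidentified")})
        phyla = sorted({sag_taxa.get(s, "unidentified") for s in sags}
                       - {"unidentified"})
        c.member_phyla = tuple(phyla)
        if len(phyla) >= 2:
            rows.append({
                "cluster_id": c.cluster_id,
                "n_members": len(c.members),
                "n_sags": len(sags),
                "phyla": ";".join(phyla),
                "sags": ";".join(sags),
                "lca_label": c.lca_label,
            })
    table = pd.DataFrame(rows, columns=[
        "cluster_id", "n_members", "n_sags", "phyla", "sags", "lca_label"])
    return table, pd.DataFrame(edges, columns=["cluster_id", "sag_id", "taxon"])
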