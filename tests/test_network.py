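"""Network construction, community detection (with a brute-force modularity
oracle), cluster categorisation, SAG filtering, LCA voting, and inter-phylum
virus detection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from virlink.classify import ContigCall
from virlink.network import (ContigCluster, assign_contig_lca,
                             build_contig_graph, categorize_all,
                             categorize_cluster, detect_clusters, filter_sags,
                             interphylum_clusters)
from virlink.sketch import DistanceRecord


def meta(ids, sag="S1", source="protist"):
    return {i: {"sag_id": sag, "source": source} for i in ids}


def rec(a, b, d=0.01):
    return DistanceRecord(a, b, 0.9, d)


class TestBuildGraph:
    def test_no_records_gives_isolated_nodes(self):
        g = build_contig_graph([], meta(["a", "b"]))
        assert set(g.nodes) == {"a", "b"} and g.number_of_edges() == 0

    def test_threshold_is_inclusive(self):
        g = build_contig_graph([rec("a", "b", 0.05)], meta(["a", "b"]))
        assert g.has_edge("a", "b")
        assert g["a"]["b"]["weight"] == pytest.approx(0.95)

    def test_unknown_contig_rejected(self):
        with pytest.raises(KeyError, match="ghost"):
            build_contig_graph([rec("a", "ghost")], meta(["a", "b"]))

    def test_above_threshold_record_rejected(self):
        with pytest.raises(ValueError):
            build_contig_graph([rec("a", "b", 0.2)], meta(["a", "b"]))


def modularity_of(g, partition):
    return nx.algorithms.community.modularity(g, partition, weight="weight")


class TestDetectClusters:
    def test_two_disjoint_cliques(self):
        ids = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        records = [rec(x, y) for grp in ("a", "b")
                   for x, y in itertools.combinations(
                       [f"{grp}{i}" for i in range(4)], 2)]
        g = build_contig_graph(records, meta(ids))
        clusters = detect_clusters(g, seed=1)
        members = sorted(c.members for c in clusters)
        assert members == [tuple(f"a{i}" for i in range(4)),
                           tuple(f"b{i}" for i in range(4))]

    def test_isolated_node_is_singleton(self):
        g = build_contig_graph([rec("a", "b")], meta(["a", "b", "lonely"]))
        clusters = detect_clusters(g, seed=1)
        assert ("lonely",) in [c.members for c in clusters]

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        ids = [f"n{i}" for i in range(30)]
        records = [rec(*sorted(rng.choice(ids, 2, replace=False)))
                   for _ in range(40)]
        records = list({(r.contig_a, r.contig_b): r for r in records
                        if r.contig_a != r.contig_b}.values())
        g = build_contig_graph(records, meta(ids))
        clusters = detect_clusters(g, seed=1)
        flat = [m for c in clusters for m in c.members]
        assert sorted(flat) == sorted(ids)

    def test_modularity_beats_bruteforce_bipartitions(self):
        """Two planted 10-cliques joined by one spurious edge: Louvain must
        find a partition at least as good as the best of all bipartitions
        (exhaustively enumerated), which is the planted split."""
        a = [f"a{i}" for i in range(10)]
        b = [f"b{i}" for i in range(10)]
        records = [rec(x, y) for grp in (a, b)
                   for x, y in itertools.combinations(grp, 2)]
        records.append(rec("a0", "b0"))  # spurious bridge
        g = build_contig_graph(records, meta(a + b))
        clusters = detect_clusters(g, seed=1)
        part = [set(c.members) for c in clusters]
        # brute-force best bipartition over all 2^19 splits of the 20 nodes,
        # via the modularity matrix B = A - k k^T / 2m (vectorised)
        nodes = a + b
        A = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        k = A.sum(axis=1)
        two_m = A.sum()
        B = A - np.outer(k, k) / two_m
        n = len(nodes)
        masks = np.arange(2 ** (n - 1), dtype=np.uint32)
        S = ((masks[:, None] >> np.arange(n, dtype=np.uint32)) & 1).astype(float)
        q_all = (np.einsum("mi,ij,mj->m", S, B, S)
                 + np.einsum("mi,ij,mj->m", 1 - S, B, 1 - S)) / two_m
        best = float(q_all.max())
        assert modularity_of(g, part) >= best - 1e-12
        assert part == [set(a), set(b)] or part == [set(b), set(a)]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        ids = [f"n{i}" for i in range(25)]
        records = list({tuple(sorted(rng.choice(ids, 2, replace=False))): None
                        for _ in range(60)})
        records = [rec(x, y) for x, y in records if x != y]
        g = build_contig_graph(records, meta(ids))
        c1 = detect_clusters(g, seed=3)
        c2 = detect_clusters(g, seed=3)
        assert [c.members for c in c1] == [c.members for c in c2]

    def test_connected_components_mode(self):
        records = [rec("a", "b"), rec("b", "c")]
        g = build_contig_graph(records, meta(["a", "b", "c", "d"]))
        clusters = detect_clusters(g, method="connected-components")
        assert sorted(c.members for c in clusters) == [("a", "b", "c"), ("d",)]


def call(cid, cat, basis=()):
    return ContigCall(cid, cat, tuple(basis))


class TestCategorize:
    def test_quarter_viral_is_viral(self):
        c = ContigCluster("cl", ("a", "b", "c", "d"))
        calls = {"a": call("a", "viral"), "b": call("b", "eukaryote"),
                 "c": call("c", "eukaryote"), "d": call("d", "eukaryote")}
        assert categorize_cluster(c, calls, set(), meta(c.members)) == "viral"
        assert c.viral_fraction == 0.25

    def test_bacterial_reference_member(self):
        c = ContigCluster("cl", ("a", "bref"))
        calls = {"a": call("a", "eukaryote"), "bref": call("bref", "bacterial")}
        nm = {**meta(["a"]), **meta(["bref"], sag="BREF", source="bacterial_reference")}
        assert categorize_cluster(c, calls, set(), nm) == "bacterial"

    def test_viral_reference_member_does_not_make_bacterial(self):
        # a prophage contig from a bacterial SAG called viral is not
        # bacterial evidence; below the 25% viral fraction the cluster
        # falls through to eukaryote
        members = ("a", "b", "c", "d", "bref")
        c = ContigCluster("cl", members)
        calls = {x: call(x, "eukaryote") for x in "abcd"}
        calls["bref"] = call("bref", "viral")
        nm = {**meta(["a", "b", "c", "d"]),
              **meta(["bref"], sag="BREF", source="bacterial_reference")}
        assert categorize_cluster(c, calls, set(), nm) == "eukaryote"

    def test_16s_flag_and_orf_majority(self):
        c = ContigCluster("cl", ("a", "b"))
        calls = {"a": call("a", "eukaryote"), "b": call("b", "eukaryote")}
        assert categorize_cluster(c, calls, {"b"}, meta(c.members)) == "bacterial"
        calls["b"] = call("b", "bacterial", ["bacterial_by_orf_majority"])
        assert categorize_cluster(c, calls, set(), meta(c.members)) == "bacterial"

    def test_below_threshold_no_evidence_is_eukaryote(self):
        c = ContigCluster("cl", tuple("abcde"))
        calls = {x: call(x, "viral" if x == "a" else "eukaryote") for x in "abcde"}
        assert categorize_cluster(c, calls, set(), meta(c.members)) == "eukaryote"

    def test_missing_call_is_error(self):
        c = ContigCluster("cl", ("a", "b"))
        with pytest.raises(KeyError):
            categorize_cluster(c, {"a": call("a", "viral")}, set(), meta(c.members))

    def test_propagation_idempotent(self):
        c1 = ContigCluster("cl", ("a", "b", "c", "d"))
        calls = {x: call(x, "viral" if x == "a" else "eukaryote") for x in "abcd"}
        p1 = categorize_all([c1], calls, set(), meta(c1.members))
        c2 = ContigCluster("cl", ("a", "b", "c", "d"))
        p2 = categorize_all([c2], calls, set(), meta(c2.members))
        assert p1 == p2 == {x: "viral" for x in "abcd"}


class TestFilterSags:
    def test_all_foreign_sag_removed(self):
        cats = {"v1": "viral", "v2": "viral", "e1": "eukaryote"}
        kept = filter_sags({"S1": ["v1", "v2"], "S2": ["e1", "v1"]}, cats)
        assert kept == ["S2"]

    def test_empty_input(self):
        assert filter_sags({}, {}) == []


class TestLca:
    def test_modal_label_above_min_freq(self):
        hits = [(0, "Caudovirales"), (1, "Caudovirales"),
                (2, "Microviridae"), (3, "none")]
        assert assign_contig_lca(hits) == "Caudovirales"

    def test_all_below_min_freq_falls_back(self):
        hits = [(i, lab) for i, lab in enumerate(
            ["A", "B", "C", "D", "E"])]
        assert assign_contig_lca(hits, min_freq=0.25) == "Viral"

    def test_single_orf(self):
        assert assign_contig_lca([(0, "Microviridae")]) == "Microviridae"

    def test_none_never_returned(self):
        assert assign_contig_lca([(0, "none"), (1, "none")]) == "Viral"
        assert assign_contig_lca([]) == "Viral"


class TestInterphylum:
    def make_cluster(self, cid, sags, category="viral"):
        c = ContigCluster(cid, tuple(f"{s}_c" for s in sags),
                          category=category)
        c.member_sags = tuple(sags)
        return c

    def test_two_phyla_detected(self):
        c = self.make_cluster("cl1", ["S1", "S2"])
        taxa = {"S1": "Choanozoa", "S2": "Picozoa"}
        table, edges = interphylum_clusters([c], taxa)
        assert list(table["cluster_id"]) == ["cl1"]
        assert len(edges) == 2

    def test_single_phylum_not_interphylum(self):
        c = self.make_cluster("cl1", ["S1", "S2", "S3"])
        taxa = {s: "Choanozoa" for s in ("S1", "S2", "S3")}
        table, _ = interphylum_clusters([c], taxa)
        assert table.empty

    def test_unidentified_does_not_count_but_is_listed(self):
        c = self.make_cluster("cl1", ["S1", "S2"])
        taxa = {"S1": "Choanozoa"}  # S2 unidentified
        table, edges = interphylum_clusters([c], taxa)
        assert table.empty
        assert set(edges["sag_id"]) == {"S1", "S2"}

    def test_nonviral_clusters_ignored(self):
        c = self.make_cluster("cl1", ["S1", "S2"], category="bacterial")
        table, edges = interphylum_clusters([c], {"S1": "A", "S2": "B"})
        assert table.empty and edges.empty
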