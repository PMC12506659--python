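"""Similarity networks: node collapsing, thresholding, sweeps, neighborhoods."""

import numpy as np
import pandas as pd
import pytest

from ecaudit.simulate import SuperfamilyConfig, gen_neighborhoods, gen_superfamily
from ecaudit.ssn import (
    SimilarityEdge,
    build_network,
    cluster_purity,
    collapse_nodes,
    connected_components,
    edges_from_sequences,
    neighborhood_signature,
    read_blast_tab,
    sweep_threshold,
    write_blast_tab,
)


def edge(a, b, ident=0.5, as_score=50.0):
    return SimilarityEdge(a, b, ident, as_score)


class TestSimilarityEdge:
    def test_endpoints_stored_sorted(self):
        e = edge("z", "a")
        assert (e.id_a, e.id_b) == ("a", "z")

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError):
            edge("a", "a")

    def test_identity_range_enforced(self):
        with pytest.raises(ValueError):
            SimilarityEdge("a", "b", 1.2, 10.0)


class TestCollapseNodes:
    def test_all_similar_collapse_to_one(self):
        edges = [edge("a", "b", 0.9), edge("a", "c", 0.9), edge("b", "c", 0.9)]
        part = collapse_nodes(edges, {"a", "b", "c"}, 0.7)
        assert list(part.values()) == [frozenset({"a", "b", "c"})]

    def test_chain_splits_at_cutoff(self):
        edges = [edge("a", "b", 0.75), edge("b", "c", 0.65)]
        part = collapse_nodes(edges, {"a", "b", "c"}, 0.7)
        assert set(part.values()) == {frozenset({"a", "b"}), frozenset({"c"})}

    def test_below_cutoff_all_singletons(self):
        edges = [edge("a", "b", 0.5), edge("b", "c", 0.6)]
        part = collapse_nodes(edges, {"a", "b", "c"}, 0.7)
        assert all(len(m) == 1 for m in part.values())

    def test_cutoff_one_keeps_only_exact_duplicates(self):
        edges = [edge("a", "b", 1.0), edge("b", "c", 0.99)]
        part = collapse_nodes(edges, {"a", "b", "c"}, 1.0)
        assert set(part.values()) == {frozenset({"a", "b"}), frozenset({"c"})}

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError):
            collapse_nodes([edge("a", "q")], {"a", "b"}, 0.7)

    def test_membership_partitions_all_sequences(self):
        ids = {f"s{i}" for i in range(10)}
        edges = [edge("s0", "s1", 0.9), edge("s2", "s3", 0.8)]
        part = collapse_nodes(edges, ids, 0.7)
        members = [m for ms in part.values() for m in ms]
        assert sorted(members) == sorted(ids)


def brute_force_components(nodes, surviving_edges):
    """Oracle: depth-first search on an explicit adjacency list."""
    adj = {n: set() for n in nodes}
    for a, b in surviving_edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            n = stack.pop()
            if n in comp:
                continue
            comp.add(n)
            stack.extend(adj[n] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestBuildNetwork:
    def test_threshold_is_strict(self):
        part = {"a": frozenset({"a"}), "b": frozenset({"b"})}
        edges = [edge("a", "b", 0.5, as_score=70.0)]
        assert build_network(part, edges, 70.0).graph.number_of_edges() == 0
        assert build_network(part, edges, 69.9).graph.number_of_edges() == 1

    def test_zero_threshold_keeps_every_recorded_pair(self):
        part = {x: frozenset({x}) for x in "abc"}
        edges = [edge("a", "b", 0.5, 5.0), edge("b", "c", 0.5, 1.0)]
        assert build_network(part, edges, 0.0).graph.number_of_edges() == 2

    def test_intra_meta_node_edges_dropped(self):
        part = {"a": frozenset({"a", "b"}), "c": frozenset({"c"})}
        edges = [edge("a", "b", 0.9, 100.0), edge("b", "c", 0.5, 50.0)]
        ssn = build_network(part, edges, 10.0)
        assert list(ssn.graph.edges()) == [("a", "c")]

    def test_cross_pair_aggregation_max_vs_mean(self):
        part = {"a": frozenset({"a", "b"}), "c": frozenset({"c"})}
        edges = [edge("a", "c", 0.5, 80.0), edge("b", "c", 0.5, 20.0)]
        assert build_network(part, edges, 60.0, aggregate="max").graph.number_of_edges() == 1
        assert build_network(part, edges, 60.0, aggregate="mean").graph.number_of_edges() == 0

    def test_components_match_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        ids = [f"s{i}" for i in range(30)]
        edges = [
            edge(ids[i], ids[j], 0.5, float(rng.integers(0, 100)))
            for i in range(30)
            for j in range(i + 1, 30)
            if rng.random() < 0.1
        ]
        part = {i: frozenset({i}) for i in ids}
        for thr in (0.0, 25.0, 50.0, 75.0):
            ssn = build_network(part, edges, thr)
            surviving = [(e.id_a, e.id_b) for e in edges if e.as_score > thr]
            assert set(connected_components(ssn)) == brute_force_components(ids, surviving)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        ids = [f"s{i}" for i in range(20)]
        edges = [
            edge(a, b, 0.5, float(rng.integers(0, 120)))
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
            if rng.random() < 0.2
        ]
        part = {i: frozenset({i}) for i in ids}
        prev_edges, prev_ncomp = None, None
        for thr in np.arange(0, 120, 5.0):
            ssn = build_network(part, edges, float(thr))
            cur = set(ssn.graph.edges())
            ncomp = len(connected_components(ssn))
            if prev_edges is not None:
                assert cur <= prev_edges
                assert ncomp >= prev_ncomp
            prev_edges, prev_ncomp = cur, ncomp


class TestSweep:
    def test_two_subgroups_separate_above_between_score(self):
        # planted scores: within 120, between max 45 -> stops at 45 (edges need AS > 45)
        ids = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
        labels = {i: i[0] for i in ids}
        edges = []
        for grp in ("a", "b"):
            g = [i for i in ids if i.startswith(grp)]
            edges += [edge(x, y, 0.8, 120.0) for i, x in enumerate(g) for y in g[i + 1 :]]
        edges.append(edge("a0", "b0", 0.4, 45.0))
        part = {i: frozenset({i}) for i in ids}
        report = sweep_threshold(part, edges, labels, as_start=40, step=5, purity_target=0.9)
        assert report.chosen_threshold == 45
        assert report.converged
        assert sorted(report.sizes) == [6, 6]
        assert all(p == 1.0 for p in report.purities)

    def test_homogeneous_family_stops_immediately(self):
        ids = ["x0", "x1", "x2"]
        labels = {i: "E" for i in ids}
        edges = [edge(a, b, 0.8, 100.0) for i, a in enumerate(ids) for b in ids[i + 1 :]]
        part = {i: frozenset({i}) for i in ids}
        report = sweep_threshold(part, edges, labels, as_start=10, step=5, min_cluster_size=2)
        assert report.chosen_threshold == 10 and report.converged

    def test_missing_labels_rejected(self):
        part = {"a": frozenset({"a"}), "b": frozenset({"b"})}
        with pytest.raises(ValueError):
            sweep_threshold(part, [edge("a", "b", 0.5, 50.0)], {"a": "E"}, as_start=0)

    def test_four_subgroup_family_resolves_to_singleton_label_sets(self):
        cfg = SuperfamilyConfig(
            n_subgroups=4, seqs_per_subgroup=15, seq_length=120, rng_seed=3
        )
        fam = gen_superfamily(cfg)
        edges = edges_from_sequences(fam.sequences)
        labels = fam.truth.labels()
        part = collapse_nodes(edges, fam.sequences.keys(), 0.7)
        report = sweep_threshold(part, edges, labels, as_start=10, step=5, min_cluster_size=5)
        assert report.converged
        big = [ls for ls, size in zip(report.cluster_labels(labels), report.sizes) if size >= 5]
        assert all(len(ls) == 1 for ls in big)


class TestNeighborhoodSignature:
    def test_planted_partner_frequency_recovered(self, two_subgroup_family):
        fam = two_subgroup_family
        ctx = gen_neighborhoods(fam.truth, colocal_prob=0.9, rng_seed=5)
        edges = edges_from_sequences(fam.sequences)
        part = collapse_nodes(edges, fam.sequences.keys(), 0.7)
        report = sweep_threshold(part, edges, fam.truth.labels(), as_start=10, step=5)
        sigs = neighborhood_signature(report, ctx, window=5)
        sub = fam.truth.subgroup_of()
        for ci, cluster in enumerate(report.clusters):
            members = report.ssn.members(cluster)
            (k,) = {sub[m] for m in members}
            frac = sigs[ci]["fractions"].get(f"partner_{k}", 0.0)
            assert frac == pytest.approx(0.9, abs=0.15)
            assert f"partner_{k}" in sigs[ci]["dominant"]

    def test_disjoint_partners_give_disjoint_dominant_signatures(self, two_subgroup_family):
        fam = two_subgroup_family
        ctx = gen_neighborhoods(fam.truth, colocal_prob=1.0, n_decoy_families=500, rng_seed=6)
        edges = edges_from_sequences(fam.sequences)
        part = collapse_nodes(edges, fam.sequences.keys(), 0.7)
        report = sweep_threshold(part, edges, fam.truth.labels(), as_start=10, step=5)
        sigs = neighborhood_signature(report, ctx, window=5)
        doms = [sigs[ci]["dominant"] for ci in sigs]
        assert len(doms) == 2
        assert doms[0] & doms[1] == set()

    def test_empty_context_gives_empty_signatures(self, two_subgroup_family):
        fam = two_subgroup_family
        edges = edges_from_sequences(fam.sequences)
        part = collapse_nodes(edges, fam.sequences.keys(), 0.7)
        report = sweep_threshold(part, edges, fam.truth.labels(), as_start=10, step=5)
        ctx = pd.DataFrame(columns=["seq_id", "genome_id", "neighbor_family", "offset"])
        sigs = neighborhood_signature(report, ctx, window=5)
        assert all(s["fractions"] == {} for s in sigs.values())


class TestBlastTabRoundTrip:
    def test_edges_survive_write_read(self, tmp_path):
        edges = [edge("a", "b", 0.83, 57.5), edge("a", "c", 0.41, 12.25)]
        path = tmp_path / "sim.tsv"
        write_blast_tab(edges, path, length=120)
        back = read_blast_tab(path)
        assert [(e.id_a, e.id_b) for e in back] == [("a", "b"), ("a", "c")]
        for orig, rt in zip(edges, back):
            assert rt.pct_identity == pytest.approx(orig.pct_identity, abs=1e-4)
            assert rt.as_score == pytest.approx(orig.as_score, rel=1e-4)

    def test_evalue_zero_maps_to_cap(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q\ts\t95.0\t100\t5\t0\t1\t100\t1\t100\t0.0\t500\n")
        (e,) = read_blast_tab(path)
        assert e.as_score == 200.0
        assert e.pct_identity == pytest.approx(0.95)

    def test_reciprocal_hits_collapse_keeping_best(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q\ts\t80.0\t100\t5\t0\t1\t100\t1\t100\t1e-50\t200\n"
            "s\tq\t85.0\t100\t5\t0\t1\t100\t1\t100\t1e-60\t220\n"
            "q\tq\t100.0\t100\t0\t0\t1\t100\t1\t100\t0.0\t500\n"
        )
        (e,) = read_blast_tab(path)
        assert e.as_score == pytest.approx(60.0)
        assert e.pct_identity == pytest.approx(0.85)
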