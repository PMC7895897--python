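"""Dereplication, pair coverage, VC graph and protein-cluster structure."""

import networkx as nx
import numpy as np
import pytest

from phagekit.align import align_pair
from phagekit.clustering import (ProteinCluster, bitscore_similarity,
                                 build_vc_graph, clade_hierarchy,
                                 cluster_proteins, dereplicate, non_singleton,
                                 pair_coverage, shared_protein_fraction,
                                 vc_graph_from_hits, viral_clusters)
from phagekit.intervals import Interval
from phagekit.records import AlignmentHit
from phagekit.simulate import gen_sequence_family

from .test_intervals import brute_force_positions


def _hit(qid, sid, qs, qe, ss, se, pct, evalue=1e-20):
    return AlignmentHit(qid, sid, qs, qe, ss, se, pct, evalue, 100.0)


class TestDereplicate:
    def test_identical_sequences_one_cluster_deterministic_representative(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=15_000))
        clusters = dereplicate({"b": seq, "a": seq}, 0.99, "global")
        assert len(clusters) == 1
        assert clusters[0].representative_id == "a"  # length tie -> lexicographic

    def test_fragment_joins_species_cluster_but_not_global(self, rng):
        recs, _ = gen_sequence_family(15_000, 0.0, 1, seed=5)
        parent = recs[0].seq
        frag = list(parent[1000:13000])
        swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in rng.choice(len(frag), size=int(0.04 * len(frag)), replace=False):
            frag[i] = swap[frag[i]]
        seqs = {"parent": parent, "frag": "".join(frag)}
        at95 = dereplicate(seqs, 0.95, "local")
        assert len(at95) == 1 and at95[0].representative_id == "parent"
        assert len(dereplicate(seqs, 0.99, "global")) == 2

    def test_90_percent_pair_splits_at_species_level(self):
        recs, _ = gen_sequence_family(12_000, 0.052, 2, seed=6)  # ~90% pairwise
        assert len(dereplicate({r.id: r.seq for r in recs}, 0.95, "local")) == 2

    def test_partition_and_representative_dissimilarity(self, rng):
        fams = []
        for k in range(3):
            recs, _ = gen_sequence_family(10_000, 0.02, 3, seed=20 + k, prefix=f"f{k}")
            fams += recs
        seqs = {r.id: r.seq for r in fams}
        clusters = dereplicate(seqs, 0.95, "local")
        members = [m for c in clusters for m in c.member_ids]
        assert sorted(members) == sorted(seqs)      # partition
        from phagekit.align import pairwise_identity
        reps = [c.representative_id for c in clusters]
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                ident, _ = pairwise_identity(seqs[reps[i]], seqs[reps[j]], "local")
                assert ident < 0.95                  # reps pairwise non-matching

    def test_bad_identity_rejected(self):
        with pytest.raises(ValueError, match="identity"):
            dereplicate({"a": "ACGT"}, 1.2, "global")
        with pytest.raises(ValueError, match="no sequences"):
            dereplicate({}, 0.99, "global")


class TestPairCoverage:
    def test_merged_qualifying_hits_low_identity_excluded(self):
        hits = [_hit("A", "B", 0, 300, 0, 300, 92.0),
                _hit("A", "B", 200, 600, 200, 600, 92.0),
                _hit("A", "B", 600, 900, 600, 900, 85.0)]  # below 90% identity
        assert pair_coverage(hits, "A", "B", 1000, 5000) == pytest.approx(0.6)

    def test_full_length_hit_covers_everything(self):
        assert pair_coverage([_hit("A", "B", 0, 1000, 0, 1000, 95.0)],
                             "A", "B", 1000, 2000) == 1.0

    def test_only_low_identity_hits_give_zero(self):
        assert pair_coverage([_hit("A", "B", 0, 1000, 0, 1000, 89.9)],
                             "A", "B", 1000, 2000) == 0.0

    def test_high_evalue_hits_excluded(self):
        assert pair_coverage([_hit("A", "B", 0, 1000, 0, 1000, 95.0, evalue=0.01)],
                             "A", "B", 1000, 2000) == 0.0

    def test_projection_onto_shorter_sequence_from_either_direction(self):
        # B is shorter; one hit reported A->B, one B->A: both project onto B
        hits = [_hit("A", "B", 100, 400, 0, 300, 95.0),
                _hit("B", "A", 300, 500, 400, 600, 95.0)]
        assert pair_coverage(hits, "A", "B", 2000, 1000) == pytest.approx(0.5)

    def test_symmetric_in_argument_order(self):
        hits = [_hit("A", "B", 0, 500, 100, 600, 95.0)]
        assert pair_coverage(hits, "A", "B", 2000, 1000) == \
            pair_coverage(hits, "B", "A", 1000, 2000)

    def test_foreign_hit_rejected(self):
        with pytest.raises(ValueError, match="not between"):
            pair_coverage([_hit("A", "C", 0, 10, 0, 10, 95.0)], "A", "B", 100, 100)

    def test_matches_position_union_oracle_on_random_hit_sets(self, rng):
        for _ in range(300):
            short_len = int(rng.integers(200, 2000))
            n = int(rng.integers(0, 12))
            intervals, hits = [], []
            for _ in range(n):
                s = int(rng.integers(0, short_len - 1))
                e = s + int(rng.integers(1, 500))
                pct = float(rng.uniform(80, 100))
                hits.append(_hit("S", "L", s, e, s, e, pct))
                if pct >= 90.0:
                    intervals.append(Interval(s, min(e, short_len)))
            expected = len(brute_force_positions(intervals, short_len)) / short_len
            assert pair_coverage(hits, "S", "L", short_len, 5000) == expected


class TestVCGraph:
    def test_edge_boundaries(self, cfg):
        g = build_vc_graph([("a", "b", 0.76), ("a", "c", 0.75), ("c", "d", 0.2)])
        assert g.has_edge("a", "b") and not g.has_edge("a", "c")
        assert set(g.nodes) == {"a", "b", "c", "d"}

    def test_edgeless_graph_yields_all_singletons(self):
        g = build_vc_graph([], nodes=["a", "b", "c"])
        vcs = viral_clusters(g)
        assert len(vcs) == 3 and all(v.is_singleton for v in vcs)
        assert non_singleton(vcs) == []

    def test_planted_families_form_their_own_vcs(self):
        """Two related families plus a diverged loner: VC graph edges from the
        built-in aligner, clusters recovered exactly."""
        fam1, _ = gen_sequence_family(9_000, 0.02, 3, seed=31, prefix="x")
        fam2, _ = gen_sequence_family(9_000, 0.02, 3, seed=32, prefix="y")
        loner, _ = gen_sequence_family(9_000, 0.0, 1, seed=33, prefix="z")
        genomes = fam1 + fam2 + loner
        lengths = {g.id: g.length for g in genomes}
        hits = []
        for i in range(len(genomes)):
            for j in range(i + 1, len(genomes)):
                hits += align_pair(genomes[i].id, genomes[i].seq,
                                   genomes[j].id, genomes[j].seq)
        graph = vc_graph_from_hits(hits, lengths)
        vcs = viral_clusters(graph)
        parts = sorted(sorted(v.member_ids) for v in vcs)
        assert parts == [["x_000", "x_001", "x_002"],
                         ["y_000", "y_001", "y_002"], ["z_000"]]
        assert len(non_singleton(vcs)) == 2


class TestProteinClusters:
    def test_two_families_cluster_and_orphan_removed(self):
        sims = [("p1", "p2", 0.9), ("p2", "p3", 0.8), ("p1", "p3", 0.85),
                ("q1", "q2", 0.95)]
        clusters = cluster_proteins(sims, proteins=["p1", "p2", "p3", "q1", "q2", "orphan"])
        assert sorted(sorted(c.member_ids) for c in clusters) == \
            [["p1", "p2", "p3"], ["q1", "q2"]]

    def test_asymmetric_similarity_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            cluster_proteins([("a", "b", 0.9), ("b", "a", 0.1)])

    def test_same_graph_same_partition_as_vc_engine(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
        from phagekit.mcl import mcl
        g = nx.Graph(edges)
        vc_part = sorted(sorted(c) for c in mcl(g))
        prot = cluster_proteins([(a, b, 1.0) for a, b in edges])
        assert sorted(sorted(c.member_ids) for c in prot) == vc_part

    def test_bitscore_similarity_normalized_by_self_score(self):
        hits = [AlignmentHit("a", "a", 0, 100, 0, 100, 100.0, 1e-50, 200.0),
                AlignmentHit("b", "b", 0, 100, 0, 100, 100.0, 1e-50, 180.0),
                AlignmentHit("a", "b", 0, 100, 0, 100, 95.0, 1e-40, 150.0)]
        assert bitscore_similarity(hits) == [("a", "b", 150.0 / 200.0)]


class TestCladeStructure:
    def test_shared_fraction_examples(self):
        assert shared_protein_fraction({"a", "b"}, {"a", "b"}) == 1.0
        assert shared_protein_fraction({"a"}, {"b"}) == 0.0
        assert shared_protein_fraction({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        with pytest.raises(ValueError, match="empty"):
            shared_protein_fraction(set(), set())

    def test_planted_two_genus_clade(self):
        """Within-genus sharing ~0.8, between ~0.3 (the 20-40% band):
        two genera, one subfamily."""
        core = {f"core{i}" for i in range(12)}  # shared across the clade
        g1 = {f"g1_{k}": core | {f"g1spec{i}" for i in range(14)} | {f"m{k}"}
              for k in range(3)}
        g2 = {f"g2_{k}": core | {f"g2spec{i}" for i in range(14)} | {f"n{k}"}
              for k in range(3)}
        genomes = {**g1, **g2}
        between = shared_protein_fraction(g1["g1_0"], g2["g2_0"])
        assert 0.20 < between < 0.40
        h = clade_hierarchy(genomes)
        assert len(set(h.genus.values())) == 2
        assert len(set(h.subfamily.values())) == 1
        assert {h.genus[g] for g in g1} != {h.genus[g] for g in g2}

    def test_empty_proteome_excluded_with_warning(self):
        genomes = {"a": {"x", "y"}, "b": {"x"}, "c": set()}
        with pytest.warns(UserWarning, match="excluded"):
            h = clade_hierarchy(genomes)
        assert "c" not in h.genus
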