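"""Spacer matching vs a naive oracle, prophage linkage, host-range LCA."""

import numpy as np
import pytest

from phagekit.hosts import (HostAssignment, Spacer, crispr_assignments,
                            dedupe_assignments, filter_spacers, host_range_rank,
                            link_prophages, match_spacers, parse_gtdb_lineage,
                            vc_diversity)
from phagekit.records import GenomeRecord, revcomp
from phagekit.simulate import gen_crispr_fixture, gen_sequence_family


def naive_two_strand_scan(spacer_seq, genome_seq):
    """Oracle: window-by-window comparison on both strands."""
    for probe in (spacer_seq, revcomp(spacer_seq)):
        m = len(probe)
        for i in range(len(genome_seq) - m + 1):
            if all(genome_seq[i + k] == probe[k] for k in range(m)):
                return True
    return False


def _genome(gid, seq):
    return GenomeRecord(gid, seq)


class TestMatchSpacers:
    def test_verbatim_substring_matches(self):
        g = _genome("p1", "AAAA" + "CGTACGTTAGCATGCATGGCATTAC" + "TTTT")
        sp = Spacer("s1", "asm1", "CGTACGTTAGCATGCATGGCATTAC", 4)
        (m,) = match_spacers([sp], [g])
        assert (m.spacer_id, m.phage_id, m.strand, m.position) == ("s1", "p1", "+", 4)

    def test_single_mismatch_anywhere_fails(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=30))
        g = _genome("p1", "A" * 50 + core + "T" * 50)
        for pos in (0, 15, 29):
            mutated = list(core)
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
            assert match_spacers([Spacer("s", "a", "".join(mutated), 3)], [g]) == []

    def test_reverse_complement_occurrence_matches(self):
        probe = "ACGGATCCGTTAAGCTTGCAATCCG"
        g = _genome("p1", "GGGG" + revcomp(probe) + "CCCC")
        (m,) = match_spacers([Spacer("s1", "a", probe, 3)], [g])
        assert m.strand == "-"

    def test_non_acgt_spacer_skipped_with_warning(self):
        g = _genome("p1", "ACGT" * 20)
        with pytest.warns(UserWarning, match="non-ACGT"):
            assert match_spacers([Spacer("s", "a", "ACGTNACGT", 3)], [g]) == []

    def test_agreement_with_naive_oracle_on_random_fixtures(self, rng):
        """Exact agreement with the two-strand scan on 200 random pairs
        (planted, reverse-complemented, and random-decoy spacers)."""
        genomes = [_genome(f"g{i}", "".join(rng.choice(list("ACGT"), size=400)))
                   for i in range(10)]
        for trial in range(200):
            g = genomes[trial % 10]
            kind = trial % 4
            length = int(rng.integers(25, 46))
            if kind in (0, 1):  # planted forward / reverse-complement
                pos = int(rng.integers(0, g.length - length))
                seq = g.seq[pos:pos + length]
                if kind == 1:
                    seq = revcomp(seq)
            else:               # random decoy
                seq = "".join(rng.choice(list("ACGT"), size=length))
            sp = Spacer("s", "a", seq, 3)
            got = bool([m for m in match_spacers([sp], [g]) if m.phage_id == g.id])
            assert got == naive_two_strand_scan(seq, g.seq)

    def test_planted_fixture_recovered_without_decoy_hits(self):
        fam, _ = gen_sequence_family(3000, 0.4, 6, seed=40, prefix="ph")
        spacers, truth = gen_crispr_fixture(fam, n_planted=20, n_decoys=20, seed=41)
        matches = match_spacers(spacers, fam)
        assert {(m.spacer_id, m.phage_id) for m in matches} == truth


def test_evidence_level_filter():
    spacers = [Spacer(f"s{lvl}", "a", "ACGT" * 8, lvl) for lvl in (1, 2, 3, 4)]
    assert [s.spacer_id for s in filter_spacers(spacers)] == ["s3", "s4"]


class TestProphageLinkage:
    def test_prophage_assigned_to_source_assembly(self):
        (a,) = link_prophages([("phageX", "asm42")])
        assert (a.phage_id, a.host_assembly_id, a.method) == ("phageX", "asm42", "prophage")

    def test_missing_assembly_rejected(self):
        with pytest.raises(ValueError, match="missing assembly"):
            link_prophages([("phageX", "")])

    def test_crispr_and_prophage_assignments_dedup_per_pair(self):
        spacers = [Spacer("s1", "asmY", "ACGTACGTACGTACGTACGTACGTA", 3)]
        g = _genome("phageX", "TTTT" + "ACGTACGTACGTACGTACGTACGTA" + "GGGG")
        crispr = crispr_assignments(match_spacers(spacers, [g]), spacers)
        both = crispr + link_prophages([("phageX", "asmX")]) + crispr
        deduped = dedupe_assignments(both)
        assert {(a.phage_id, a.host_assembly_id) for a in deduped} == \
            {("phageX", "asmY"), ("phageX", "asmX")}
        assert len(deduped) == 2


LINEAGES = {
    "caccae": "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
              "f__Bacteroidaceae;g__Bacteroides;s__Bacteroides caccae",
    "xylan": "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
             "f__Bacteroidaceae;g__Bacteroides;s__Bacteroides xylanisolvens B",
    "merdae": "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
              "f__Tannerellaceae;g__Parabacteroides;s__Parabacteroides merdae",
    "faecali": "d__Bacteria;p__Firmicutes;c__Clostridia;o__Oscillospirales;"
               "f__Ruminococcaceae;g__Faecalibacterium;s__Faecalibacterium prausnitzii C",
    "bifido": "d__Bacteria;p__Actinobacteriota;c__Actinomycetia;o__Actinomycetales;"
              "f__Bifidobacteriaceae;g__Bifidobacterium;s__Bifidobacterium longum",
}


class TestHostRange:
    def test_same_species(self):
        assert host_range_rank([LINEAGES["caccae"]] * 3) == "species"

    def test_same_genus_different_species(self):
        assert host_range_rank([LINEAGES["caccae"], LINEAGES["xylan"]]) == "genus"

    def test_same_order_different_family(self):
        assert host_range_rank([LINEAGES["caccae"], LINEAGES["merdae"]]) == "order"

    def test_cross_phylum(self):
        assert host_range_rank([LINEAGES["faecali"], LINEAGES["bifido"]]) == "cross-phylum"

    def test_adding_a_host_only_broadens(self):
        ranks = ["species", "genus", "family", "order", "class", "phylum", "domain"]
        seq = [LINEAGES["caccae"], LINEAGES["xylan"], LINEAGES["merdae"]]
        prev = ranks.index(host_range_rank(seq[:1]))
        for k in (2, 3):
            cur = ranks.index(host_range_rank(seq[:k]))
            assert cur >= prev
            prev = cur

    def test_missing_species_label_caps_depth(self):
        trunc = LINEAGES["caccae"].rsplit("s__", 1)[0] + "s__"
        assert host_range_rank([trunc, LINEAGES["caccae"]]) == "genus"

    def test_inconsistent_lineage_rejected(self):
        bad = LINEAGES["caccae"].replace("p__Bacteroidota", "p__Firmicutes")
        with pytest.raises(ValueError, match="inconsistent"):
            host_range_rank([bad, LINEAGES["xylan"]])

    def test_malformed_lineage_rejected(self):
        with pytest.raises(ValueError, match="7 semicolon"):
            parse_gtdb_lineage("p__Firmicutes;g__Blautia")


class TestVCDiversity:
    def test_vcs_per_isolate_arithmetic(self):
        vc_hosts = {"VC_1": {"i1"}, "VC_2": {"i1", "i2"}, "VC_3": {"i2"}, "VC_4": {"i2"}}
        taxa = {"i1": "Firmicutes", "i2": "Firmicutes", "i3": "Actinobacteriota"}
        df = vc_diversity(vc_hosts, taxa).set_index("taxon")
        assert df.loc["Firmicutes", "vcs_per_isolate"] == pytest.approx(2.0)  # 4 VCs / 2 isolates
        assert df.loc["Actinobacteriota", "vcs_per_isolate"] == 0.0

    def test_shared_vc_counted_once(self):
        vc_hosts = {"VC_1": {"i1", "i2"}}
        df = vc_diversity(vc_hosts, {"i1": "t", "i2": "t"}).set_index("taxon")
        assert df.loc["t", "n_vcs"] == 1

    def test_isolate_without_taxon_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="without taxon"):
            df = vc_diversity({"VC_1": {"i1"}}, {"i1": "t", "i2": None})
        assert df.set_index("taxon").loc["t", "n_isolates"] == 1
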