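"""Assign viral taxonomy by gene-hit consensus and hosts by CRISPR/prophage.

Taxonomy: a contig needs hits on >=20% of genes (or >=2 genes when it
has fewer than 10) and a taxon agreeing across >=60% of hit genes.
Hosts: exact full-length spacer matches (either strand) and prophage
source assemblies; a cluster's host range is the most specific rank
shared by all its hosts.
"""

from phagekit import (GeneTaxHit, assign_taxon, crispr_assignments,
                      dedupe_assignments, host_range_rank, link_prophages,
                      match_spacers)
from phagekit.simulate import gen_crispr_fixture, gen_sequence_family

# --- taxonomy consensus: 3 of 5 hit genes agree (support 0.6, eligible) ---
hits = [GeneTaxHit("ctg1", i, "Siphoviridae", "family", 1e-12, 0.01) for i in range(3)]
hits += [GeneTaxHit("ctg1", i, "Myoviridae", "family", 1e-12, 0.01) for i in (3, 4)]
call = assign_taxon("ctg1", n_genes=20, hits=hits)
print(f"ctg1 -> {call.taxon} ({call.rank}, support {call.support:.0%})")

# --- CRISPR spacers planted in synthetic phages ---
phages, _ = gen_sequence_family(4000, 0.4, 5, seed=8, prefix="phage")
spacers, truth = gen_crispr_fixture(phages, n_planted=5, n_decoys=5, seed=9)
matches = match_spacers(spacers, phages)
print(f"spacer matches: {len(matches)} recovered of {len(truth)} planted, "
      f"decoy hits: {sum(m.spacer_id.startswith('decoy') for m in matches)}")

assignments = crispr_assignments(matches, spacers)
assignments += link_prophages([("phage_000", "asm_cultured_42")])
for a in dedupe_assignments(assignments)[:4]:
    print(f"  {a.phage_id} -> {a.host_assembly_id} ({a.method})")

# --- host range of a viral cluster from its hosts' GTDB lineages ---
lineages = [
    "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
    "f__Bacteroidaceae;g__Bacteroides;s__Bacteroides caccae",
    "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
    "f__Bacteroidaceae;g__Bacteroides;s__Bacteroides xylanisolvens B",
]
print("host range rank:", host_range_rank(lineages))
# Two Bacteroides species -> the cluster is genus-restricted.
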