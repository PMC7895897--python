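"""Screen candidate contigs: predictor selection + human decontamination.

A contig enters the catalog when it is >= 10 kb and either VirSorter
placed it in category 1, 2, 4 or 5, or VirFinder gave it score > 0.9
with p < 0.01; it is then discarded if alignments to the human genome
cover more than 60% of its length.
"""

from phagekit import (AlignmentHit, GenomeRecord, PredictionRecord,
                      human_filter, prophage_ids, select_predictions)

predictions = [
    PredictionRecord("contig_a", "virsorter", 25_000, virsorter_category=1),
    PredictionRecord("contig_b", "virsorter", 30_000, virsorter_category=3),   # rejected
    PredictionRecord("contig_c", "virsorter", 18_000, virsorter_category=4),   # prophage
    PredictionRecord("contig_d", "virfinder", 12_000, virfinder_score=0.97, virfinder_p=0.002),
    PredictionRecord("contig_e", "virfinder", 9_500, virfinder_score=0.99, virfinder_p=0.001),  # < 10 kb
]

selected = select_predictions(predictions)
print("selected contigs:", selected)
print("prophage provenance (VirSorter 4/5):", sorted(prophage_ids(predictions)))

# contig_a turns out to be 70% human sequence -> dropped
contig = GenomeRecord("contig_a", "ACGT" * 2500)  # 10 kb stand-in
human_hits = [AlignmentHit("contig_a", "chr1", 0, 7_000, 0, 7_000, 98.0, 1e-80, 9000.0)]
print("contig_a kept after human filter:", human_filter(contig, human_hits))
# Three contigs pass selection; contig_a is then removed because 70% of
# its length matches the human genome (the rule is strict: >60% drops).
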