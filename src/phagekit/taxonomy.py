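"""Rule-based viral taxonomy consensus from per-gene homology hits.

Each gene of a contig may carry hits against a database of
taxon-specific profile HMMs (pre-filtered upstream at a full-sequence
E-value < 1e-3 and per-domain independent E-value < 0.1).  A contig is
eligible for assignment when at least 20% of its genes have hits — or at
least two genes when the contig has fewer than 10 — and receives the most
specific taxon on which at least 60% of the hit genes agree, walking up
the rank ladder until consensus holds.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

from .config import DEFAULT_CONFIG, ThresholdConfig

# most specific -> least specific
RANKS: Sequence[str] = ("genus", "subfamily", "family", "order", "class", "phylum")

FULL_SEQ_EVALUE_MAX = 1e-3
DOMAIN_IEVALUE_MAX = 0.1

# Taxa that are viral but not phage; contigs assigned to them are purged
# from the catalog (giant amoeba viruses and poxviruses turn up in gut
# assemblies but are not bacteriophages).
NONPHAGE_BLOCKLIST = frozenset({"Mimiviridae", "Poxviridae", "Marseilleviridae"})


@dataclass(frozen=True)
class GeneTaxHit:
    contig_id: str
    gene_index: int
    taxon: str
    rank: str
    full_seq_evalue: float
    domain_ievalue: float
    bitscore: float = 0.0

    def __post_init__(self):
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}; expected one of {list(RANKS)}")
        if self.gene_index < 0:
            raise ValueError(f"negative gene_index {self.gene_index}")


def filter_tax_hits(hits: Iterable[GeneTaxHit]) -> List[GeneTaxHit]:
    """Apply the reporting thresholds (E < 1e-3 full sequence, i-E < 0.1)."""
    return [h for h in hits
            if h.full_seq_evalue < FULL_SEQ_EVALUE_MAX
            and h.domain_ievalue < DOMAIN_IEVALUE_MAX]


@dataclass(frozen=True)
class TaxonCall:
    contig_id: str
    taxon: str          # "unassigned" when no consensus
    rank: Optional[str]
    support: float      # fraction of hit genes agreeing (0 when unassigned)

    @property
    def assigned(self) -> bool:
        return self.taxon != "unassigned"


def assign_taxon(contig_id: str, n_genes: int, hits: Iterable[GeneTaxHit],
                 cfg: ThresholdConfig = DEFAULT_CONFIG,
                 lineage: Mapping[str, Mapping[str, str]] | None = None) -> TaxonCall:
    """Consensus taxon for one contig.

    One vote per gene (its best hit: lowest full-sequence E-value, ties
    by bitscore then taxon name for determinism).  *lineage* optionally
    maps a taxon to its ancestors per rank so votes cast at specific
    ranks also count toward broader ones; without it, votes count only at
    their own rank.  An exact support tie between two taxa at the winning
    rank yields "unassigned".
    """
    if n_genes < 1:
        raise ValueError(f"{contig_id}: contig must have at least 1 gene")
    hits = list(hits)
    for h in hits:
        if h.gene_index >= n_genes:
            raise ValueError(f"{contig_id}: hit references gene {h.gene_index} "
                             f"but contig has {n_genes} genes")

    best: Dict[int, GeneTaxHit] = {}
    for h in hits:
        cur = best.get(h.gene_index)
        if cur is None or (h.full_seq_evalue, -h.bitscore, h.taxon) < \
                (cur.full_seq_evalue, -cur.bitscore, cur.taxon):
            best[h.gene_index] = h
    n_hit = len(best)

    if n_genes < cfg.tax_small_contig:
        eligible = n_hit >= cfg.tax_min_hits
    else:
        eligible = n_hit / n_genes >= cfg.tax_hit_frac
    if not eligible or n_hit == 0:
        return TaxonCall(contig_id, "unassigned", None, 0.0)

    rank_index = {r: i for i, r in enumerate(RANKS)}
    for rank in RANKS:
        votes: Counter = Counter()
        for h in best.values():
            if h.rank == rank:
                votes[h.taxon] += 1
            elif lineage and rank_index[h.rank] < rank_index[rank]:
                ancestor = lineage.get(h.taxon, {}).get(rank)
                if ancestor:
                    votes[ancestor] += 1
        if not votes:
            continue
        top_count = max(votes.values())
        support = top_count / n_hit
        if support >= cfg.tax_consensus:
            winners = [t for t, c in votes.items() if c == top_count]
            if len(winners) > 1:
                return TaxonCall(contig_id, "unassigned", None, 0.0)
            return TaxonCall(contig_id, winners[0], rank, support)
    return TaxonCall(contig_id, "unassigned", None, 0.0)


def exclude_nonphage(calls: Iterable[TaxonCall],
                     blocklist: Set[str] = NONPHAGE_BLOCKLIST) -> List[str]:
    """Contig ids assigned to a blocklisted (non-phage) taxon."""
    return [c.contig_id for c in calls if c.assigned and c.taxon in blocklist]
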