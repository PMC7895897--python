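"""Prediction selection and decontamination rules for candidate contigs.

Selection admits a contig when either upstream predictor supports it:
VirSorter category 1, 2, 4 or 5, or VirFinder score > 0.9 with p < 0.01 —
and the contig is at least 10 kb.  The human filter then discards contigs
whose merged human-genome hits cover strictly more than 60% of their
length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set

from .config import DEFAULT_CONFIG, ThresholdConfig
from .intervals import Interval, covered_fraction
from .records import AlignmentHit, GenomeRecord

PROPHAGE_CATEGORIES = frozenset({4, 5})  # VirSorter "integrated" predictions


@dataclass(frozen=True)
class PredictionRecord:
    """One upstream predictor's verdict on one contig."""

    contig_id: str
    source: str  # "virsorter" | "virfinder"
    length: int
    virsorter_category: Optional[int] = None
    virfinder_score: Optional[float] = None
    virfinder_p: Optional[float] = None

    def __post_init__(self):
        if self.source == "virsorter":
            if self.virsorter_category is None:
                raise ValueError(f"{self.contig_id}: virsorter record lacks a category")
        elif self.source == "virfinder":
            if self.virfinder_score is None or self.virfinder_p is None:
                raise ValueError(f"{self.contig_id}: virfinder record lacks score/p-value")
        else:
            raise ValueError(f"{self.contig_id}: unknown prediction source {self.source!r}")

    def passes(self, cfg: ThresholdConfig) -> bool:
        if self.length < cfg.min_len:
            return False
        if self.source == "virsorter":
            return self.virsorter_category in cfg.virsorter_keep
        return (self.virfinder_score > cfg.virfinder_score
                and self.virfinder_p < cfg.virfinder_p)


def select_predictions(records: Iterable[PredictionRecord],
                       cfg: ThresholdConfig = DEFAULT_CONFIG) -> List[str]:
    """Contig ids passing either predictor's rule, deduplicated, input order."""
    seen: Set[str] = set()
    out: List[str] = []
    for rec in records:
        if rec.passes(cfg) and rec.contig_id not in seen:
            seen.add(rec.contig_id)
            out.append(rec.contig_id)
    return out


def prophage_ids(records: Iterable[PredictionRecord]) -> Set[str]:
    """Contigs with 'integrated' VirSorter provenance (categories 4/5)."""
    return {r.contig_id for r in records
            if r.source == "virsorter" and r.virsorter_category in PROPHAGE_CATEGORIES}


def human_filter(contig: GenomeRecord, hits: Iterable[AlignmentHit],
                 cfg: ThresholdConfig = DEFAULT_CONFIG) -> bool:
    """True = keep the contig; False = drop as human contamination.

    Drop iff the union of query intervals of *hits* covers strictly more
    than ``cfg.human_cov`` of the contig (coverage of exactly the
    threshold keeps the contig).
    """
    intervals = []
    for h in hits:
        if h.query_id != contig.id:
            raise ValueError(f"hit query {h.query_id!r} does not match contig {contig.id!r}")
        if h.q_end > contig.length:
            raise ValueError(f"hit [{h.q_start}, {h.q_end}) outside contig "
                             f"{contig.id!r} of length {contig.length}")
        intervals.append(Interval(h.q_start, h.q_end))
    return covered_fraction(intervals, contig.length) <= cfg.human_cov


def filter_human(contigs: Iterable[GenomeRecord],
                 hits_by_contig: Dict[str, List[AlignmentHit]],
                 cfg: ThresholdConfig = DEFAULT_CONFIG) -> List[GenomeRecord]:
    """Apply :func:`human_filter` across a contig collection."""
    return [c for c in contigs if human_filter(c, hits_by_contig.get(c.id, []), cfg)]
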