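"""Core domain records: genomes, gene annotations and alignment hits."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional

# Product strings counted as "hypothetical" when computing the fraction of
# hypothetical proteins.  The GFFs this mirrors label unannotated genes with
# free text; an empty product is treated the same way.  Case-insensitive
# full-string match; override via the `pattern` argument of GeneAnnotation.
HYPOTHETICAL_PATTERN = re.compile(r"^(hypothetical protein|unknown function|)$", re.IGNORECASE)

_DNA_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene on a genome; 0-based half-open coordinates."""

    start: int
    end: int
    strand: str = "+"
    product: str = ""
    is_hypothetical: bool = field(init=False, default=False)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene coordinates [{self.start}, {self.end}) invalid")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(
            self, "is_hypothetical",
            bool(HYPOTHETICAL_PATTERN.match(self.product.strip())),
        )


@dataclass
class GenomeRecord:
    """A candidate phage/MGE nucleotide sequence with its gene calls."""

    id: str
    seq: str
    genes: List[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        if not _DNA_RE.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValueError(f"genome {self.id!r}: non-ACGTN characters {bad}")
        for g in self.genes:
            if g.end > len(self.seq):
                raise ValueError(
                    f"genome {self.id!r}: gene [{g.start}, {g.end}) outside length {len(self.seq)}"
                )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between two sequences.

    Coordinates are 0-based half-open and strand-normalized: both
    coordinate pairs ascend; a reverse-ordered subject range from a
    tabular alignment file is swapped and recorded as ``strand='-'``.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    pct_identity: float
    evalue: float
    bitscore: float
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.q_start < self.q_end):
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: bad query range")
        if not (0 <= self.s_start < self.s_end):
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: bad subject range")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")

    @classmethod
    def from_blast6(cls, qseqid, sseqid, pident, length, mismatch, gapopen,
                    qstart, qend, sstart, send, evalue, bitscore) -> "AlignmentHit":
        """Build from a BLAST outfmt-6 row (1-based inclusive coordinates)."""
        qstart, qend, sstart, send = int(qstart), int(qend), int(sstart), int(send)
        strand = "+"
        if sstart > send:
            sstart, send = send, sstart
            strand = "-"
        return cls(str(qseqid), str(sseqid), qstart - 1, qend, sstart - 1, send,
                   float(pident), float(evalue), float(bitscore), strand)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
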