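"""Readers and writers for the flat formats the toolkit touches.

FASTA goes through Biopython, GFF3 parsing through gffutils, tables
through pandas.  All coordinate conversion (GFF3 and BLAST tabular are
1-based inclusive; the package is 0-based half-open throughout) happens
here and nowhere else.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Dict, Iterable, List

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import AlignmentHit, GeneAnnotation, GenomeRecord

BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                  "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> Dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    seqs: Dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if rec.id in seqs:
            raise ValueError(f"{path}: record {i}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Dict[str, str] | Iterable[GenomeRecord], path: str | Path,
                width: int = 60) -> None:
    if not isinstance(seqs, dict):
        seqs = {g.id: g.seq for g in seqs}
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(records)


# ---------------------------------------------------------------- GFF3

def read_gff3(path: str | Path) -> Dict[str, List[GeneAnnotation]]:
    """Parse gene features per contig; 1-based inclusive -> 0-based half-open."""
    try:
        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    except Exception as exc:  # gffutils wraps parse errors opaquely
        raise ValueError(f"{path}: unparseable GFF3: {exc}") from exc
    genes: Dict[str, List[GeneAnnotation]] = {}
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in ("gene", "CDS"):
            continue
        product = (feat.attributes.get("product") or [""])[0]
        ann = GeneAnnotation(start=feat.start - 1, end=feat.end,
                             strand=feat.strand if feat.strand in "+-" else "+",
                             product=product)
        genes.setdefault(feat.seqid, []).append(ann)
    return genes


def write_gff3(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genomes:
            fh.write(f"##sequence-region {g.id} 1 {g.length}\n")
            for i, gene in enumerate(g.genes, start=1):
                attrs = f"ID={g.id}_{i};product={gene.product or 'hypothetical protein'}"
                fh.write("\t".join([g.id, "phagekit", "CDS", str(gene.start + 1),
                                    str(gene.end), ".", gene.strand, "0", attrs]) + "\n")


def read_genomes(fasta_path: str | Path, gff_path: str | Path | None = None
                 ) -> List[GenomeRecord]:
    """Assemble GenomeRecords from a FASTA file and an optional GFF3."""
    seqs = read_fasta(fasta_path)
    genes = read_gff3(gff_path) if gff_path else {}
    return [GenomeRecord(id=name, seq=seq, genes=genes.get(name, []))
            for name, seq in seqs.items()]


# ---------------------------------------------------------------- tables

def read_blast6(path: str | Path) -> List[AlignmentHit]:
    """Read a BLAST outfmt-6 table into strand-normalized AlignmentHits."""
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    hits = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            hits.append(AlignmentHit.from_blast6(*row))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return hits


def write_blast6(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits back to outfmt-6 (1-based inclusive, '-' strand reversed)."""
    rows = []
    for h in hits:
        sstart, send = (h.s_end, h.s_start + 1) if h.strand == "-" else (h.s_start + 1, h.s_end)
        aln_len = max(h.q_end - h.q_start, h.s_end - h.s_start)
        rows.append([h.query_id, h.subject_id, h.pct_identity, aln_len, 0, 0,
                     h.q_start + 1, h.q_end, sstart, send, h.evalue, h.bitscore])
    pd.DataFrame(rows, columns=BLAST6_COLUMNS).to_csv(path, sep="\t", header=False, index=False)


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """Long-form covered-fraction table: sample_id, genome_id, covered_fraction."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "genome_id", "covered_fraction"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    return df


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata CSV: sample_id, country, continent, read_count."""
    df = pd.read_csv(path)
    required = {"sample_id", "country", "continent", "read_count"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    return df.set_index("sample_id")
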