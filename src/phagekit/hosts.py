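"""CRISPR-spacer and prophage host assignment, and host-range summaries.

A bacterial CRISPR spacer matching a phage genome verbatim (100%
identity across the spacer's whole length, either strand) records a past
infection and links the phage to the spacer's assembly; prophages are
linked to the assembly they were predicted in.  Host lineages use the
7-rank GTDB semicolon format; a viral cluster's host range is the most
specific rank at which all of its hosts agree.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .records import GenomeRecord, revcomp

ADMITTED_EVIDENCE_LEVELS = frozenset({3, 4})

# GTDB rank prefixes, domain -> species
GTDB_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
GTDB_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class Spacer:
    spacer_id: str
    host_assembly_id: str
    seq: str
    evidence_level: int


def filter_spacers(spacers: Iterable[Spacer]) -> List[Spacer]:
    """Keep spacers from CRISPR arrays with evidence level 3 or 4."""
    return [s for s in spacers if s.evidence_level in ADMITTED_EVIDENCE_LEVELS]


@dataclass(frozen=True)
class HostAssignment:
    phage_id: str
    host_assembly_id: str
    method: str  # "crispr" | "prophage"
    host_lineage: Optional[str] = None


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    phage_id: str
    strand: str
    position: int  # 0-based start on the phage forward strand


def match_spacers(spacers: Iterable[Spacer], genomes: Iterable[GenomeRecord]
                  ) -> List[SpacerMatch]:
    """Exact full-length spacer occurrences in phage genomes, either strand.

    Equivalent to a short-word alignment at 100% identity with a
    full-length filter: zero mismatches, no gaps.  One match per
    (spacer, phage) pair is reported (first occurrence; forward strand
    preferred).  Spacers with non-ACGT characters are skipped with a
    warning.  Genomes are treated as linear.
    """
    genomes = list(genomes)
    matches = []
    for sp in spacers:
        seq = sp.seq.upper()
        if set(seq) - set("ACGT"):
            warnings.warn(f"spacer {sp.spacer_id!r} contains non-ACGT characters; skipped",
                          stacklevel=2)
            continue
        rc = revcomp(seq)
        for g in genomes:
            pos = g.seq.find(seq)
            if pos >= 0:
                matches.append(SpacerMatch(sp.spacer_id, g.id, "+", pos))
                continue
            pos = g.seq.find(rc)
            if pos >= 0:
                matches.append(SpacerMatch(sp.spacer_id, g.id, "-", pos))
    return matches


def crispr_assignments(matches: Iterable[SpacerMatch],
                       spacers: Iterable[Spacer],
                       lineages: Mapping[str, str] | None = None
                       ) -> List[HostAssignment]:
    by_id = {s.spacer_id: s for s in spacers}
    out = []
    for m in matches:
        host = by_id[m.spacer_id].host_assembly_id
        out.append(HostAssignment(m.phage_id, host, "crispr",
                                  (lineages or {}).get(host)))
    return out


def link_prophages(prophages: Iterable[Tuple[str, str]],
                   lineages: Mapping[str, str] | None = None
                   ) -> List[HostAssignment]:
    """One assignment per (prophage_id, source_assembly_id) pair."""
    out = []
    for phage_id, assembly_id in prophages:
        if not assembly_id:
            raise ValueError(f"prophage {phage_id!r}: missing assembly of origin")
        out.append(HostAssignment(phage_id, assembly_id, "prophage",
                                  (lineages or {}).get(assembly_id)))
    return out


def dedupe_assignments(assignments: Iterable[HostAssignment]) -> List[HostAssignment]:
    """Deduplicate per (phage, host) pair; distinct hosts all retained."""
    seen: Set[Tuple[str, str]] = set()
    out = []
    for a in assignments:
        key = (a.phage_id, a.host_assembly_id)
        if key not in seen:
            seen.add(key)
            out.append(a)
    return out


# ------------------------------------------------------------ host range

def parse_gtdb_lineage(lineage: str) -> Dict[str, str]:
    """'d__Bacteria;p__...;s__...' -> {rank: taxon}, empty labels dropped."""
    parts = [p.strip() for p in lineage.split(";")]
    if len(parts) != len(GTDB_PREFIXES):
        raise ValueError(f"expected 7 semicolon-separated ranks, got {lineage!r}")
    out = {}
    for rank, prefix, part in zip(GTDB_RANKS, GTDB_PREFIXES, parts):
        if not part.startswith(prefix):
            raise ValueError(f"rank {rank} should start with {prefix!r} in {lineage!r}")
        name = part[len(prefix):]
        if name:
            out[rank] = name
    return out


def _check_consistency(parsed: Sequence[Dict[str, str]]) -> None:
    # a taxon may not sit under two different parents
    parent_of: Dict[Tuple[str, str], str] = {}
    for lin in parsed:
        for child_rank, parent_rank in zip(GTDB_RANKS[1:][::-1], GTDB_RANKS[:-1][::-1]):
            child, parent = lin.get(child_rank), lin.get(parent_rank)
            if child is None or parent is None:
                continue
            key = (child_rank, child)
            if parent_of.setdefault(key, parent) != parent:
                raise ValueError(f"inconsistent lineages: {child_rank} {child!r} "
                                 f"appears under both {parent_of[key]!r} and {parent!r}")


def host_range_rank(lineages: Sequence[str]) -> str:
    """Most specific rank shared by every host lineage.

    Hosts spanning more than one phylum are labeled "cross-phylum".
    Never returns a rank more specific than the shallowest lineage.
    """
    if not lineages:
        raise ValueError("need at least one host lineage")
    parsed = [parse_gtdb_lineage(l) for l in lineages]
    _check_consistency(parsed)
    phyla = {lin.get("phylum") for lin in parsed}
    if None not in phyla and len(phyla) > 1:
        return "cross-phylum"
    for rank in GTDB_RANKS[::-1]:  # species first
        values = {lin.get(rank) for lin in parsed}
        if None not in values and len(values) == 1:
            return rank
    return "cross-phylum"


# ------------------------------------------------------------ diversity

def vc_diversity(vc_hosts: Mapping[str, Set[str]],
                 isolate_taxon: Mapping[str, Optional[str]]) -> pd.DataFrame:
    """Viral diversity per taxon: distinct VCs with a host in the taxon,
    divided by the taxon's isolate count.

    *vc_hosts* maps vc_id -> host assembly ids; *isolate_taxon* maps every
    isolate to its taxon (None -> excluded with a warning).  Taxa with
    isolates but no assigned VCs report 0.0.
    """
    missing = sorted(i for i, t in isolate_taxon.items() if t is None)
    if missing:
        warnings.warn(f"isolates without taxon excluded: {missing}", stacklevel=2)
    taxon_isolates: Dict[str, Set[str]] = defaultdict(set)
    for isolate, taxon in isolate_taxon.items():
        if taxon is not None:
            taxon_isolates[taxon].add(isolate)
    taxon_vcs: Dict[str, Set[str]] = defaultdict(set)
    for vc_id, hosts in vc_hosts.items():
        for h in hosts:
            taxon = isolate_taxon.get(h)
            if taxon is not None:
                taxon_vcs[taxon].add(vc_id)
    rows = [{"taxon": t, "n_isolates": len(isolates),
             "n_vcs": len(taxon_vcs.get(t, set())),
             "vcs_per_isolate": len(taxon_vcs.get(t, set())) / len(isolates)}
            for t, isolates in sorted(taxon_isolates.items())]
    return pd.DataFrame(rows, columns=["taxon", "n_isolates", "n_vcs", "vcs_per_isolate"])
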