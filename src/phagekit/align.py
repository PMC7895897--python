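"""Pluggable pairwise-alignment backend (edlib) for desk-scale fixtures.

The pipeline's published form consumes tabular hits from an external
all-vs-all aligner; this module supplies the minimal built-in backend the
synthetic fixtures need — pairwise identity for dereplication and single
best local hits for the viral-cluster coverage graph.  Both entry points
accept a replacement callable, so an external aligner's output can be
dropped in unchanged.
"""

from __future__ import annotations

from typing import Tuple

import edlib

from .records import AlignmentHit


def pairwise_identity(seq_a: str, seq_b: str, mode: str = "global") -> Tuple[float, float]:
    """Return ``(identity, aligned_fraction_of_shorter)`` for two sequences.

    mode="global": end-to-end alignment; identity = 1 - edits/len(longer);
    aligned fraction is 1 by construction.
    mode="local": the shorter sequence is aligned as an infix of the
    longer (free end-gaps on the longer), matching the fragment-vs-parent
    comparisons species-level dereplication needs; identity is computed
    over the shorter sequence, which is aligned in full.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    short, long_ = sorted((seq_a.upper(), seq_b.upper()), key=len)
    if mode == "global":
        res = edlib.align(short, long_, mode="NW")
        ident = 1.0 - res["editDistance"] / max(len(long_), 1)
    else:
        res = edlib.align(short, long_, mode="HW")
        ident = 1.0 - res["editDistance"] / max(len(short), 1)
    return max(ident, 0.0), 1.0


def align_pair(id_a: str, seq_a: str, id_b: str, seq_b: str,
               min_identity: float = 0.5) -> list[AlignmentHit]:
    """Produce the best local hit between two sequences as an AlignmentHit.

    The shorter sequence is aligned as an infix of the longer on the
    forward strand, then on the reverse complement; the better alignment
    is reported (empty list if identity falls below *min_identity*).
    Fixture genomes are generated indel-free, so a single infix alignment
    captures the aligned fraction exactly.
    """
    from .records import revcomp

    a_short = len(seq_a) <= len(seq_b)
    short_id, short_seq = (id_a, seq_a) if a_short else (id_b, seq_b)
    long_id, long_seq = (id_b, seq_b) if a_short else (id_a, seq_a)

    best = None
    for strand, target in (("+", long_seq), ("-", revcomp(long_seq))):
        res = edlib.align(short_seq, target, mode="HW", task="locations")
        if best is None or res["editDistance"] < best[0]["editDistance"]:
            best = (res, strand, target)
    res, strand, target = best
    ident = 1.0 - res["editDistance"] / len(short_seq)
    if ident < min_identity or not res["locations"]:
        return []
    loc_s, loc_e = res["locations"][0]
    s_start, s_end = loc_s, loc_e + 1
    if strand == "-":  # map back onto the forward strand of the long sequence
        s_start, s_end = len(long_seq) - s_end, len(long_seq) - s_start
    matches = round(ident * len(short_seq))
    return [AlignmentHit(query_id=short_id, subject_id=long_id,
                         q_start=0, q_end=len(short_seq),
                         s_start=s_start, s_end=s_end,
                         pct_identity=100.0 * ident, evalue=1e-30,
                         bitscore=2.0 * matches, strand=strand)]
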