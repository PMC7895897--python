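"""Feature extraction for the phage-vs-ICE classifier.

Each genome is summarized by 1026 numbers: gene density (genes per kb),
fraction of hypothetical proteins, and the relative frequencies of all
4^5 = 1024 DNA 5-mers in fixed lexicographic order, counted on the given
strand (no canonical collapsing — collapsing would halve the dimension).
Windows containing N are skipped and the remaining counts renormalized.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, List

import numpy as np

from .records import GenomeRecord

K = 5
KMERS: List[str] = ["".join(p) for p in product("ACGT", repeat=K)]
N_FEATURES = 2 + len(KMERS)

_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def feature_names() -> List[str]:
    return ["gene_density", "hypothetical_frac"] + [f"kmer_{k}" for k in KMERS]


def kmer_frequencies(seq: str) -> np.ndarray:
    """Relative frequencies of all 1024 5-mers (zeros if no valid window)."""
    codes = _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    n = len(codes) - K + 1
    if n <= 0:
        return np.zeros(len(KMERS))
    windows = np.lib.stride_tricks.sliding_window_view(codes, K)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return np.zeros(len(KMERS))
    powers = 4 ** np.arange(K - 1, -1, -1, dtype=np.int64)
    idx = windows[valid] @ powers
    counts = np.bincount(idx, minlength=len(KMERS)).astype(float)
    return counts / counts.sum()


def extract_features(genome: GenomeRecord) -> np.ndarray:
    """1026-dim feature vector [gene_density, hypothetical_frac, 5-mer freqs]."""
    if genome.length < K:
        raise ValueError(f"genome {genome.id!r}: length {genome.length} < {K} bp")
    n_genes = len(genome.genes)
    gene_density = n_genes / (genome.length / 1000.0)
    hyp_frac = (sum(g.is_hypothetical for g in genome.genes) / n_genes) if n_genes else 0.0
    return np.concatenate([[gene_density, hyp_frac], kmer_frequencies(genome.seq)])


def feature_matrix(genomes: Iterable[GenomeRecord]) -> np.ndarray:
    return np.vstack([extract_features(g) for g in genomes])
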