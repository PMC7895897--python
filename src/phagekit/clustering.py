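"""Genome dereplication, viral-cluster (VC) construction and protein clustering.

Dereplication is greedy longest-first clustering in the CD-HIT style: a
global 99%-identity pass collapses near-duplicates, then a species-level
pass groups sequences at 95% identity over a local alignment covering at
least 75% of the shorter sequence.

VCs are built from all-vs-all alignment hits: per unordered pair, hits at
E <= 0.001 and >= 90% identity are projected onto the shorter sequence
and merged; pairs covering > 75% of it become edges of an unweighted
graph, which Markov Clustering at inflation 6.0 partitions into VCs
(singletons excluded from the reported set).  The same engine clusters
the proteome, after which shared-protein-cluster fractions between
genomes resolve genus/subfamily structure within a clade.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage

from .align import pairwise_identity
from .config import DEFAULT_CONFIG, ThresholdConfig
from .intervals import Interval, covered_fraction
from .mcl import mcl
from .records import AlignmentHit


@dataclass
class SequenceCluster:
    representative_id: str
    member_ids: Set[str]
    level: str  # "global99" | "species95" | "vc"

    def __post_init__(self):
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member of its cluster")


@dataclass
class ViralCluster:
    vc_id: str
    member_ids: frozenset
    is_singleton: bool = field(init=False)

    def __post_init__(self):
        self.is_singleton = len(self.member_ids) == 1


@dataclass
class ProteinCluster:
    pc_id: str
    member_ids: frozenset


# ------------------------------------------------------------ dereplication

IdentityBackend = Callable[[str, str, str], Tuple[float, float]]


def dereplicate(seqs: Mapping[str, str], identity: float, mode: str = "global",
                cfg: ThresholdConfig = DEFAULT_CONFIG,
                backend: IdentityBackend = pairwise_identity) -> List[SequenceCluster]:
    """Greedy longest-first clustering at an identity threshold.

    Sequences are visited by decreasing length (ties broken
    lexicographically by id) and join the first existing representative
    they match: in "global" mode at >= *identity* over the end-to-end
    alignment; in "local" mode at >= *identity* over a local alignment
    that must cover >= ``cfg.species_af`` of the shorter sequence.
    Non-matching sequences found new clusters.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError(f"identity must be in (0, 1], got {identity}")
    if not seqs:
        raise ValueError("no sequences to dereplicate")
    level = "global99" if mode == "global" else "species95"
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    clusters: List[SequenceCluster] = []
    for sid in order:
        for cl in clusters:
            ident, af = backend(seqs[sid], seqs[cl.representative_id], mode)
            if ident >= identity and (mode == "global" or af >= cfg.species_af):
                cl.member_ids.add(sid)
                break
        else:
            clusters.append(SequenceCluster(sid, {sid}, level))
    return clusters


# ------------------------------------------------------------ VC graph

def pair_coverage(hits: Iterable[AlignmentHit], id_a: str, id_b: str,
                  len_a: int, len_b: int,
                  cfg: ThresholdConfig = DEFAULT_CONFIG) -> float:
    """Fraction of the shorter sequence covered by qualifying hits.

    Hits from either direction (A->B or B->A) with E-value within
    ``cfg.pair_evalue`` and identity >= ``cfg.vc_identity`` are projected
    onto the shorter of the two sequences, merged, and measured.
    """
    if id_a == id_b:
        raise ValueError("pair coverage is defined between two distinct sequences")
    short_id, short_len = (id_a, len_a) if (len_a, id_a) <= (len_b, id_b) else (id_b, len_b)
    intervals = []
    for h in hits:
        if {h.query_id, h.subject_id} != {id_a, id_b}:
            raise ValueError(f"hit {h.query_id}->{h.subject_id} is not between "
                             f"{id_a!r} and {id_b!r}")
        if h.evalue > cfg.pair_evalue or h.pct_identity < cfg.vc_identity:
            continue
        s, e = (h.q_start, h.q_end) if h.query_id == short_id else (h.s_start, h.s_end)
        s, e = max(s, 0), min(e, short_len)
        if s < e:
            intervals.append(Interval(s, e))
    if not intervals:
        return 0.0
    return covered_fraction(intervals, short_len)


def build_vc_graph(coverages: Iterable[Tuple[str, str, float]],
                   nodes: Iterable[str] = (),
                   cfg: ThresholdConfig = DEFAULT_CONFIG) -> nx.Graph:
    """Unweighted graph with an edge per pair with coverage strictly > 75%."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b, cov in coverages:
        g.add_nodes_from((a, b))
        if a != b and cov > cfg.vc_coverage:
            g.add_edge(a, b, weight=1.0)
    return g


def vc_graph_from_hits(hits: Iterable[AlignmentHit], lengths: Mapping[str, int],
                       cfg: ThresholdConfig = DEFAULT_CONFIG) -> nx.Graph:
    """Group all-vs-all hits per unordered pair and build the VC graph."""
    by_pair: Dict[frozenset, List[AlignmentHit]] = defaultdict(list)
    for h in hits:
        if h.query_id != h.subject_id:  # self-hits carry no pairing information
            by_pair[frozenset((h.query_id, h.subject_id))].append(h)
    coverages = []
    for pair, pair_hits in sorted(by_pair.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(pair)
        coverages.append((a, b, pair_coverage(pair_hits, a, b, lengths[a], lengths[b], cfg)))
    return build_vc_graph(coverages, nodes=lengths.keys(), cfg=cfg)


def viral_clusters(graph: nx.Graph, cfg: ThresholdConfig = DEFAULT_CONFIG,
                   inflation: float | None = None) -> List[ViralCluster]:
    """MCL partition of the VC graph, labeled VC_1, VC_2, ... by size."""
    partition = mcl(graph, inflation=inflation or cfg.mcl_inflation)
    return [ViralCluster(f"VC_{i}", members)
            for i, members in enumerate(partition, start=1)]


def non_singleton(vcs: Iterable[ViralCluster]) -> List[ViralCluster]:
    return [vc for vc in vcs if not vc.is_singleton]


# ------------------------------------------------------------ proteins

def bitscore_similarity(hits: Iterable[AlignmentHit],
                        cfg: ThresholdConfig = DEFAULT_CONFIG
                        ) -> List[Tuple[str, str, float]]:
    """Pairwise protein similarity: bitscore normalized by max self-bitscore.

    A pluggable stand-in for a hybrid identity/coverage/bitscore metric;
    any ``(a, b, similarity)`` iterable can be fed to
    :func:`cluster_proteins` instead.  Hits above ``cfg.pair_evalue`` are
    ignored; pairs are symmetrized by their best hit in either direction.
    """
    self_score: Dict[str, float] = {}
    best: Dict[frozenset, float] = {}
    kept = []
    for h in hits:
        if h.evalue > cfg.pair_evalue:
            continue
        if h.query_id == h.subject_id:
            self_score[h.query_id] = max(self_score.get(h.query_id, 0.0), h.bitscore)
        else:
            kept.append(h)
    out = []
    for h in kept:
        denom = max(self_score.get(h.query_id, 0.0), self_score.get(h.subject_id, 0.0))
        sim = h.bitscore / denom if denom > 0 else 0.0
        key = frozenset((h.query_id, h.subject_id))
        best[key] = max(best.get(key, 0.0), min(sim, 1.0))
    return [(a, b, s) for (a, b), s in
            sorted(((tuple(sorted(k)), v) for k, v in best.items()))]


def cluster_proteins(similarities: Iterable[Tuple[str, str, float]],
                     proteins: Iterable[str] = (),
                     cfg: ThresholdConfig = DEFAULT_CONFIG,
                     inflation: float | None = None,
                     tol: float = 1e-9) -> List[ProteinCluster]:
    """MCL on the protein-similarity graph; single-member clusters removed.

    Duplicate (a, b) and (b, a) entries must agree within *tol*.
    """
    g = nx.Graph()
    g.add_nodes_from(proteins)
    for a, b, sim in similarities:
        if sim < 0:
            raise ValueError(f"negative similarity {sim} for pair ({a}, {b})")
        if a == b:
            continue
        if g.has_edge(a, b) and abs(g[a][b]["weight"] - sim) > tol:
            raise ValueError(f"asymmetric similarity for pair ({a}, {b}): "
                             f"{g[a][b]['weight']} vs {sim}")
        g.add_edge(a, b, weight=sim)
    partition = mcl(g, inflation=inflation or cfg.mcl_inflation)
    clusters = [c for c in partition if len(c) > 1]
    return [ProteinCluster(f"PC_{i}", members)
            for i, members in enumerate(clusters, start=1)]


# ------------------------------------------------------------ clade structure

def shared_protein_fraction(clusters_a: Set[str], clusters_b: Set[str]) -> float:
    """|shared protein clusters| / |union| between two genomes' cluster sets."""
    union = clusters_a | clusters_b
    if not union:
        raise ValueError("both genomes have empty protein-cluster sets")
    return len(clusters_a & clusters_b) / len(union)


@dataclass
class CladeHierarchy:
    genome_ids: List[str]
    share_matrix: np.ndarray            # pairwise shared-protein fractions
    linkage: np.ndarray                 # scipy average-linkage on the rows
    genus: Dict[str, int]               # components at share > genus_share_hi
    subfamily: Dict[str, int]           # components at share > genus_share_lo


def clade_hierarchy(genome_to_clusters: Mapping[str, Set[str]],
                    cfg: ThresholdConfig = DEFAULT_CONFIG) -> CladeHierarchy:
    """Genus/subfamily structure from shared-protein-cluster fractions.

    Genomes sharing more than ``genus_share_hi`` of protein clusters are
    placed in one genus; pairs in the open band (lo, hi) fall in the same
    subfamily but different genera.  A dendrogram (average linkage,
    Euclidean metric, over rows of the shared-fraction matrix)
    accompanies the discrete calls.  Genomes with no clustered proteins
    are excluded with a warning.
    """
    ids = sorted(genome_to_clusters)
    empty = [i for i in ids if not genome_to_clusters[i]]
    if empty:
        warnings.warn(f"genomes with no clustered proteins excluded: {empty}",
                      stacklevel=2)
        ids = [i for i in ids if i not in set(empty)]
    if len(ids) < 2:
        raise ValueError("need at least 2 genomes with clustered proteins")
    n = len(ids)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = shared_protein_fraction(
                genome_to_clusters[ids[i]], genome_to_clusters[ids[j]])
    Z = linkage(S, method="average", metric="euclidean")

    def components(threshold: float) -> Dict[str, int]:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if S[i, j] > threshold:
                    g.add_edge(i, j)
        labels = {}
        for k, comp in enumerate(sorted(nx.connected_components(g), key=min), start=1):
            for i in comp:
                labels[ids[i]] = k
        return labels

    return CladeHierarchy(ids, S, Z,
                          genus=components(cfg.genus_share_hi),
                          subfamily=components(cfg.genus_share_lo))
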