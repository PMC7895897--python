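"""Single home for every numeric threshold used by the pipeline.

All the screening, clustering, annotation and profiling rules in this
package are threshold comparisons; keeping the constants in one frozen
dataclass makes the strictness of each comparison (strict ``>`` vs
inclusive ``>=``) auditable in one place.  Individual operations document
which side of the boundary they take.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class ThresholdConfig:
    """Pipeline thresholds.

    Attributes
    ----------
    min_len : int
        Minimum contig length (bp) for a viral prediction to be retained
        (inclusive: "at least 10 kb").
    virfinder_score, virfinder_p : float
        VirFinder acceptance requires score strictly above and p strictly
        below these values.
    virsorter_keep : frozenset[int]
        VirSorter categories accepted (1, 2 = free phage; 4, 5 = prophage).
    human_cov : float
        A contig is discarded when merged human-genome hits cover strictly
        more than this fraction of its length.
    derep_global_id : float
        Global nucleotide identity for the first dereplication pass.
    species_id, species_af : float
        Species-level dereplication: identity over a local alignment
        covering at least this fraction of the shorter sequence.
    vc_identity : float
        Percent identity floor (inclusive) for alignment segments counted
        toward viral-cluster pair coverage.
    vc_coverage : float
        Pair coverage must be strictly greater than this to create a
        viral-cluster graph edge.
    mcl_inflation : float
        Inflation exponent for Markov Clustering.
    pair_evalue : float
        E-value ceiling (inclusive) for all-vs-all alignment hits.
    tax_hit_frac, tax_small_contig, tax_min_hits, tax_consensus : thresholds
        Taxonomy eligibility (>=20% of genes with hits, or >=2 hits when
        the contig has fewer than 10 genes) and consensus (>=60% of hit
        genes agreeing).
    target_fpr : float
        Operating false-positive rate allowed when flagging ICEs (a false
        positive is a true phage flagged as ICE).
    presence_cov : float
        A genome is present in a sample when reads cover strictly more
        than this fraction of its length.
    min_depth : float
        Samples with fewer reads than this are dropped from profiling.
    global_continents : int
        A viral cluster is "global" when detected on at least this many
        continents.
    genus_share_lo, genus_share_hi : float
        Shared-protein-cluster fractions bounding the same-subfamily /
        different-genus band; above the upper bound is a same-genus call.
    """

    min_len: int = 10_000
    virfinder_score: float = 0.9
    virfinder_p: float = 0.01
    virsorter_keep: frozenset = frozenset({1, 2, 4, 5})
    human_cov: float = 0.60
    derep_global_id: float = 0.99
    species_id: float = 0.95
    species_af: float = 0.75
    vc_identity: float = 90.0
    vc_coverage: float = 0.75
    mcl_inflation: float = 6.0
    pair_evalue: float = 0.001
    tax_hit_frac: float = 0.20
    tax_small_contig: int = 10
    tax_min_hits: int = 2
    tax_consensus: float = 0.60
    target_fpr: float = 0.0025
    presence_cov: float = 0.75
    min_depth: float = 5e7
    global_continents: int = 5
    genus_share_lo: float = 0.20
    genus_share_hi: float = 0.40

    def __post_init__(self):
        for name in ("human_cov", "derep_global_id", "species_id", "species_af",
                     "vc_coverage", "tax_hit_frac", "tax_consensus", "target_fpr",
                     "presence_cov", "genus_share_lo", "genus_share_hi",
                     "virfinder_score", "virfinder_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} must be a fraction in [0, 1]")
        if not 0.0 <= self.vc_identity <= 100.0:
            raise ValueError(f"vc_identity={self.vc_identity!r} must be a percentage in [0, 100]")

    def replace(self, **kwargs) -> "ThresholdConfig":
        return dataclasses.replace(self, **kwargs)


DEFAULT_CONFIG = ThresholdConfig()

_INT_FIELDS = {"min_len", "tax_small_contig", "tax_min_hits", "global_continents"}


def load_config(path: str | Path, base: ThresholdConfig | None = None) -> ThresholdConfig:
    """Read ``key = value`` overrides (``#`` comments allowed) on top of *base*.

    ``virsorter_keep`` takes a comma-separated list of categories.
    Unknown keys raise ``ValueError`` naming the file and line.
    """
    base = base or DEFAULT_CONFIG
    names = {f.name for f in dataclasses.fields(ThresholdConfig)}
    overrides: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = (s.strip() for s in line.partition("="))
        if key not in names:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if key == "virsorter_keep":
            overrides[key] = frozenset(int(x) for x in value.split(","))
        elif key in _INT_FIELDS:
            overrides[key] = int(value)
        else:
            overrides[key] = float(value)
    return base.replace(**overrides)
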