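"""Synthetic-data generators with planted ground truth.

Every pipeline stage gets a generator that emulates its real input at
desk scale: labeled phage/ICE genome sets for the classifier, mutated
sequence families for dereplication and viral-cluster construction,
CRISPR spacer collections for host assignment, and per-sample coverage
tables for phageome profiling.  Each generator is a pure function of its
seed and parameters and emits machine-readable truth alongside the data,
so downstream tests consume planted truth rather than re-deriving it.

Class differences in the phage/ICE generator follow the directions seen
in real mobile-element corpora — phages are gene-dense with fewer
hypothetical proteins, conjugative elements sparser with more — but the
gaps are deliberately wider than in real data, so classifier checks
exercise the machinery rather than the biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .records import GeneAnnotation, GenomeRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MIN_GENE_LEN = 100

PRODUCT_POOL = (
    "terminase large subunit", "portal protein", "major capsid protein",
    "tail fiber protein", "tape measure protein", "integrase",
    "DNA polymerase I", "DNA primase", "DNA helicase", "holin",
    "endolysin", "single-stranded DNA-binding protein", "dUTPase",
    "thymidylate kinase", "homing endonuclease", "peptidase",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the labeled phage/ICE genome generator."""

    rng_seed: int = 17
    n_phage: int = 400
    n_ice: int = 400
    genome_length_range: Tuple[int, int] = (8_000, 16_000)
    phage_gene_density_mean: float = 1.4      # genes per kb
    ice_gene_density_mean: float = 0.9
    gene_density_sd: float = 0.15
    phage_hypothetical_mean: float = 0.45
    ice_hypothetical_mean: float = 0.75
    hypothetical_sd: float = 0.08
    spacer_length_range: Tuple[int, int] = (25, 45)
    # covered-fraction noise: present ~ Beta(hi), absent ~ Beta(lo)
    beta_present: Tuple[float, float] = (25.0, 3.0)
    beta_absent: Tuple[float, float] = (2.0, 30.0)


def _class_transitions(seed: int, class_index: int) -> np.ndarray:
    """Class-specific first-order Markov transition matrix (rows stochastic)."""
    rng = np.random.default_rng([seed, class_index])
    # blend a Dirichlet draw with uniform so chains stay ergodic but the
    # resulting 5-mer spectra separate cleanly between classes
    raw = rng.dirichlet(np.full(4, 2.0), size=4)
    return 0.4 * 0.25 + 0.6 * raw


def _markov_sequences(T: np.ndarray, lengths: np.ndarray,
                      rng: np.random.Generator) -> List[str]:
    """Sample a batch of Markov-chain sequences (vectorized across the batch)."""
    n, L = len(lengths), int(lengths.max())
    cum = np.cumsum(T, axis=1)
    states = np.empty((n, L), dtype=np.int8)
    states[:, 0] = rng.integers(0, 4, size=n)
    U = rng.random((n, L))
    for pos in range(1, L):
        c = cum[states[:, pos - 1]]
        states[:, pos] = (U[:, pos, None] < c).argmax(axis=1)
    return [_BASES[states[i, :lengths[i]]].tobytes().decode() for i in range(n)]


def _place_genes(length: int, density_per_kb: float, hypothetical_frac: float,
                 rng: np.random.Generator) -> List[GeneAnnotation]:
    n_genes = max(1, round(density_per_kb * length / 1000.0))
    if n_genes * _MIN_GENE_LEN > length:
        raise ValueError(f"infeasible gene density: {n_genes} genes of >= "
                         f"{_MIN_GENE_LEN} bp cannot fit in {length} bp")
    slot = length // n_genes
    genes = []
    for i in range(n_genes):
        glen = max(_MIN_GENE_LEN, int(slot * rng.uniform(0.6, 0.9)))
        start = i * slot + rng.integers(0, max(slot - glen, 1))
        product = ("hypothetical protein" if rng.random() < hypothetical_frac
                   else str(rng.choice(PRODUCT_POOL)))
        genes.append(GeneAnnotation(start=int(start), end=int(start + glen),
                                    strand="+" if rng.random() < 0.5 else "-",
                                    product=product))
    return genes


def gen_mge_set(spec: FixtureSpec = FixtureSpec()
                ) -> Tuple[List[GenomeRecord], Dict[str, str]]:
    """Labeled phage/ICE genomes with planted class differences.

    Returns (genomes, labels) with labels in {"phage", "ICE"}.  Phage and
    ICE sequences come from distinct seeded Markov chains; gene density
    and hypothetical fraction are drawn around class means.
    """
    if spec.n_phage < 1 or spec.n_ice < 1:
        raise ValueError("need at least 1 genome per class (use the single-class "
                         "error path explicitly if that is the point)")
    rng = np.random.default_rng(spec.rng_seed)
    genomes: List[GenomeRecord] = []
    labels: Dict[str, str] = {}
    lo, hi = spec.genome_length_range
    for class_index, (label, n, dens, hyp) in enumerate([
            ("phage", spec.n_phage, spec.phage_gene_density_mean, spec.phage_hypothetical_mean),
            ("ICE", spec.n_ice, spec.ice_gene_density_mean, spec.ice_hypothetical_mean)]):
        T = _class_transitions(spec.rng_seed, class_index)
        lengths = rng.integers(lo, hi + 1, size=n)
        seqs = _markov_sequences(T, lengths, rng)
        for i, seq in enumerate(seqs):
            d = max(0.2, rng.normal(dens, spec.gene_density_sd))
            h = float(np.clip(rng.normal(hyp, spec.hypothetical_sd), 0.0, 1.0))
            gid = f"{label.lower()}_{i:04d}"
            genomes.append(GenomeRecord(id=gid, seq=seq,
                                        genes=_place_genes(len(seq), d, h, rng)))
            labels[gid] = label
    return genomes, labels


def gen_single_class_set(spec: FixtureSpec) -> Tuple[List[GenomeRecord], Dict[str, str]]:
    """One-class variant (for exercising the classifier's error path)."""
    one = FixtureSpec(rng_seed=spec.rng_seed, n_phage=spec.n_phage, n_ice=1,
                      genome_length_range=spec.genome_length_range)
    genomes, labels = gen_mge_set(one)
    genomes = [g for g in genomes if labels[g.id] == "phage"]
    return genomes, {g.id: "phage" for g in genomes}


# ------------------------------------------------------------ families

def expected_pairwise_identity(divergence: float) -> float:
    """Expected identity between two copies mutated independently at rate d.

    A site matches when neither copy mutated, (1-d)^2, or both mutated to
    the same of the 3 alternative bases, d^2/3.
    """
    d = divergence
    return (1 - d) ** 2 + d ** 2 / 3


def gen_sequence_family(ancestor_length: int, divergence: float, n: int,
                        seed: int = 0, prefix: str = "fam"
                        ) -> Tuple[List[GenomeRecord], pd.DataFrame]:
    """n copies of a random ancestor with point substitutions at rate d.

    No indels, so realized identity is analytically controllable.  The
    returned truth table gives, per unordered pair, whether the copies
    are expected to co-cluster at the global-99%, species-95% and
    VC-90% levels (from the expected pairwise identity).
    """
    if not 0.0 <= divergence <= 0.5:
        raise ValueError(f"divergence must be in [0, 0.5], got {divergence}")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=ancestor_length).astype(np.int8)
    records = []
    for i in range(n):
        copy = ancestor.copy()
        mutate = rng.random(ancestor_length) < divergence
        # shift by 1..3 mod 4: always a different base
        copy[mutate] = (copy[mutate] + rng.integers(1, 4, size=int(mutate.sum()))) % 4
        records.append(GenomeRecord(id=f"{prefix}_{i:03d}",
                                    seq=_BASES[copy].tobytes().decode()))
    p = expected_pairwise_identity(divergence)
    rows = [{"id_a": records[i].id, "id_b": records[j].id,
             "expected_identity": p,
             "same_global99": p >= 0.99, "same_species95": p >= 0.95,
             "same_vc": p >= 0.90}
            for i in range(n) for j in range(i + 1, n)]
    truth = pd.DataFrame(rows, columns=["id_a", "id_b", "expected_identity",
                                        "same_global99", "same_species95", "same_vc"])
    return records, truth


# ------------------------------------------------------------ CRISPR

def gen_crispr_fixture(genomes: Sequence[GenomeRecord], n_planted: int = 50,
                       n_decoys: int = 50, seed: int = 0,
                       length_range: Tuple[int, int] = (25, 45)):
    """Spacers planted verbatim in phage genomes plus shuffle decoys.

    Half the planted spacers are stored reverse-complemented.  Decoys are
    random sequences verified to differ from every genome window on both
    strands.  Returns (spacers, truth) where truth is the set of
    (spacer_id, phage_id) pairs that must be recovered.
    """
    from .hosts import Spacer

    rng = np.random.default_rng(seed)
    lo, hi = length_range
    eligible = [g for g in genomes if g.length >= hi]
    if not eligible:
        raise ValueError(f"no genome long enough for a {hi} bp spacer")
    spacers: List[Spacer] = []
    truth: Set[Tuple[str, str]] = set()
    haystacks = [(g.id, g.seq, revcomp(g.seq)) for g in genomes]

    def occurs_in(seq: str) -> List[str]:
        return [gid for gid, fwd, rc in haystacks if seq in fwd or seq in rc]

    i = 0
    while len(truth) < n_planted:
        g = eligible[int(rng.integers(len(eligible)))]
        length = int(rng.integers(lo, hi + 1))
        pos = int(rng.integers(0, g.length - length + 1))
        frag = g.seq[pos:pos + length]
        if occurs_in(frag) != [g.id]:  # avoid cross-genome coincidences
            continue
        stored = revcomp(frag) if i % 2 else frag
        sid = f"spacer_{i:03d}"
        spacers.append(Spacer(sid, f"asm_{i:03d}", stored,
                              evidence_level=int(rng.choice([3, 4]))))
        truth.add((sid, g.id))
        i += 1
    for j in range(n_decoys):
        while True:
            length = int(rng.integers(lo, hi + 1))
            seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
            if not occurs_in(seq):
                break
        spacers.append(Spacer(f"decoy_{j:03d}", f"asm_d{j:03d}", seq,
                              evidence_level=int(rng.choice([3, 4]))))
    return spacers, truth


# ------------------------------------------------------------ coverage tables

RURAL = ("Africa", "South America", "Oceania")
URBAN = ("Asia", "Europe", "North America")


def gen_coverage_table(n_samples_per_continent: int = 10, n_genomes: int = 40,
                       n_vcs: int = 8, seed: int = 0, noiseless: bool = False,
                       p_present: float = 0.8, frac_shallow: float = 0.0,
                       beta_present: Tuple[float, float] = FixtureSpec().beta_present,
                       beta_absent: Tuple[float, float] = FixtureSpec().beta_absent):
    """Per-sample covered fractions with two planted continent groups.

    Continents split into a rural and an urban group with disjoint VC
    repertoires; samples carry each in-repertoire genome with probability
    *p_present*.  Present entries draw covered fraction from
    Beta(beta_present) (concentrated above 0.75), absent entries from
    Beta(beta_absent) (concentrated well below); ``noiseless=True`` uses
    exact 1.0/0.0.  *frac_shallow* of samples get read counts under the
    50-million depth floor.

    Returns (coverage, meta, truth, genome_to_vc): a long-form coverage
    table, sample metadata, the planted boolean presence matrix, and the
    genome -> VC map.
    """
    rng = np.random.default_rng(seed)
    genome_ids = [f"g_{i:03d}" for i in range(n_genomes)]
    vc_ids = [f"VC_{i + 1}" for i in range(n_vcs)]
    genome_to_vc = pd.Series({g: vc_ids[i % n_vcs] for i, g in enumerate(genome_ids)})
    rural_vcs = set(vc_ids[: n_vcs // 2])

    samples, continents, countries = [], [], []
    for cont in RURAL + URBAN:
        for k in range(n_samples_per_continent):
            samples.append(f"s_{cont[:2].upper()}_{k:03d}")
            continents.append(cont)
            countries.append(f"{cont}_country")
    n_samples = len(samples)
    shallow = rng.random(n_samples) < frac_shallow
    read_count = np.where(shallow,
                          rng.integers(1e7, 5e7, size=n_samples),
                          rng.integers(5e7, 2e8, size=n_samples))
    meta = pd.DataFrame({"country": countries, "continent": continents,
                         "read_count": read_count},
                        index=pd.Index(samples, name="sample_id"))

    in_repertoire = np.array([[genome_to_vc[g] in rural_vcs if cont in RURAL
                               else genome_to_vc[g] not in rural_vcs
                               for g in genome_ids] for cont in continents])
    truth_vals = in_repertoire & (rng.random((n_samples, n_genomes)) < p_present)
    truth = pd.DataFrame(truth_vals, index=meta.index, columns=genome_ids)

    if noiseless:
        frac = truth_vals.astype(float)
    else:
        hi = rng.beta(*beta_present, size=truth_vals.shape)
        lo = rng.beta(*beta_absent, size=truth_vals.shape)
        frac = np.where(truth_vals, hi, lo)
    coverage = pd.DataFrame({
        "sample_id": np.repeat(samples, n_genomes),
        "genome_id": genome_ids * n_samples,
        "covered_fraction": frac.ravel(),
    })
    return coverage, meta, truth, genome_to_vc
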