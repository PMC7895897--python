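"""Presence/absence phageome profiling across metagenome samples.

A genome is called present in a sample when mapped reads cover strictly
more than 75% of its length; shallow samples (below 50 million reads)
are removed before between-sample comparisons because detection scales
with depth below that point.  Phageomes are compared at the
viral-cluster level with Jaccard distances, embedded by PCA, and
summarized as continent-level prevalence and globally-distributed VCs
(detected on at least 5 continents).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .config import DEFAULT_CONFIG, ThresholdConfig

CONTINENTS = ("Africa", "Asia", "Europe", "North America", "South America", "Oceania")


@dataclass
class PresenceMatrix:
    """Boolean samples x genomes calls plus sample metadata and a VC map."""

    presence: pd.DataFrame               # bool, index=sample_id, columns=genome_id
    meta: pd.DataFrame                   # index=sample_id: country, continent, read_count
    genome_to_vc: Optional[pd.Series] = None  # genome_id -> vc_id

    def __post_init__(self):
        missing = self.presence.index.difference(self.meta.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)[:5]}")
        if self.genome_to_vc is not None:
            mapped = self.presence.columns.intersection(self.genome_to_vc.index)
            self.genome_to_vc = self.genome_to_vc.loc[mapped]

    def vc_presence(self) -> pd.DataFrame:
        """Collapse genomes to VCs: a VC is present iff any member is."""
        if self.genome_to_vc is None:
            raise ValueError("no genome -> VC map attached")
        cols = self.presence.columns.intersection(self.genome_to_vc.index)
        collapsed = self.presence[cols].T.groupby(self.genome_to_vc.loc[cols]).any().T
        return collapsed

    def sample_sets(self, level: str = "vc") -> "pd.Series":
        """Per-sample set of present genome or VC ids."""
        table = self.vc_presence() if level == "vc" else self.presence
        return table.apply(lambda row: frozenset(table.columns[row.values]), axis=1)


def call_presence(coverage: pd.DataFrame, meta: pd.DataFrame,
                  genome_to_vc: Optional[pd.Series] = None,
                  cfg: ThresholdConfig = DEFAULT_CONFIG) -> PresenceMatrix:
    """Presence calls from a long-form covered-fraction table.

    *coverage* columns: sample_id, genome_id, covered_fraction.  Missing
    (sample, genome) entries count as absent.  Present iff strictly
    greater than ``cfg.presence_cov``.
    """
    frac = coverage["covered_fraction"].astype(float)
    bad = coverage[(frac < 0) | (frac > 1)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(f"covered_fraction outside [0, 1]: sample "
                         f"{row['sample_id']!r} genome {row['genome_id']!r} "
                         f"value {row['covered_fraction']!r}")
    wide = coverage.pivot_table(index="sample_id", columns="genome_id",
                                values="covered_fraction", fill_value=0.0)
    wide = wide.reindex(meta.index, fill_value=0.0)
    return PresenceMatrix(wide > cfg.presence_cov, meta, genome_to_vc)


def depth_filter(meta: pd.DataFrame, cfg: ThresholdConfig = DEFAULT_CONFIG
                 ) -> List[str]:
    """Sample ids with read_count >= the depth floor (missing -> excluded)."""
    counts = meta["read_count"]
    missing = counts.index[counts.isna()].tolist()
    if missing:
        warnings.warn(f"samples without read_count excluded: {missing}", stacklevel=2)
    return counts.index[counts >= cfg.min_depth].tolist()


def jaccard_distance(set_a: Set[str], set_b: Set[str]) -> float:
    """1 - |intersection| / |union|; two empty phageomes are identical (0)."""
    union = set_a | set_b
    if not union:
        return 0.0
    return 1.0 - len(set_a & set_b) / len(union)


def jaccard_matrix(pm: PresenceMatrix, level: str = "vc") -> pd.DataFrame:
    """Symmetric inter-sample Jaccard distance matrix at genome or VC level."""
    sets = pm.sample_sets(level)
    ids = sets.index.tolist()
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = jaccard_distance(sets.iloc[i], sets.iloc[j])
    return pd.DataFrame(D, index=ids, columns=ids)


def global_vcs(pm: PresenceMatrix, cfg: ThresholdConfig = DEFAULT_CONFIG,
               min_samples_per_continent: int = 1) -> Set[str]:
    """VCs detected on at least ``cfg.global_continents`` continents.

    A continent counts when the VC is present in at least
    *min_samples_per_continent* of its samples.
    """
    vp = pm.vc_presence()
    if vp.empty:
        return set()
    continent = pm.meta.loc[vp.index, "continent"]
    per_continent = vp.groupby(continent).sum()
    n_continents = (per_continent >= min_samples_per_continent).sum(axis=0)
    return set(n_continents.index[n_continents >= cfg.global_continents])


def prevalence(pm: PresenceMatrix, clade: Set[str], level: str = "genome",
               groupby: str = "continent") -> pd.Series:
    """Fraction of samples per group with any clade member present.

    *clade* is a set of genome ids (level="genome") or VC ids
    (level="vc").  Groups with no samples are omitted with a warning.
    """
    table = pm.vc_presence() if level == "vc" else pm.presence
    members = table.columns.intersection(sorted(clade))
    hit = table[members].any(axis=1) if len(members) else pd.Series(False, index=table.index)
    groups = pm.meta.loc[table.index, groupby]
    out = hit.groupby(groups).mean()
    empty = [g for g in pd.unique(pm.meta[groupby]) if g not in out.index]
    if empty:
        warnings.warn(f"groups without samples omitted: {empty}", stacklevel=2)
    return out


def pca_embedding(distances: pd.DataFrame, n_components: int = 2,
                  seed: int = 0) -> pd.DataFrame:
    """PCA of the inter-sample distance matrix (rows as feature vectors)."""
    pca = PCA(n_components=n_components, random_state=seed)
    coords = pca.fit_transform(distances.values)
    return pd.DataFrame(coords, index=distances.index,
                        columns=[f"PC{i + 1}" for i in range(n_components)])
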