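"""Cross-species comparison: pooled usage profiles, distances, clustering.

Each species is summarized by its pooled 59-codon RSCU vector (RSCU of the
summed codon counts, not the mean of per-gene RSCU) plus mean GC/GC3 over
genes.  Species are compared by Euclidean distance on either the RSCU
vector or the GC3 summary, and related by agglomerative clustering
(average linkage by default); the dendrogram is a usage-similarity tree,
not a phylogeny.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .codon_metrics import (
    CodonCountTable,
    composition_profile,
    count_codons,
    pool_counts,
    rscu,
)
from .genetic_code import SYNONYMOUS_CODONS
from .sequence_io import CodingSequence

__all__ = [
    "SpeciesUsageProfile",
    "species_profile",
    "euclidean_distance_matrix",
    "hierarchical_clustering",
    "ClusteringResult",
]


@dataclass
class SpeciesUsageProfile:
    label: str
    pooled_counts: CodonCountTable
    rscu59: pd.Series  # indexed by the 59 degenerate sense codons
    mean_gc: float
    mean_gc3: float
    mean_gc3s: float
    gene_count: int


def species_profile(genes: list[CodingSequence], label: str) -> SpeciesUsageProfile:
    """Pool a species' genes into one usage profile."""
    if not genes:
        raise ValueError("empty gene set")
    pooled = pool_counts((count_codons(g) for g in genes), source=label)
    values = rscu(pooled)
    vec = pd.Series(
        [0.0 if math.isnan(values[c]) else values[c] for c in SYNONYMOUS_CODONS],
        index=list(SYNONYMOUS_CODONS), name=label,
    )
    profs = [composition_profile(g) for g in genes]
    return SpeciesUsageProfile(
        label=label,
        pooled_counts=pooled,
        rscu59=vec,
        mean_gc=float(np.mean([p.GC for p in profs])),
        mean_gc3=float(np.mean([p.GC3 for p in profs])),
        mean_gc3s=float(np.nanmean([p.GC3s for p in profs])),
        gene_count=len(genes),
    )


def euclidean_distance_matrix(
    profiles: list[SpeciesUsageProfile], feature: str = "rscu59"
) -> pd.DataFrame:
    """Symmetric Euclidean distance matrix on RSCU vectors or GC3 means."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    labels = [p.label for p in profiles]
    if feature == "rscu59":
        X = np.vstack([p.rscu59.to_numpy() for p in profiles])
    elif feature == "gc3":
        X = np.array([[p.mean_gc3] for p in profiles])
    else:
        raise ValueError(f"unknown feature {feature!r}")
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))
    return pd.DataFrame(D, index=labels, columns=labels)


@dataclass
class ClusteringResult:
    newick: str
    linkage_matrix: np.ndarray
    labels: list[str]
    method: str

    def first_bipartition(self) -> tuple[frozenset[str], frozenset[str]]:
        """The two label sets produced by the root split of the tree."""
        assignment = hierarchy.fcluster(self.linkage_matrix, t=2, criterion="maxclust")
        a = frozenset(l for l, c in zip(self.labels, assignment) if c == 1)
        b = frozenset(l for l, c in zip(self.labels, assignment) if c == 2)
        return a, b


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a SciPy linkage matrix as Newick with merge-height branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def render(node: int, parent_height: float) -> str:
        if node < n:
            return f"{labels[node]}:{parent_height:.10g}"
        row = Z[node - n]
        h = float(row[2])
        left = render(int(row[0]), h)
        right = render(int(row[1]), h)
        return f"({left},{right}):{parent_height - h:.10g}"

    root = 2 * n - 2
    h_root = float(Z[-1, 2])
    left = render(int(Z[-1, 0]), h_root)
    right = render(int(Z[-1, 1]), h_root)
    return f"({left},{right});"


def hierarchical_clustering(
    distance_matrix: pd.DataFrame, linkage: str = "average"
) -> ClusteringResult:
    """Agglomerative clustering of a species distance matrix.

    Labels are sorted before linkage so the result does not depend on the
    input order; branch lengths in the Newick output are merge heights.
    """
    if distance_matrix.shape[0] < 2:
        raise ValueError("need at least 2 leaves")
    labels = sorted(distance_matrix.index)
    D = distance_matrix.loc[labels, labels].to_numpy(dtype=float)
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusteringResult(
        newick=_to_newick(Z, labels),
        linkage_matrix=Z,
        labels=labels,
        method=linkage,
    )
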