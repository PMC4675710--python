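"""Community composition summaries: relative abundances, Shannon-Wiener
diversity, correlation-distance sample clustering, and genus co-occurrence
clustering.

Samples are compared by d(A,B) = 1 - r(A,B), the Pearson correlation
distance of their feature abundance vectors, agglomerated with complete
linkage.  Genus co-occurrence uses the same distance on time profiles
(features as observations), cutting the dendrogram at a requested number of
co-occurrence clusters.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .table_io import CountTable, NormalizedAbundanceTable

__all__ = [
    "DiversityResult",
    "SampleDistanceMatrix",
    "relative_abundance",
    "shannon_index",
    "correlation_distance",
    "hclust_complete",
    "cooccurrence_clusters",
    "top_features",
]


@dataclass
class DiversityResult:
    """Per-sample Shannon-Wiener index H' = -sum p_i ln p_i (natural log)."""

    h_prime: pd.Series

    def __getitem__(self, sample_id: str) -> float:
        return float(self.h_prime[sample_id])

    def to_tsv(self, path: str | Path) -> None:
        self.h_prime.rename("shannon_h").to_frame().to_csv(path, sep="\t")


@dataclass
class SampleDistanceMatrix:
    """Square symmetric matrix of 1 - Pearson distances, zero diagonal."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.data.to_numpy()
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")
        if arr.min() < -1e-9 or arr.max() > 2 + 1e-9:
            raise ValueError("1 - Pearson distances must lie in [0, 2]")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")


def relative_abundance(counts: CountTable) -> NormalizedAbundanceTable:
    """Column-normalized proportions; every sample column must have reads."""
    sums = counts.data.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total count")
    df = counts.data.astype(float).div(sums, axis=1)
    return NormalizedAbundanceTable(df, feature_kind=counts.feature_kind)


def shannon_index(proportions: NormalizedAbundanceTable | pd.DataFrame) -> DiversityResult:
    """Shannon-Wiener H' per sample, natural log, zero-proportion terms
    dropped.  Columns must each sum to 1."""
    df = proportions.data if isinstance(proportions, NormalizedAbundanceTable) else proportions
    sums = df.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("proportions must sum to 1 per sample; run relative_abundance first")
    arr = df.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(arr > 0, -arr * np.log(arr), 0.0)
    return DiversityResult(pd.Series(terms.sum(axis=0), index=df.columns))


def correlation_distance(
    table: NormalizedAbundanceTable | pd.DataFrame, axis: str = "samples"
) -> SampleDistanceMatrix:
    """d = 1 - Pearson r between sample columns (or feature rows with
    ``axis='features'``).  Constant vectors have undefined r and are an error.
    """
    df = table.data if isinstance(table, NormalizedAbundanceTable) else table
    mat = df.to_numpy(dtype=float)
    if axis == "samples":
        vectors, ids = mat.T, list(df.columns.astype(str))
    elif axis == "features":
        vectors, ids = mat, list(df.index.astype(str))
    else:
        raise ValueError("axis must be 'samples' or 'features'")
    sd = vectors.std(axis=1)
    if (sd == 0).any():
        bad = ids[int(np.argwhere(sd == 0)[0][0])]
        raise ValueError(f"constant vector for {bad!r}: correlation undefined")
    r = np.corrcoef(vectors)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # enforce exact symmetry/bounds
    return SampleDistanceMatrix(pd.DataFrame(d, index=ids, columns=ids))


@dataclass
class Dendrogram:
    """Complete-linkage agglomeration of a distance matrix."""

    linkage_matrix: np.ndarray
    ids: list[str]

    def cut(self, k: int) -> dict[str, int]:
        """Cut into k groups; labels renumbered 0..k-1 in first-seen order."""
        if k < 1 or k > len(self.ids):
            raise ValueError(f"cannot cut {len(self.ids)} leaves into {k} groups")
        raw = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        remap: dict[int, int] = {}
        out = {}
        for sid, c in zip(self.ids, raw):
            if c not in remap:
                remap[c] = len(remap)
            out[sid] = remap[c]
        return out

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.ids)
        return str(tree)


def hclust_complete(dist: SampleDistanceMatrix, k: int | None = None):
    """Complete-linkage hierarchical clustering of a distance matrix.

    Returns the :class:`Dendrogram`, or ``(Dendrogram, labels)`` when a cut
    count ``k`` is given.
    """
    condensed = squareform(dist.data.to_numpy(), checks=False)
    z = linkage(condensed, method="complete")
    dend = Dendrogram(z, dist.ids)
    if k is None:
        return dend
    return dend, dend.cut(k)


def top_features(
    table: NormalizedAbundanceTable, n: int, ranking: str = "max"
) -> NormalizedAbundanceTable:
    """Top-n features by maximum (default) or mean relative abundance across
    samples.  Max-ranking keeps transient bloomers that mean-ranking would
    drown out."""
    if ranking == "max":
        score = table.data.max(axis=1)
    elif ranking == "mean":
        score = table.data.mean(axis=1)
    else:
        raise ValueError("ranking must be 'max' or 'mean'")
    keep = score.sort_values(ascending=False, kind="stable").index[:n]
    return NormalizedAbundanceTable(table.data.loc[keep], feature_kind=table.feature_kind)


def cooccurrence_clusters(
    genus_profiles: NormalizedAbundanceTable, k: int = 4
) -> dict[str, int]:
    """Cluster genus time profiles into k co-occurrence groups: correlation
    distance between profiles, complete linkage, dendrogram cut at k."""
    if len(genus_profiles.feature_ids) < k:
        raise ValueError("need at least k genus profiles")
    dist = correlation_distance(genus_profiles, axis="features")
    _, labels = hclust_complete(dist, k=k)
    return labels
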