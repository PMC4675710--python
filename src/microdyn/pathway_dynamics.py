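"""Pathway variation-pattern analysis.

Each pathway's normalized abundance time series K_p(t) is reduced to a
vector of log2 step changes

    V_p(t) = log2( K_p(t) / K_p(t-1) )

over consecutive sampled weeks, so a 6-point series yields 5 scores.  The
score vectors are k-means clustered; the number of clusters is chosen by
maximizing the Calinski-Harabasz (CH) index, the ratio of between-cluster
to within-cluster dispersion scaled by (n-k)/(k-1).  The cluster whose
centroid is nearest the origin is labelled "constant" (no systematic change
at any step); all others are "responsive".

Pathways unusable for this analysis are removed first: those absent from
prokaryotes, those whose maximum normalized abundance stays below a cutoff
(default 1e-4) throughout the time course, and those with a zero abundance
at any analysed sample (V is undefined at zeros).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .table_io import NormalizedAbundanceTable

__all__ = [
    "VariationProfile",
    "ClusteringResult",
    "filter_pathways",
    "variation_scores",
    "ch_index",
    "cluster_variation_profiles",
    "label_clusters",
]

CONSTANT = "constant"
RESPONSIVE = "responsive"


@dataclass(frozen=True)
class VariationProfile:
    """Per-pathway vector of V_p(t) step scores, one per week transition."""

    pathway_id: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.scores)):
            raise ValueError(f"non-finite variation score for {self.pathway_id!r}")


@dataclass
class ClusteringResult:
    k_selected: int
    labels: dict[str, int]  # pathway -> cluster index (0-based)
    ch_scores: dict[int, float]  # k -> CH index of the best-of-restarts fit
    centroids: np.ndarray  # (k_selected, n_scores)

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def to_frame(self) -> pd.DataFrame:
        names = label_clusters(self)
        return pd.DataFrame(
            {
                "pathway": list(self.labels),
                "cluster": list(self.labels.values()),
                "label": [names[c] for c in self.labels.values()],
            }
        ).set_index("pathway")


def filter_pathways(
    table: NormalizedAbundanceTable,
    prokaryote_flags: Mapping[str, bool],
    cutoff: float = 1e-4,
) -> NormalizedAbundanceTable:
    """Retain pathways that are prokaryotic, reach the abundance cutoff at
    some time point, and are nonzero at every analysed sample."""
    keep = []
    for pw in table.feature_ids:
        if pw not in prokaryote_flags:
            raise KeyError(f"no prokaryote flag for pathway {pw!r}")
        row = table.data.loc[pw].to_numpy()
        if prokaryote_flags[pw] and row.max() >= cutoff and (row > 0).all():
            keep.append(pw)
    return NormalizedAbundanceTable(table.data.loc[keep], feature_kind=table.feature_kind)


def variation_scores(
    table: NormalizedAbundanceTable, weeks: Sequence[int] | None = None
) -> list[VariationProfile]:
    """V_p(t) = log2 of consecutive abundance ratios, one score per step
    between sampled weeks (regardless of week spacing).

    ``weeks``, when given, must parallel the table's columns and be strictly
    increasing; it fixes the column order interpretation.  Zero abundances
    are a hard error: such pathways must be filtered out first, not imputed.
    """
    data = table.data
    if weeks is not None:
        if len(weeks) != data.shape[1]:
            raise ValueError("weeks must match the table's sample columns")
        if not all(b > a for a, b in zip(weeks, weeks[1:])):
            raise ValueError("weeks must be strictly increasing")
    if data.shape[1] < 2:
        raise ValueError("need at least two time points")
    arr = data.to_numpy(dtype=float)
    if (arr <= 0).any():
        bad = data.index[np.argwhere(arr <= 0)[0][0]]
        raise ValueError(
            f"zero abundance in pathway {bad!r}: run filter_pathways before scoring"
        )
    v = np.log2(arr[:, 1:] / arr[:, :-1])
    return [
        VariationProfile(pw, tuple(v[i])) for i, pw in enumerate(data.index.astype(str))
    ]


def ch_index(points: np.ndarray, labels: Sequence[int]) -> float:
    """Calinski-Harabasz index: [B/(k-1)] / [W/(n-k)].

    B is the between-cluster and W the within-cluster sum of squared
    Euclidean distances to the respective means.  Returns +inf when W = 0
    (perfectly tight clusters).  Requires 2 <= k < n and no empty cluster.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = points.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("CH index requires at least 2 clusters")
    if n <= k:
        raise ValueError("CH index requires more points than clusters")
    grand = points.mean(axis=0)
    b = 0.0
    w = 0.0
    for c in uniq:
        members = points[labels == c]
        if members.shape[0] == 0:
            raise ValueError(f"empty cluster {c!r}")
        centroid = members.mean(axis=0)
        b += members.shape[0] * float(np.sum((centroid - grand) ** 2))
        w += float(np.sum((members - centroid) ** 2))
    if w == 0.0:
        return float("inf")
    return (b / (k - 1)) / (w / (n - k))


def cluster_variation_profiles(
    profiles: Sequence[VariationProfile],
    k_range: tuple[int, int] = (2, 10),
    restarts: int = 100,
    seed: int = 0,
) -> ClusteringResult:
    """k-means over the V score vectors for each k in ``k_range``; the k with
    the highest CH index wins (smallest k on ties).  Best-of-``restarts``
    Euclidean k-means under a fixed seed makes the result deterministic.
    """
    ids = [p.pathway_id for p in profiles]
    x = np.array([p.scores for p in profiles], dtype=float)
    n = x.shape[0]
    k_lo, k_hi = k_range
    if k_lo < 2:
        raise ValueError("k_range must start at 2 or more")
    candidates = [k for k in range(k_lo, k_hi + 1) if k < n]
    if not candidates:
        raise ValueError(f"too few profiles ({n}) for any k in {k_range}")
    ch_scores: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in candidates:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        lab = km.fit_predict(x)
        if len(np.unique(lab)) < k:  # degenerate fit (duplicate points)
            continue
        ch_scores[k] = ch_index(x, lab)
        fits[k] = km
    if not ch_scores:
        raise ValueError("no valid clustering for any k in range")
    k_best = max(sorted(ch_scores), key=lambda k: ch_scores[k])
    km = fits[k_best]
    labels = {pid: int(c) for pid, c in zip(ids, km.labels_)}
    return ClusteringResult(k_best, labels, ch_scores, km.cluster_centers_.copy())


def label_clusters(result: ClusteringResult) -> dict[int, str]:
    """The cluster with the smallest centroid Euclidean norm is "constant";
    every other cluster is "responsive".  Ties go to the lowest index."""
    norms = np.linalg.norm(result.centroids, axis=1)
    constant = int(np.argmin(norms))  # argmin takes the first on ties
    return {
        c: (CONSTANT if c == constant else RESPONSIVE)
        for c in range(result.centroids.shape[0])
    }
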