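"""All-against-all gene-pool comparison between samples.

Each ordered sample pair (A, B) is summarized by S(A->B): the sum over A's
reads of the best-hit alignment bit score against B's read set (reads with
no hit contribute 0).  The gene-pool distance between two samples is the
self-normalized symmetric form

    D2(A, B) = 1 - ( S(A->B) + S(B->A) ) / ( S(A->A) + S(B->B) )

clamped to [0, 1]: identical pools score 0, pools sharing no alignable
sequence score 1.  The full matrix (121 ordered pairs for 11 samples,
self-comparisons included) feeds complete-linkage clustering.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .community_structure import Dendrogram, SampleDistanceMatrix, hclust_complete
from .table_io import BlastHitRecord

__all__ = [
    "PairwiseBitScoreSummary",
    "summarize_bitscores",
    "d2_matrix",
    "cluster_genepools",
]


@dataclass
class PairwiseBitScoreSummary:
    """S(A->B) for every ordered sample pair, self-comparisons included."""

    sample_ids: list[str]
    scores: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for a in self.sample_ids:
            for b in self.sample_ids:
                if (a, b) not in self.scores:
                    raise ValueError(f"missing ordered pair ({a!r}, {b!r})")
        if len(self.scores) != n * n:
            extra = set(self.scores) - {
                (a, b) for a in self.sample_ids for b in self.sample_ids
            }
            raise ValueError(f"scores for samples outside the design: {sorted(extra)}")
        for a in self.sample_ids:
            if self.scores[(a, a)] <= 0:
                raise ValueError(f"self-score for sample {a!r} must be positive")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self.scores[pair]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairwiseBitScoreSummary":
        df = pd.read_csv(path, sep="\t", dtype={"query_sample": str, "target_sample": str})
        ids = sorted(set(df["query_sample"]) | set(df["target_sample"]))
        scores = {
            (str(r.query_sample), str(r.target_sample)): float(r.score)
            for r in df.itertuples()
        }
        return cls(ids, scores)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"query_sample": a, "target_sample": b, "score": self.scores[(a, b)]}
            for a in self.sample_ids
            for b in self.sample_ids
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def summarize_bitscores(
    hits_per_pair: Mapping[tuple[str, str], Sequence[BlastHitRecord]],
    sample_ids: Sequence[str] | None = None,
    max_evalue: float = 0.01,
) -> PairwiseBitScoreSummary:
    """Reduce per-pair hit lists to S(A->B) = sum over queries of the best
    bit score.  Hits above ``max_evalue`` are discarded first; duplicate hits
    for a query contribute only their maximum."""
    if sample_ids is None:
        sample_ids = sorted({s for pair in hits_per_pair for s in pair})
    scores: dict[tuple[str, str], float] = {}
    for a in sample_ids:
        for b in sample_ids:
            hits = hits_per_pair.get((a, b), ())
            best: dict[str, float] = {}
            for h in hits:
                if h.evalue > max_evalue:
                    continue
                best[h.query_id] = max(best.get(h.query_id, 0.0), h.bitscore)
            scores[(a, b)] = float(sum(best.values()))
    return PairwiseBitScoreSummary(list(sample_ids), scores)


def d2_matrix(summary: PairwiseBitScoreSummary) -> SampleDistanceMatrix:
    """D2(A,B) = 1 - (S(A->B) + S(B->A)) / (S(A->A) + S(B->B)), clamped to
    [0, 1].  Cross-scores exceeding the self-score pair (possible with
    heuristic alignment) clamp to D2 = 0 rather than going negative."""
    ids = summary.sample_ids
    n = len(ids)
    d = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i == j:
                continue
            cross = summary[(a, b)] + summary[(b, a)]
            selfs = summary[(a, a)] + summary[(b, b)]
            d[i, j] = min(1.0, max(0.0, 1.0 - cross / selfs))
    d = (d + d.T) / 2.0
    return SampleDistanceMatrix(pd.DataFrame(d, index=ids, columns=ids))


def cluster_genepools(d2: SampleDistanceMatrix, k: int | None = None) -> Dendrogram:
    """Complete-linkage clustering of the D2 matrix (see hclust_complete)."""
    return hclust_complete(d2, k=k)
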