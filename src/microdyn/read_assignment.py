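"""Threshold-based read assignment from BLAST tabular hits.

Reads are assigned to reference features by their best-scoring hit after
identity and bit-score filtering (defaults: identity >=70%, bit-score >=40).
For custom reference collections (e.g. a curated degradation-gene database)
a two-stage confirmation is supported: a candidate assignment against the
curated database survives only if the read's best hit against a
comprehensive database is itself a member of the curated set.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence, Set
from dataclasses import dataclass

from .table_io import BlastHitRecord

__all__ = [
    "Assignment",
    "filter_hits",
    "best_hit",
    "confirm_inhouse",
    "db_build_filter",
]


@dataclass(frozen=True)
class Assignment:
    """One read's feature assignment: at most one per query."""

    query_id: str
    feature_id: str
    bitscore: float


def filter_hits(
    hits: Sequence[BlastHitRecord],
    min_identity: float = 70.0,
    min_bitscore: float = 40.0,
) -> list[BlastHitRecord]:
    """Keep hits with identity >= min_identity and bitscore >= min_bitscore
    (both thresholds inclusive); input order preserved."""
    return [h for h in hits if h.identity >= min_identity and h.bitscore >= min_bitscore]


def _best(hits: Iterable[BlastHitRecord]) -> BlastHitRecord:
    # max bitscore; ties broken to the lexicographically smallest subject id
    return max(hits, key=lambda h: (h.bitscore, _NegStr(h.subject_id)))


class _NegStr(str):
    """String whose ordering is reversed, so max() prefers the smallest id."""

    def __lt__(self, other: str) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other: str) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


def best_hit(
    hits: Sequence[BlastHitRecord],
    feature_of: Mapping[str, str] | None = None,
) -> list[Assignment]:
    """Per query, the assignment of the hit with maximal bitscore.

    Ties on bitscore go to the lexicographically smallest subject id so the
    result is deterministic.  ``feature_of`` optionally maps subject ids to
    taxon/KO labels; unmapped subjects keep their own id.  Queries appear in
    first-seen order.
    """
    by_query: dict[str, list[BlastHitRecord]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out = []
    for query, group in by_query.items():
        top = _best(group)
        feature = feature_of.get(top.subject_id, top.subject_id) if feature_of else top.subject_id
        out.append(Assignment(query, feature, top.bitscore))
    return out


def confirm_inhouse(
    candidates: Sequence[Assignment],
    nr_hits: Sequence[BlastHitRecord],
    inhouse_ids: Set[str],
) -> list[Assignment]:
    """Second-stage confirmation of curated-database assignments.

    A candidate is kept iff its query's best comprehensive-database hit (by
    bitscore, same tie rule as :func:`best_hit`) is a member of
    ``inhouse_ids`` — or the query has no comprehensive-database hit at all,
    in which case the curated hit is trivially the best known one.
    ``nr_hits`` must already be filtered at the same thresholds.
    """
    best_nr: dict[str, BlastHitRecord] = {}
    for h in nr_hits:
        cur = best_nr.get(h.query_id)
        if cur is None or _best([cur, h]) is h:
            best_nr[h.query_id] = h
    out = []
    for cand in candidates:
        top = best_nr.get(cand.query_id)
        if top is None or top.subject_id in inhouse_ids:
            out.append(cand)
    return out


def db_build_filter(
    hits: Sequence[BlastHitRecord],
    min_identity: float = 90.0,
    min_qcov: float = 70.0,
    min_scov: float = 70.0,
) -> set[str]:
    """Subjects qualifying for inclusion in a curated database: hits with
    identity >= 90% and both query and subject coverage >= 70% (inclusive),
    deduplicated.  Hits must carry coverage columns."""
    accepted: set[str] = set()
    for h in hits:
        if h.qcov is None or h.scov is None:
            raise ValueError(
                f"hit {h.query_id!r}->{h.subject_id!r} lacks coverage fields "
                "required by the database-construction filter"
            )
        if h.identity >= min_identity and h.qcov >= min_qcov and h.scov >= min_scov:
            accepted.add(h.subject_id)
    return accepted
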