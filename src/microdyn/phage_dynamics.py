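"""Phage-contig classification and host-bloom / phage-bloom asynchrony.

A candidate contig is accepted as a putative phage-genome contig when it
(i) exceeds 2 kb, (ii) belongs to the phage genome-related contig set,
(iii) carries at least one CDS with >=40% amino-acid identity to a phage
ortholog family, and (iv) contains at least one phage-derived genomic
region call.

The "kill-the-winner" signal — phage predation of the currently most
successful host — is operationalized on matched per-week abundance series:
the phage peak must lag the host peak, the phage rise from its baseline
must be large (default >=100-fold), and the host must have declined from
its own peak by the time the phage peaks (default >=2-fold).  All three
thresholds are parameters, not claims.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import GenomeEquivalents, length_normalize, normalize_per_genome
from .table_io import CountTable, NormalizedAbundanceTable

__all__ = [
    "PhageContigRecord",
    "BloomReport",
    "classify_phage_contigs",
    "read_contig_annotations",
    "contig_abundance_series",
    "rescale_min_to_one",
    "detect_bloom_asynchrony",
]

COMPLETENESS = ("intact", "incomplete", "unknown")


@dataclass(frozen=True)
class PhageContigRecord:
    """Assembled-contig annotations consumed by the phage classifier."""

    contig_id: str
    length_bp: int
    phage_related: bool
    max_pog_identity: float  # best aa identity of any CDS vs phage ortholog DB
    phast_region_count: int
    completeness: str = "unknown"

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"non-positive length for contig {self.contig_id!r}")
        if not (0.0 <= self.max_pog_identity <= 100.0):
            raise ValueError(f"identity outside [0,100] for contig {self.contig_id!r}")
        if self.phast_region_count < 0:
            raise ValueError(f"negative region count for contig {self.contig_id!r}")
        if self.completeness not in COMPLETENESS:
            raise ValueError(f"unknown completeness {self.completeness!r}")


def classify_phage_contigs(
    records: Sequence[PhageContigRecord],
    min_length_bp: int = 2000,
    min_identity: float = 40.0,
) -> list[str]:
    """Contig ids passing all four phage-contig criteria.  Length is a strict
    inequality (>2 kb); identity is inclusive (>=40%)."""
    return [
        r.contig_id
        for r in records
        if r.length_bp > min_length_bp
        and r.phage_related
        and r.max_pog_identity >= min_identity
        and r.phast_region_count >= 1
    ]


def read_contig_annotations(path: str | Path) -> list[PhageContigRecord]:
    """TSV columns: contig_id, length_bp, phage_related (0/1), max_pog_identity,
    phast_region_count, completeness (optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for r in df.itertuples():
        records.append(
            PhageContigRecord(
                contig_id=str(r.contig_id),
                length_bp=int(r.length_bp),
                phage_related=str(r.phage_related) in {"1", "true", "True", "TRUE"},
                max_pog_identity=float(r.max_pog_identity),
                phast_region_count=int(r.phast_region_count),
                completeness=str(getattr(r, "completeness", "unknown")),
            )
        )
    return records


def contig_abundance_series(
    hits: CountTable,
    lengths: Mapping[str, float],
    ge: GenomeEquivalents,
) -> NormalizedAbundanceTable:
    """Normalized contig abundance: hit count / contig length (bp) / sample
    genome equivalents — the standard two-step normalization applied to
    contig-hit counts."""
    return normalize_per_genome(length_normalize(hits, lengths), ge)


def rescale_min_to_one(series: pd.Series) -> pd.Series:
    """Express a positive abundance series relative to its smallest value
    (smallest value becomes 1) — the display convention for bloom series."""
    m = float(series.min())
    if m <= 0:
        raise ValueError("series must be strictly positive to rescale")
    return series / m


@dataclass(frozen=True)
class BloomReport:
    """Timing and magnitude of a host bloom and its trailing phage bloom."""

    host_feature: str
    contig_id: str
    host_peak_week: int
    phage_peak_week: int
    lag_weeks: int
    host_fold_rise: float
    phage_fold_rise: float
    host_decline_after_phage_rise: float
    ktw_flag: bool

    def __post_init__(self) -> None:
        if self.lag_weeks != self.phage_peak_week - self.host_peak_week:
            raise ValueError("lag_weeks must equal phage_peak_week - host_peak_week")
        if self.ktw_flag and self.lag_weeks <= 0:
            raise ValueError("kill-the-winner flag requires a positive lag")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _peak_week(series: pd.Series) -> int:
    arr = series.to_numpy(dtype=float)
    return int(series.index[int(np.argmax(arr))])  # argmax: earliest on ties


def detect_bloom_asynchrony(
    host_series: pd.Series,
    phage_series: pd.Series,
    min_phage_fold: float = 100.0,
    min_host_decline_fold: float = 2.0,
    host_baseline_week: int | None = None,
    phage_baseline_week: int | None = None,
    host_feature: str = "host",
    contig_id: str = "contig",
) -> BloomReport:
    """Locate the host and phage abundance peaks and test for the
    kill-the-winner pattern.

    Both series are indexed by week on the same grid (>= 3 points, strictly
    positive).  Peaks take the earliest week on ties.  Fold rises are peak /
    baseline-week value; baselines default to each series' earliest week but
    are explicit parameters (a phage absent before the bloom is naturally
    referenced to its first observed week).  The flag fires iff the phage
    peak lags the host peak, the phage rise reaches ``min_phage_fold``, and
    the host has declined from its peak by ``min_host_decline_fold`` at the
    phage's peak week.
    """
    if list(host_series.index) != list(phage_series.index):
        raise ValueError("host and phage series must share the same week grid")
    if len(host_series) < 3:
        raise ValueError("need at least 3 time points")
    for name, s in (("host", host_series), ("phage", phage_series)):
        if (s.to_numpy(dtype=float) <= 0).any():
            raise ValueError(f"{name} series must be strictly positive")

    weeks = [int(w) for w in host_series.index]
    host_base = weeks[0] if host_baseline_week is None else int(host_baseline_week)
    phage_base = weeks[0] if phage_baseline_week is None else int(phage_baseline_week)
    for base in (host_base, phage_base):
        if base not in weeks:
            raise ValueError(f"baseline week {base} not in the sampled grid")

    host_peak = _peak_week(host_series)
    phage_peak = _peak_week(phage_series)
    host_fold = float(host_series[host_peak] / host_series[host_base])
    phage_fold = float(phage_series[phage_peak] / phage_series[phage_base])
    decline = float(host_series[host_peak] / host_series[phage_peak])
    lag = phage_peak - host_peak
    ktw = lag > 0 and phage_fold >= min_phage_fold and decline >= min_host_decline_fold
    return BloomReport(
        host_feature=host_feature,
        contig_id=contig_id,
        host_peak_week=host_peak,
        phage_peak_week=phage_peak,
        lag_weeks=lag,
        host_fold_rise=host_fold,
        phage_fold_rise=phage_fold,
        host_decline_after_phage_rise=decline,
        ktw_flag=bool(ktw),
    )
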