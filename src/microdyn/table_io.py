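"""Readers/writers for the pipeline's tabular formats and the sampling design.

Every stage of the pipeline exchanges plain TSV matrices: a header row of
sample ids and a first column of feature ids.  TSV keeps intermediate
results diffable and language-neutral.  BLAST hits are consumed as standard
12-column tabular output (``-outfmt 6``), optionally extended with query and
subject coverage columns.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("microdyn")

ARMS = ("baseline", "control", "polluted")
FEATURE_KINDS = ("otu", "genus", "ko", "gene", "contig", "pathway", "marker")

#: Sampled weeks of the microcosm experiment: a week-0 baseline shared by
#: both arms, then five sampling points per arm.
DEFAULT_WEEKS = (0, 1, 3, 6, 12, 24)


class TableFormatError(ValueError):
    """Raised when an input table violates its documented format."""


@dataclass(frozen=True)
class Sample:
    sample_id: str
    arm: str
    week: int

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r} for sample {self.sample_id!r}")
        if self.week < 0:
            raise ValueError(f"negative week for sample {self.sample_id!r}")


@dataclass(frozen=True)
class SampleDesign:
    """The experimental design: which sample was taken from which arm and week.

    Invariants: at most one baseline sample, at week 0; within each arm the
    weeks are unique (ordering is normalised on construction).
    """

    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in design")
        baselines = [s for s in self.samples if s.arm == "baseline"]
        if len(baselines) > 1:
            raise ValueError("more than one baseline sample")
        if baselines and baselines[0].week != 0:
            raise ValueError("baseline sample must be at week 0")
        for arm in ("control", "polluted"):
            weeks = [s.week for s in self.samples if s.arm == arm]
            if len(set(weeks)) != len(weeks):
                raise ValueError(f"duplicate weeks within arm {arm!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def arm_series(self, arm: str, include_baseline: bool = True) -> list[Sample]:
        """Time-ordered samples of one arm, with the shared week-0 baseline
        prepended by default (each arm's time series starts at week 0)."""
        if arm not in ("control", "polluted"):
            raise ValueError(f"arm_series expects control or polluted, got {arm!r}")
        series = sorted((s for s in self.samples if s.arm == arm), key=lambda s: s.week)
        if include_baseline:
            series = [s for s in self.samples if s.arm == "baseline"] + series
        return series


def default_design() -> SampleDesign:
    """The 11-sample design: baseline '0', control 1C..24C, polluted 1M..24M."""
    samples = [Sample("0", "baseline", 0)]
    for week in DEFAULT_WEEKS[1:]:
        samples.append(Sample(f"{week}C", "control", week))
    for week in DEFAULT_WEEKS[1:]:
        samples.append(Sample(f"{week}M", "polluted", week))
    return SampleDesign(tuple(samples))


def _check_ids(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise TableFormatError(f"duplicate {what} id {lab!r}")
        seen.add(lab)


@dataclass
class CountTable:
    """Features × samples matrix of non-negative integer read counts."""

    data: pd.DataFrame  # index = feature ids, columns = sample ids
    feature_kind: str = "ko"

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        _check_ids(list(self.data.index.astype(str)), "feature")
        _check_ids(list(self.data.columns.astype(str)), "sample")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise TableFormatError("counts must be integral")
            self.data = self.data.round().astype(np.int64)
        if (self.data.to_numpy() < 0).any():
            bad = np.argwhere(self.data.to_numpy() < 0)[0]
            raise TableFormatError(
                f"negative count at feature {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns.astype(str))

    def to_tsv(self, path: str | Path) -> None:
        write_table(self.data, path)


@dataclass
class NormalizedAbundanceTable:
    """Features × samples matrix of non-negative real abundances.

    Unit: reads per residue (or per bp for contigs), optionally further
    divided by the per-sample genome-equivalent estimate.
    """

    data: pd.DataFrame
    feature_kind: str = "ko"

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        _check_ids(list(self.data.index.astype(str)), "feature")
        _check_ids(list(self.data.columns.astype(str)), "sample")
        if (self.data.to_numpy() < 0).any():
            raise TableFormatError("abundances must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns.astype(str))

    def to_tsv(self, path: str | Path) -> None:
        write_table(self.data, path)


def read_count_table(path: str | Path, kind: str = "ko") -> CountTable:
    """Read a TSV count table (header = sample ids, first column = feature ids).

    Raises :class:`TableFormatError` naming the offending cell for negative
    or non-numeric counts, and for duplicate feature or sample ids.
    """
    df = _read_matrix(path)
    arr = df.to_numpy()
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            v = arr[i, j]
            if not np.isfinite(v) or v < 0 or v != int(v):
                raise TableFormatError(
                    f"{path}: invalid count {v!r} at feature {df.index[i]!r}, "
                    f"sample {df.columns[j]!r}"
                )
    table = CountTable(df.astype(np.int64), feature_kind=kind)
    logger.info("read %s: %d features x %d samples (%s)", path, *df.shape, kind)
    return table


def read_abundance_table(path: str | Path, kind: str = "pathway") -> NormalizedAbundanceTable:
    return NormalizedAbundanceTable(_read_matrix(path).astype(float), feature_kind=kind)


def _read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed TSV
        raise TableFormatError(f"{path}: cannot parse as TSV matrix: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    non_numeric = df.select_dtypes(exclude="number").columns
    if len(non_numeric):
        col = non_numeric[0]
        raise TableFormatError(f"{path}: non-numeric cell in sample column {col!r}")
    _check_ids(list(df.index), "feature")
    _check_ids(list(df.columns), "sample")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=True, lineterminator="\n")


@dataclass(frozen=True)
class BlastHitRecord:
    """One line of BLAST tabular output (``-outfmt 6``), plus optional
    query/subject coverage percentages (columns 13-14 when present)."""

    query_id: str
    subject_id: str
    identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qcov: float | None = None
    scov: float | None = None

    def __post_init__(self) -> None:
        for name in ("identity", "qcov", "scov"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")


def read_blast_tabular(path: str | Path) -> list[BlastHitRecord]:
    """Parse BLAST tabular hits; one record per non-empty line.

    Lines must carry the 12 canonical columns; columns 13-14, when present,
    are read as query and subject coverage percentages.
    """
    records: list[BlastHitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise TableFormatError(
                    f"{path}: line {lineno}: expected >=12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                rec = BlastHitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    qcov=float(fields[12]) if len(fields) > 12 else None,
                    scov=float(fields[13]) if len(fields) > 13 else None,
                )
            except ValueError as exc:
                raise TableFormatError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_blast_tabular(records: Iterable[BlastHitRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for r in records:
            fields = [
                r.query_id, r.subject_id, f"{r.identity:.2f}", str(r.aln_length),
                str(r.mismatches), str(r.gap_opens), str(r.qstart), str(r.qend),
                str(r.sstart), str(r.send), f"{r.evalue:.3g}", f"{r.bitscore:.1f}",
            ]
            if r.qcov is not None:
                fields.append(f"{r.qcov:.1f}")
                if r.scov is not None:
                    fields.append(f"{r.scov:.1f}")
            fh.write("\t".join(fields) + "\n")


@dataclass
class Config:
    """Pipeline thresholds and clustering parameters.

    Defaults are the study's operating points: read assignment at identity
    >=70% and bit-score >=40, pathway abundance cutoff 1e-4, in-house DB
    construction at identity >=90% with both coverages >=70%.
    """

    min_identity: float = 70.0
    min_bitscore: float = 40.0
    abundance_cutoff: float = 1e-4
    db_min_identity: float = 90.0
    db_min_qcov: float = 70.0
    db_min_scov: float = 70.0
    k_min: int = 2
    k_max: int = 10
    kmeans_restarts: int = 100
    seed: int = 0
    marker_list_path: str | None = None
    ko_catalog_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("min_identity", "db_min_identity", "db_min_qcov", "db_min_scov"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.abundance_cutoff <= 0:
            raise ValueError("abundance_cutoff must be positive")
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("need 2 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
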