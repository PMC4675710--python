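"""Length normalization and genome-equivalent normalization of read counts.

The scheme removes two confounders from raw read counts before any
cross-sample comparison:

1. gene length — longer genes recruit more reads, so each feature's count is
   divided by its (amino-acid or bp) length;
2. sequencing depth and community genome count — each sample's abundances are
   divided by the sample's *genome equivalents*: the mean length-normalized
   abundance of a fixed set of 36 marker genes (gyrB plus 35 universal
   single-copy genes), each carried once by almost every prokaryotic genome.

The resulting unit is "per-genome copy number": an abundance of 1 means one
copy per average prokaryotic genome in the sample.  Doubling a sample's
read depth doubles counts and the marker estimate alike and leaves the
per-genome abundances unchanged — the invariance the scheme exists for.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .table_io import CountTable, NormalizedAbundanceTable, write_table

__all__ = [
    "KOCatalog",
    "MarkerSet",
    "GenomeEquivalents",
    "default_marker_set",
    "length_normalize",
    "estimate_genome_equivalents",
    "pathway_abundance",
    "normalize_per_genome",
]


@dataclass
class KOCatalog:
    """KO metadata: median protein length (aa), pathway memberships, and
    per-pathway prokaryote flags."""

    median_length: dict[str, int]
    pathways: dict[str, frozenset[str]]  # ko -> pathway ids
    prokaryote_flag: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ko, length in self.median_length.items():
            if length <= 0:
                raise ValueError(f"non-positive median length for {ko!r}")

    def pathway_members(self) -> dict[str, list[str]]:
        members: dict[str, list[str]] = {}
        for ko, pws in self.pathways.items():
            for pw in pws:
                members.setdefault(pw, []).append(ko)
        for pw in members:
            members[pw].sort()
        return members

    @classmethod
    def from_tsv(cls, ko_path: str | Path, flags_path: str | Path | None = None) -> "KOCatalog":
        """Catalog TSV: columns ko_id, median_length, pathways (comma-separated);
        flags TSV: pathway_id, prokaryote_flag (0/1 or true/false)."""
        df = pd.read_csv(ko_path, sep="\t", dtype=str)
        lengths = {str(r.ko_id): int(r.median_length) for r in df.itertuples()}
        pathways = {
            str(r.ko_id): frozenset(
                p for p in str(getattr(r, "pathways", "") or "").split(",") if p and p != "nan"
            )
            for r in df.itertuples()
        }
        flags: dict[str, bool] = {}
        if flags_path is not None:
            fdf = pd.read_csv(flags_path, sep="\t", dtype=str)
            truthy = {"1", "true", "True", "TRUE", "yes"}
            flags = {
                str(r.pathway_id): str(r.prokaryote_flag) in truthy for r in fdf.itertuples()
            }
        return cls(lengths, pathways, flags)

    def to_tsv(self, ko_path: str | Path, flags_path: str | Path | None = None) -> None:
        rows = [
            {"ko_id": ko, "median_length": self.median_length[ko],
             "pathways": ",".join(sorted(self.pathways.get(ko, ())))}
            for ko in sorted(self.median_length)
        ]
        pd.DataFrame(rows).to_csv(ko_path, sep="\t", index=False)
        if flags_path is not None:
            frows = [
                {"pathway_id": pw, "prokaryote_flag": int(flag)}
                for pw, flag in sorted(self.prokaryote_flag.items())
            ]
            pd.DataFrame(frows).to_csv(flags_path, sep="\t", index=False)


@dataclass(frozen=True)
class MarkerSet:
    """The marker genes used for genome-equivalent estimation: gyrB plus 35
    universal single-copy genes, 36 in total by default (configurable)."""

    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        if not self.marker_ids:
            raise ValueError("empty marker set")

    def __len__(self) -> int:
        return len(self.marker_ids)

    @classmethod
    def from_file(cls, path: str | Path) -> "MarkerSet":
        ids = [ln.strip() for ln in Path(path).read_text().splitlines()
               if ln.strip() and not ln.startswith("#")]
        return cls(tuple(ids))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.marker_ids) + "\n")


# Default marker list: gyrB plus 35 universal single-copy genes.  The set of
# ribosomal proteins and tRNA synthetases below is a documented synthetic
# stand-in with typical bacterial protein lengths — the analysis only needs a
# fixed id->length marker panel, and both the ids and the lengths are fully
# configurable via MarkerSet / KOCatalog inputs.
_DEFAULT_MARKERS: tuple[tuple[str, int], ...] = (
    ("gyrB", 650),
    ("rpsB", 245), ("rpsC", 230), ("rpsE", 170), ("rpsG", 156), ("rpsH", 132),
    ("rpsI", 130), ("rpsJ", 103), ("rpsK", 129), ("rpsL", 124), ("rpsM", 118),
    ("rpsO", 89), ("rpsQ", 84), ("rpsS", 92),
    ("rplA", 234), ("rplB", 273), ("rplC", 209), ("rplD", 201), ("rplE", 179),
    ("rplF", 177), ("rplK", 142), ("rplM", 142), ("rplN", 122), ("rplO", 144),
    ("rplP", 136), ("rplR", 117), ("rplS", 115), ("rplT", 118), ("rplV", 110),
    ("rplX", 104),
    ("argS", 577), ("cysS", 461), ("hisS", 424), ("leuS", 860), ("pheS", 327),
    ("valS", 951),
)


def default_marker_set() -> MarkerSet:
    return MarkerSet(tuple(name for name, _ in _DEFAULT_MARKERS))


def default_marker_lengths() -> dict[str, int]:
    return dict(_DEFAULT_MARKERS)


@dataclass
class GenomeEquivalents:
    """Per-sample estimate of prokaryotic genomes per unit sequencing effort."""

    values: pd.Series  # index = sample ids, strictly positive

    def __post_init__(self) -> None:
        if (self.values <= 0).any():
            bad = self.values.index[self.values <= 0][0]
            raise ValueError(
                f"genome-equivalent estimate is not positive for sample {bad!r}; "
                "normalization impossible"
            )

    def __getitem__(self, sample_id: str) -> float:
        return float(self.values[sample_id])

    def to_tsv(self, path: str | Path) -> None:
        self.values.rename("genome_equivalents").to_frame().to_csv(path, sep="\t")


def length_normalize(
    counts: CountTable, lengths: Mapping[str, float]
) -> NormalizedAbundanceTable:
    """Divide each feature's counts by its length (aa for protein features,
    bp for contigs).  Every feature must have a positive length."""
    vals = np.empty(len(counts.feature_ids))
    for i, fid in enumerate(counts.feature_ids):
        if fid not in lengths:
            raise KeyError(f"no length for feature {fid!r}")
        if lengths[fid] <= 0:
            raise ValueError(f"non-positive length for feature {fid!r}")
        vals[i] = lengths[fid]
    df = counts.data.astype(float).div(pd.Series(vals, index=counts.data.index), axis=0)
    return NormalizedAbundanceTable(df, feature_kind=counts.feature_kind)


def estimate_genome_equivalents(
    ko_table: CountTable, markers: MarkerSet, catalog: KOCatalog
) -> GenomeEquivalents:
    """Genome equivalents per sample: the arithmetic mean, over the full
    marker panel, of count/length.

    The mean is always over all markers in the panel: a marker absent from a
    sample contributes abundance 0.  Excluding absent markers would inflate
    estimates in shallowly sequenced samples.
    """
    per_marker = np.zeros((len(markers), len(ko_table.sample_ids)))
    for i, marker in enumerate(markers.marker_ids):
        if marker not in catalog.median_length:
            raise KeyError(f"marker {marker!r} missing from catalog")
        if marker in ko_table.data.index:
            per_marker[i] = ko_table.data.loc[marker].to_numpy() / catalog.median_length[marker]
    est = pd.Series(per_marker.mean(axis=0), index=ko_table.sample_ids)
    return GenomeEquivalents(est)


def pathway_abundance(
    ko_abund: NormalizedAbundanceTable, catalog: KOCatalog
) -> NormalizedAbundanceTable:
    """Sum member-KO abundances per pathway; a KO in m pathways contributes
    to all m sums.  Pathways with no observed member get 0."""
    for ko in ko_abund.feature_ids:
        if ko not in catalog.pathways:
            raise KeyError(f"KO {ko!r} absent from catalog")
    members = catalog.pathway_members()
    observed = set(ko_abund.feature_ids)
    rows = {}
    for pw in sorted(members):
        present = [ko for ko in members[pw] if ko in observed]
        if present:
            rows[pw] = ko_abund.data.loc[present].sum(axis=0)
        else:
            rows[pw] = pd.Series(0.0, index=ko_abund.data.columns)
    df = pd.DataFrame(rows).T
    df.columns = ko_abund.data.columns
    return NormalizedAbundanceTable(df, feature_kind="pathway")


def normalize_per_genome(
    table: NormalizedAbundanceTable, ge: GenomeEquivalents
) -> NormalizedAbundanceTable:
    """Divide each sample column by the sample's genome-equivalent estimate.

    Applied identically to KO, pathway, degradation-gene, and phage-contig
    abundance tables — the same two-step normalization serves all of them.
    """
    for sid in table.sample_ids:
        if sid not in ge.values.index:
            raise KeyError(f"no genome-equivalent estimate for sample {sid!r}")
    divisors = ge.values[table.sample_ids]
    df = table.data.div(divisors, axis=1)
    return NormalizedAbundanceTable(df, feature_kind=table.feature_kind)
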