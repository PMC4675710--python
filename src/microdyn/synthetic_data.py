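"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure function of its parameters and a seed, and every
generated data set ships its planted truth, so each downstream stage can be
tested as an inverse problem: generate with known structure, analyse,
compare to the plant.

What is emulated: the 11-sample two-arm time-course design; a majority of
pathways with flat abundance plus a minority oscillating in log2 space
(drastic rise at week 1, fall at week 3, slight re-rise at week 6);
marker-gene counts consistent with a planted per-sample genome-equivalent;
a transient host bloom followed by a phage-contig bloom in the polluted arm
only; and pairwise best-hit bit-score summaries with controllable pool
similarity.  Noise models are the simplest consistent with count data:
multiplicative lognormal on abundances, Poisson on read counts.  No
sequence-level structure is simulated — counts and scores only.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import KOCatalog, MarkerSet, default_marker_lengths, default_marker_set
from .genepool_distance import PairwiseBitScoreSummary
from .table_io import (
    CountTable,
    NormalizedAbundanceTable,
    SampleDesign,
    default_design,
)

__all__ = [
    "PathwayArchetype",
    "BloomSpec",
    "simulate_pathway_tables",
    "simulate_marker_and_ko_counts",
    "simulate_phage_bloom",
    "make_filter_fixture",
    "simulate_blast_summaries",
    "m1m2_preset",
    "bloom_preset",
    "filter_preset",
    "default_catalog",
]


@dataclass(frozen=True)
class PathwayArchetype:
    """Expected log2 step change per sampled week, plus lognormal noise sd
    (in log2 space) applied independently at every time point."""

    name: str
    log2_shifts: Mapping[int, float]  # week -> expected log2 change vs previous week
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def cumulative(self, weeks: list[int]) -> np.ndarray:
        """Cumulative log2 offset at each week of the series (0 at baseline)."""
        missing = [w for w in weeks[1:] if w not in self.log2_shifts]
        if missing:
            raise ValueError(
                f"archetype {self.name!r} lacks shifts for weeks {missing}"
            )
        out = [0.0]
        for w in weeks[1:]:
            out.append(out[-1] + float(self.log2_shifts[w]))
        return np.array(out)


#: The oscillating minority pattern: drastic rise at week 1, fall back at
#: week 3, slight re-rise at week 6, then flat.  The magnitudes are a
#: well-separated-from-noise default; the study reported the shape, not the
#: log2 sizes.
RESPONSIVE_SHIFTS = {1: 3.0, 3: -3.0, 6: 1.0, 12: 0.0, 24: 0.0}
CONSTANT_SHIFTS = {1: 0.0, 3: 0.0, 6: 0.0, 12: 0.0, 24: 0.0}


def simulate_pathway_tables(
    design: SampleDesign,
    n_constant: int,
    n_responsive: int,
    archetypes: tuple[PathwayArchetype, PathwayArchetype] | None = None,
    baseline_abundance: float = 0.01,
    seed: int = 0,
    arm: str = "polluted",
) -> tuple[NormalizedAbundanceTable, pd.Series]:
    """Plant a constant-majority / responsive-minority pathway table.

    Returns the normalized pathway abundance table over one arm's time
    series (baseline week 0 included) and the planted truth labels
    ('constant' / 'responsive') per pathway.
    """
    if n_constant + n_responsive < 2:
        raise ValueError("need at least 2 pathways in total")
    if archetypes is None:
        archetypes = (
            PathwayArchetype("constant", CONSTANT_SHIFTS, 0.0),
            PathwayArchetype("responsive", RESPONSIVE_SHIFTS, 0.0),
        )
    const_arch, resp_arch = archetypes
    series = design.arm_series(arm)
    weeks = [s.week for s in series]
    sample_ids = [s.sample_id for s in series]
    rng = np.random.default_rng(seed)

    rows = []
    ids = []
    labels = []
    for group, arch, n in (
        ("constant", const_arch, n_constant),
        ("responsive", resp_arch, n_responsive),
    ):
        cum = arch.cumulative(weeks)
        for i in range(n):
            eps = rng.normal(0.0, arch.noise_sd, size=len(weeks)) if arch.noise_sd else 0.0
            rows.append(baseline_abundance * np.power(2.0, cum + eps))
            ids.append(f"pw_{group}_{i:03d}")
            labels.append(group)
    table = NormalizedAbundanceTable(
        pd.DataFrame(np.array(rows), index=ids, columns=sample_ids),
        feature_kind="pathway",
    )
    truth = pd.Series(labels, index=ids, name="group")
    return table, truth


def simulate_marker_and_ko_counts(
    design: SampleDesign,
    catalog: KOCatalog,
    markers: MarkerSet,
    genome_equivalents_truth: Mapping[str, float],
    seed: int = 0,
    noise: bool = True,
) -> CountTable:
    """Marker-gene read counts consistent with a planted genome-equivalent
    per sample: expected count = truth(sample) x marker length, Poisson
    sampled unless ``noise`` is off."""
    for m in markers.marker_ids:
        if m not in catalog.median_length:
            raise KeyError(f"marker {m!r} missing from catalog")
    rng = np.random.default_rng(seed)
    sample_ids = design.sample_ids
    counts = np.zeros((len(markers), len(sample_ids)), dtype=np.int64)
    for i, m in enumerate(markers.marker_ids):
        length = catalog.median_length[m]
        for j, sid in enumerate(sample_ids):
            truth = genome_equivalents_truth[sid]
            if truth <= 0:
                raise ValueError(f"planted genome equivalents must be positive ({sid!r})")
            lam = truth * length
            counts[i, j] = rng.poisson(lam) if noise else int(round(lam))
    df = pd.DataFrame(counts, index=list(markers.marker_ids), columns=sample_ids)
    return CountTable(df, feature_kind="ko")


@dataclass(frozen=True)
class BloomSpec:
    """A transient host bloom and its trailing phage-contig bloom."""

    host_feature: str = "Burkholderia"
    host_peak_week: int = 1
    host_fold: float = 23.0
    phage_contig_id: str = "contig_A"
    phage_contig_length: int = 44_500
    phage_peak_week: int = 6
    phage_fold: float = 17_000.0

    def __post_init__(self) -> None:
        if self.host_fold < 1 or self.phage_fold < 1:
            raise ValueError("bloom folds must be >= 1")
        if self.phage_contig_length <= 0:
            raise ValueError("contig length must be positive")


def _bloom_series(
    weeks: list[int], peak_week: int, fold: float, baseline: int
) -> np.ndarray:
    if peak_week not in weeks:
        raise ValueError(f"peak week {peak_week} not in sampled weeks {weeks}")
    out = np.full(len(weeks), baseline, dtype=np.int64)
    out[weeks.index(peak_week)] = int(round(fold * baseline))
    return out


def simulate_phage_bloom(
    design: SampleDesign,
    spec: BloomSpec | None = None,
    baseline_hits: int = 10,
    seed: int = 0,
    noise: bool = False,
) -> tuple[CountTable, CountTable]:
    """Host genus counts and phage-contig hit counts across the full design.

    The bloom appears in the polluted arm only: the host peaks at
    ``host_peak_week`` at ``host_fold`` x baseline, the contig at
    ``phage_peak_week`` at ``phage_fold`` x baseline; the control arm stays
    flat at baseline.  Optional Poisson noise on all counts.
    """
    if spec is None:
        spec = BloomSpec()
    if baseline_hits < 1:
        raise ValueError("baseline_hits must be >= 1")
    rng = np.random.default_rng(seed)
    sample_ids = design.sample_ids
    polluted = design.arm_series("polluted")
    pol_weeks = [s.week for s in polluted]

    host = np.full(len(sample_ids), baseline_hits, dtype=np.int64)
    contig = np.full(len(sample_ids), baseline_hits, dtype=np.int64)
    host_pol = _bloom_series(pol_weeks, spec.host_peak_week, spec.host_fold, baseline_hits)
    contig_pol = _bloom_series(pol_weeks, spec.phage_peak_week, spec.phage_fold, baseline_hits)
    for s, h, c in zip(polluted, host_pol, contig_pol):
        j = sample_ids.index(s.sample_id)
        host[j] = h
        contig[j] = c
    if noise:
        host = rng.poisson(host)
        contig = rng.poisson(contig)
    host_table = CountTable(
        pd.DataFrame(host[None, :], index=[spec.host_feature], columns=sample_ids),
        feature_kind="genus",
    )
    contig_table = CountTable(
        pd.DataFrame(contig[None, :], index=[spec.phage_contig_id], columns=sample_ids),
        feature_kind="contig",
    )
    return host_table, contig_table


def make_filter_fixture(
    n_total: int,
    n_nonprok: int,
    n_below_cutoff: int,
    n_with_zero: int,
    seed: int = 0,
    cutoff: float = 1e-4,
    design: SampleDesign | None = None,
    arm: str = "polluted",
) -> tuple[NormalizedAbundanceTable, dict[str, bool], pd.Series]:
    """Pathway table in which exactly the declared numbers of pathways
    violate each exclusion rule (non-prokaryotic / below cutoff throughout /
    zero somewhere), with disjoint failure sets; all others pass all three.
    """
    n_fail = n_nonprok + n_below_cutoff + n_with_zero
    if n_fail > n_total:
        raise ValueError("failure counts exceed the total pathway count")
    design = design or default_design()
    sample_ids = [s.sample_id for s in design.arm_series(arm)]
    n_cols = len(sample_ids)
    rng = np.random.default_rng(seed)

    rows, ids, flags, status = [], [], {}, []
    good_level = 100 * cutoff

    def add(pw_id: str, row: np.ndarray, prok: bool, why: str) -> None:
        ids.append(pw_id)
        rows.append(row)
        flags[pw_id] = prok
        status.append(why)

    for i in range(n_nonprok):
        add(f"pw_nonprok_{i:03d}",
            good_level * rng.uniform(0.5, 2.0, n_cols), False, "nonprok")
    for i in range(n_below_cutoff):
        # positive everywhere but never reaching the cutoff
        add(f"pw_low_{i:03d}",
            cutoff * rng.uniform(0.1, 0.9, n_cols), True, "below_cutoff")
    for i in range(n_with_zero):
        row = good_level * rng.uniform(0.5, 2.0, n_cols)
        row[rng.integers(0, n_cols)] = 0.0
        add(f"pw_zero_{i:03d}", row, True, "has_zero")
    for i in range(n_total - n_fail):
        add(f"pw_ok_{i:03d}",
            good_level * rng.uniform(0.5, 2.0, n_cols), True, "pass")

    table = NormalizedAbundanceTable(
        pd.DataFrame(np.array(rows), index=ids, columns=sample_ids),
        feature_kind="pathway",
    )
    truth = pd.Series(status, index=ids, name="status")
    return table, flags, truth


def simulate_blast_summaries(
    design: SampleDesign,
    self_scores: Mapping[str, float],
    similarity: Mapping[tuple[str, str], float],
    seed: int = 0,
) -> PairwiseBitScoreSummary:
    """Pairwise best-hit bit-score summaries with planted pool similarity:
    S(A->B) = similarity(A,B) x self_score(A), all ordered pairs present.

    ``similarity`` is symmetric (either orientation may be supplied);
    similarity(A,A) is fixed at 1.
    """
    ids = design.sample_ids
    scores: dict[tuple[str, str], float] = {}
    for a in ids:
        if a not in self_scores or self_scores[a] <= 0:
            raise ValueError(f"positive self score required for sample {a!r}")
    for a in ids:
        for b in ids:
            if a == b:
                sim = 1.0
            elif (a, b) in similarity:
                sim = similarity[(a, b)]
            elif (b, a) in similarity:
                sim = similarity[(b, a)]
            else:
                raise ValueError(f"missing similarity for pair ({a!r}, {b!r})")
            if not (0.0 <= sim <= 1.0):
                raise ValueError(f"similarity for ({a!r}, {b!r}) outside [0, 1]")
            scores[(a, b)] = sim * self_scores[a]
    return PairwiseBitScoreSummary(list(ids), scores)


# ---------------------------------------------------------------------------
# Presets: the study conditions, runnable as a single call.

def m1m2_preset(
    seed: int = 0,
    n_constant: int = 100,
    n_responsive: int = 46,
    noise_sd: float = 0.1,
) -> tuple[NormalizedAbundanceTable, pd.Series]:
    """Constant-majority (100) / oscillating-minority (46) pathway table on
    the polluted arm's six time points, lognormal noise sd 0.1 in log2."""
    archetypes = (
        PathwayArchetype("constant", CONSTANT_SHIFTS, noise_sd),
        PathwayArchetype("responsive", RESPONSIVE_SHIFTS, noise_sd),
    )
    return simulate_pathway_tables(
        default_design(), n_constant, n_responsive, archetypes, seed=seed
    )


def bloom_preset(seed: int = 0, noise: bool = False) -> tuple[CountTable, CountTable, BloomSpec]:
    """Host bloom at week 1 (23x) followed by a phage-contig bloom at week 6."""
    spec = BloomSpec()
    host, contig = simulate_phage_bloom(default_design(), spec, seed=seed, noise=noise)
    return host, contig, spec


def filter_preset(seed: int = 0):
    """The 160-pathway filter fixture: 8 non-prokaryotic, 4 below cutoff,
    2 with a zero — 146 survivors."""
    return make_filter_fixture(160, 8, 4, 2, seed=seed)


def default_catalog(n_extra_kos: int = 20, seed: int = 0) -> KOCatalog:
    """A small synthetic KO catalog: the default marker panel plus
    ``n_extra_kos`` demo KOs spread over a handful of pathways."""
    rng = np.random.default_rng(seed)
    lengths = dict(default_marker_lengths())
    pathways: dict[str, frozenset[str]] = {m: frozenset() for m in lengths}
    flags: dict[str, bool] = {}
    pw_ids = [f"map{i:05d}" for i in range(1, 6)]
    for pw in pw_ids:
        flags[pw] = True
    for i in range(n_extra_kos):
        ko = f"K{i + 1:05d}"
        lengths[ko] = int(rng.integers(150, 900))
        k = int(rng.integers(1, 3))
        members = rng.choice(pw_ids, size=k, replace=False)
        pathways[ko] = frozenset(str(p) for p in members)
    return KOCatalog(lengths, pathways, flags)


def write_truth(truth: pd.Series, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_frame().to_csv(path, sep="\t")
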