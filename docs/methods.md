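# Methods

## Study design assumed throughout

The default `SampleDesign` is an 11-sample microcosm time course: one
baseline sample at week 0 shared by both arms, and control and polluted
arms sampled at weeks 1, 3, 6, 12 and 24. Each arm's time series therefore
has six points and five week-to-week transitions. All operations accept
arbitrary designs satisfying the same invariants (one week-0 baseline,
unique weeks per arm).

## Normalization model

Raw read counts confound gene length, sequencing depth and community
genome count. The pipeline removes them in two steps:

1. **Length normalization**: count / feature length. Protein-family
   features (KOs, genes) use amino-acid lengths (the catalog's median
   protein length per KO); contigs use bp. The `feature_kind` tag prevents
   mixing the two unit systems.
2. **Genome-equivalent normalization**: division by the per-sample genome
   equivalents — the arithmetic mean of count/length over a fixed panel of
   36 single-copy marker genes (*gyrB* + 35 universal single-copy genes).

The mean is always taken over the full panel: a marker with zero reads
contributes 0 rather than being dropped. Dropping absent markers would
bias the estimate upward exactly in the shallow samples where depth
correction matters most. This choice is test-pinned
(`test_absent_marker_counts_as_zero_in_mean`).

The exact published 36-gene panel is not redistributable here; the default
`MarkerSet` ships a documented synthetic stand-in (*gyrB* plus ribosomal
proteins and tRNA synthetases with typical bacterial lengths) and both the
ids and lengths are plain inputs (`MarkerSet.from_file`,
`KOCatalog.from_tsv`), so a user supplies their own panel for real data.

Pathway abundance is the sum of member-KO abundances; a KO belonging to m
pathways contributes to all m sums (no splitting). The whole chain is
linear in counts, which gives the central invariant: multiplying a
sample's counts by any constant leaves its per-genome abundances unchanged
(sequencing-depth invariance, asserted as a property test).

## Pathway dynamics

Pathways enter the variation analysis only if they (i) are prokaryotic,
(ii) reach a normalized abundance of at least `cutoff` (default 1e-4) at
some time point, and (iii) are nonzero at every analysed sample. Rule
(iii) is interpreted as "zero anywhere excludes": V_p(t) is a log ratio
and is undefined at zeros, and imputing pseudo-counts would manufacture
cluster structure. The filter is a hard gate; `variation_scores` raises on
zeros rather than imputing.

V_p(t) = log2 K_p(t)/K_p(t−1) is computed over consecutive sampled weeks
regardless of their spacing, so six time points give exactly five scores.
Scores are scale-invariant per pathway (any per-pathway constant cancels),
another property test.

Clustering is Euclidean k-means on the score vectors for each k in
[2, 10], best of 100 restarts under a fixed seed (scikit-learn `KMeans`);
the k maximizing the Calinski–Harabasz index
CH = [B/(k−1)] / [W/(n−k)] is selected, smallest k on ties. CH is
implemented in-package (sum-of-squares form, +inf when W = 0) and is
cross-checked in tests against both a plain-Python brute-force oracle and
`sklearn.metrics.calinski_harabasz_score` at relative tolerance 1e-9. The
k-range default [2, 10] reflects that CH is undefined at k = 1 and that
~150 profiles cannot support many more clusters; it is a parameter.

Cluster labelling: the cluster whose centroid has the smallest Euclidean
norm is "constant" (no systematic step change at any transition); all
others are "responsive". Ties go to the lowest cluster index.

Control and polluted arms are scored and clustered independently.

## Community structure

Shannon–Wiener diversity uses the natural log (the field's convention;
base choice only rescales comparisons). Sample distance is 1 − Pearson r
of abundance vectors, complete-linkage agglomerated via
`scipy.cluster.hierarchy.linkage`; dendrograms export as Newick through
scikit-bio. Tied merge distances are resolved by scipy's deterministic
internal order rather than a bespoke lexicographic rule; fixtures used for
order-invariance tests are tie-free. Genus co-occurrence clustering reuses
the same distance on time profiles (features as observations) and cuts the
dendrogram at k (default 4, explicit because no published cut rule
exists). Top-N genus selection ranks by maximum relative abundance across
samples (default) so that transient bloomers are retained; mean-ranking is
available.

## Gene-pool distance

S(A→B) sums, over A's reads, the best-hit bit score against B's read set
(hits with e-value > 0.01 discarded; reads without hits contribute 0). The
distance

    D2(A,B) = 1 − (S(A→B) + S(B→A)) / (S(A→A) + S(B→B))

is the package's single point of interpretive freedom: the original
formulation is only cited, not printed, in the source literature. The
symmetric self-normalized form above was adopted because it has every
property the analysis relies on — identical pools give 0, disjoint pools
give 1, best-hit bit scores normalize library-size differences, and the
result is a valid input to complete-linkage clustering. It is isolated in
`d2_matrix` so an alternative can be swapped in. Cross-scores exceeding
the self-score pair (possible with heuristic alignment) clamp to D2 = 0.

## Phage–host dynamics

A contig is a putative phage-genome contig iff it is >2 kb (strict),
belongs to the phage genome-related contig set, has at least one CDS with
≥40% amino-acid identity (inclusive) to a phage ortholog family, and
contains at least one phage-derived region call. The accepted set shrinks
monotonically as thresholds rise (property test).

Kill-the-winner is a narrative inference in the field; the package
operationalizes it on matched host/phage weekly series as the conjunction
of three testable conditions: (1) the phage peak lags the host peak
(peaks = argmax, earliest week on ties); (2) the phage fold rise from its
baseline week is at least `min_phage_fold` (default 100); (3) the host has
declined from its own peak by at least `min_host_decline_fold` (default 2)
at the phage's peak week. Fold baselines are explicit parameters defaulting
to each series' earliest week (a phage effectively absent before its bloom
is naturally referenced to its first observed week). The defaults are
chosen so that a bloom of the observed scale (host 23×, phage ~10⁴×, lag
5 weeks, host back at baseline) raises the flag; they are parameters, not
claims about a universal threshold. The detector is scale-invariant in
both series.

## Synthetic-data generator

Every generator is a pure function of (parameters, seed) via
`numpy.random.default_rng`. Noise models are the simplest consistent with
count data: multiplicative lognormal on abundances (Gaussian in log2
space, independent per feature and time point) and Poisson on read counts.
Defaults encode the study conditions:

- `m1m2_preset`: 100 constant + 46 responsive pathways on the polluted
  arm's six time points; responsive log2 step shifts (+3, −3, +1, 0, 0) —
  a drastic rise at week 1, fall at week 3, slight re-rise at week 6 —
  and noise sd 0.1. The step magnitudes are the generator's own choice
  (the shape is reported in the field, the log2 sizes are not); they are
  set well clear of the noise floor.
- `bloom_preset`: host bloom 23× at week 1, phage-contig bloom 17 000× at
  week 6 on a 44.5-kb contig, polluted arm only, control flat.
- `filter_preset`: 160 pathways of which 8 non-prokaryotic, 4 below the
  abundance cutoff throughout, 2 with a zero — 146 survivors.

What the generator does *not* emulate: compositional coupling between
features, overdispersion beyond Poisson, correlated noise across time
points, assembly and mapping artefacts, and any sequence-level structure.
Passing recovery tests therefore demonstrates correctness of the
estimators and the identifiability of the planted structure under simple
noise — not robustness to real-data pathologies.

## Numerical and degenerate-input choices

- Best-hit ties (equal bit scores) go to the lexicographically smallest
  subject id; determinism is required for testing.
- Reads hitting the curated database but absent from the comprehensive
  database are retained by `confirm_inhouse` (the curated hit is then
  trivially the best known hit); this unaddressed edge case is a
  documented choice.
- k-means fits that collapse to fewer than k distinct clusters (duplicate
  points) are skipped during model selection; CH = +inf (W = 0) is allowed
  and compares as larger than any finite CH, with ties to smaller k.
- `GenomeEquivalents` refuses non-positive estimates: normalization by a
  zero is meaningless and silently producing inf would poison everything
  downstream.
- Distance matrices are symmetrized ((D + Dᵀ)/2) and clipped to their
  theoretical ranges before validation to absorb floating-point drift.

## Problem sizes

Tests and the acceptance script run the study-scale problems directly
(146 × 5 score vectors, 11 × 11 score matrices, six-point series); the
Monte-Carlo check of marker-count estimation uses 200 replicate draws of a
36-marker panel. These sizes are the analysis' natural scale.

## Known limitations

- The D2 form is an interpretation (see above).
- The dendrogram tie-break differs from a strict lexicographic rule (it
  follows scipy's deterministic merge order).
- The default marker panel is a synthetic stand-in; real analyses must
  supply their own panel and KO catalog.
- No ordination, no alternative cluster-count criteria, no lysogenic/lytic
  inference — out of scope by design.
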