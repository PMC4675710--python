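# microdyn

Quantitative analysis of time-series soil-microcosm metagenomes: how does a
microbial community's taxonomic structure and gene pool respond to — and
recover from — a chemical disturbance such as aromatic-compound pollution?

The package is aimed at microbial ecologists working with count tables
derived from shotgun metagenome time courses (a baseline sample plus
control and disturbed arms sampled over weeks). It provides:

- **Genome-equivalent normalization.** Per-sample genome equivalents are
  estimated as the mean length-normalized abundance of 36 marker genes
  (*gyrB* plus 35 universal single-copy genes). KO, pathway, gene and
  contig read counts are divided by feature length and then by the genome
  equivalents, giving per-genome copy numbers that are invariant to
  sequencing depth.
- **Pathway-dynamics clustering.** Each pathway's normalized abundance
  series K_p(t) is reduced to step scores V_p(t) = log2 K_p(t)/K_p(t−1)
  over consecutive sampled weeks; the score vectors are k-means clustered,
  the cluster count chosen by maximizing the Calinski–Harabasz index
  CH = [B/(k−1)]/[W/(n−k)], and clusters are labelled *constant* (centroid
  nearest the origin) or *responsive*.
- **Community structure.** Relative abundances, Shannon–Wiener diversity
  H′ = −Σ pᵢ ln pᵢ, 1 − Pearson correlation distances with complete-linkage
  clustering of samples, and genus co-occurrence clustering of time
  profiles.
- **Gene-pool distances.** From all-against-all best-hit bit-score sums
  S(A→B), the distance D2(A,B) = 1 − (S(A→B)+S(B→A))/(S(A→A)+S(B→B)).
- **Phage–host asynchrony.** Classification of putative phage-genome
  contigs (>2 kb, phage-related, ≥40% identity to a phage ortholog family,
  ≥1 phage-derived region) and detection of the "kill-the-winner" pattern:
  a phage-contig abundance peak lagging a transient host bloom, with the
  host declining by the time the phage peaks.
- **Read assignment.** Best-hit assignment from BLAST tabular output with
  identity/bit-score thresholds, two-stage confirmation against a curated
  database, and the curated-database construction filter.
- **Synthetic data.** Every pipeline input can be generated with planted
  structure (pathway archetypes, marker counts, blooms, pairwise scores),
  so the whole analysis is testable without any sequence data.

## Worked example

Simulate the two-regime pathway structure (100 constant + 46 oscillating
pathways over the six sampled weeks of the polluted arm, lognormal noise
sd 0.1 in log2 space) and recover it:

```python
from microdyn.synthetic_data import m1m2_preset
from microdyn.pathway_dynamics import (
    variation_scores, cluster_variation_profiles, label_clusters,
)

table, truth = m1m2_preset(seed=42)
profiles = variation_scores(table)
print("pathways:", len(profiles), " scores per pathway:", len(profiles[0].scores))
result = cluster_variation_profiles(profiles, seed=42)
print("CH-selected k:", result.k_selected)
names = label_clusters(result)
for c, size in sorted(result.cluster_sizes().items()):
    print(f"cluster {c}: {size} pathways -> {names[c]}")
```

prints

```
pathways: 146  scores per pathway: 5
CH-selected k: 2
cluster 0: 100 pathways -> constant
cluster 1: 46 pathways -> responsive
```

Each of the 146 pathways contributes five V scores (one per week-to-week
step, t = 1, 3, 6, 12, 24); the CH index peaks at k = 2 (6807 vs 4056 at
k = 3), and the constant/responsive labelling recovers the planted group
sizes exactly.

The same stages are available from the shell:

```sh
microdyn simulate --preset m1m2 --seed 42 --out sim/
microdyn dynamics --pathway-table sim/pathway_abundance.tsv --seed 42 --out dyn/
```

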