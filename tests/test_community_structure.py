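import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from microdyn.community_structure import (
    SampleDistanceMatrix,
    cooccurrence_clusters,
    correlation_distance,
    hclust_complete,
    relative_abundance,
    shannon_index,
    top_features,
)
from microdyn.table_io import CountTable

from conftest import make_abundance


def counts(rows, index, columns, kind="otu"):
    return CountTable(pd.DataFrame(rows, index=index, columns=columns), feature_kind=kind)


def brute_force_complete_cut(dist: np.ndarray, ids, k):
    """Oracle: naive agglomeration tracking max inter-cluster distance."""
    clusters = [{i} for i in range(len(ids))]
    while len(clusters) > k:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        clusters[a] |= clusters[b]
        del clusters[b]
    partition = {}
    for c, members in enumerate(clusters):
        for i in members:
            partition[ids[i]] = c
    return partition


def same_partition(p1, p2):
    groups1 = {}
    for key, lab in p1.items():
        groups1.setdefault(lab, set()).add(key)
    groups2 = {}
    for key, lab in p2.items():
        groups2.setdefault(lab, set()).add(key)
    return set(map(frozenset, groups1.values())) == set(map(frozenset, groups2.values()))


class TestRelativeAbundance:
    def test_simple_proportions(self):
        t = counts([[2], [3], [5]], ["a", "b", "c"], ["s1"])
        rel = relative_abundance(t)
        assert rel.data["s1"].tolist() == pytest.approx([0.2, 0.3, 0.5])

    def test_single_feature_gives_one(self):
        t = counts([[17]], ["a"], ["s1"])
        assert relative_abundance(t).data.loc["a", "s1"] == 1.0

    def test_columns_sum_to_one_on_random_tables(self):
        rng = np.random.default_rng(3)
        t = counts(rng.integers(0, 50, size=(6, 4)) + 1, list("abcdef"), list("wxyz"))
        sums = relative_abundance(t).data.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_zero_sample_is_error(self):
        t = counts([[0]], ["a"], ["s1"])
        with pytest.raises(ValueError, match="s1"):
            relative_abundance(t)


class TestShannonIndex:
    def test_single_category_is_zero(self):
        t = make_abundance([[1.0]], ["a"], ["s1"])
        assert shannon_index(t)["s1"] == 0.0

    def test_uniform_four_is_ln4(self):
        t = make_abundance([[0.25]] * 4, list("abcd"), ["s1"])
        assert shannon_index(t)["s1"] == pytest.approx(np.log(4))

    def test_half_quarter_quarter(self):
        t = make_abundance([[0.5], [0.25], [0.25]], list("abc"), ["s1"])
        # 0.5 ln2 + 0.5 ln4 = 1.5 ln2 = 1.0397...
        assert shannon_index(t)["s1"] == pytest.approx(1.0397, abs=1e-4)

    def test_unnormalized_input_rejected(self):
        t = make_abundance([[2.0]], ["a"], ["s1"])
        with pytest.raises(ValueError, match="sum to 1"):
            shannon_index(t)

    def test_uniform_maximises_over_simplex_grid(self):
        # H' is maximal at the uniform distribution, zero iff one category
        grid = np.linspace(0, 1, 11)
        best = np.log(3)
        for p1 in grid:
            for p2 in grid:
                p3 = 1 - p1 - p2
                if p3 < -1e-12:
                    continue
                t = make_abundance([[p1], [p2], [max(p3, 0.0)]], list("abc"), ["s1"])
                h = shannon_index(t)["s1"]
                assert h <= best + 1e-9
                if sorted([p1, p2, max(p3, 0)])[2] == 1.0:
                    assert h == pytest.approx(0.0, abs=1e-12)


class TestCorrelationDistance:
    def test_identical_columns_give_zero(self):
        t = make_abundance([[1, 1], [2, 2], [3, 3]], list("abc"), ["s1", "s2"])
        assert correlation_distance(t).data.loc["s1", "s2"] == pytest.approx(0.0)

    def test_anticorrelated_columns_give_two(self):
        t = make_abundance([[1, 3], [2, 2], [3, 1]], list("abc"), ["s1", "s2"])
        assert correlation_distance(t).data.loc["s1", "s2"] == pytest.approx(2.0)

    def test_symmetric_on_random_input(self):
        rng = np.random.default_rng(8)
        t = make_abundance(rng.uniform(size=(10, 5)), [f"f{i}" for i in range(10)],
                           list("vwxyz"))
        d = correlation_distance(t).data.to_numpy()
        assert np.allclose(d, d.T, atol=1e-12)
        assert np.allclose(np.diag(d), 0.0)

    def test_constant_sample_is_error(self):
        t = make_abundance([[1, 5], [1, 2]], ["a", "b"], ["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            correlation_distance(t)

    def test_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(size=(6, 4))
        t1 = make_abundance(vals, [f"f{i}" for i in range(6)], list("wxyz"))
        scaled = vals * np.array([2.0, 0.5, 7.0, 1.3]) + np.array([1.0, 0.2, 0.0, 3.0])
        t2 = make_abundance(scaled, [f"f{i}" for i in range(6)], list("wxyz"))
        pd.testing.assert_frame_equal(
            correlation_distance(t1).data, correlation_distance(t2).data, atol=1e-12
        )


class TestHclustComplete:
    def planted_two_group_distance(self):
        # two tight groups of 3 samples: each group shares a base feature
        # profile, samples deviate by small noise (tie-free distances)
        rng = np.random.default_rng(12)
        bases = rng.uniform(0.1, 1.0, size=(2, 8))
        profiles = np.vstack([
            bases[0] + rng.normal(0, 0.01, size=(3, 8)),
            bases[1] + rng.normal(0, 0.01, size=(3, 8)),
        ])
        t = make_abundance(np.abs(profiles.T), [f"f{i}" for i in range(8)],
                           [f"s{i}" for i in range(6)])
        return correlation_distance(t)

    def test_two_planted_groups_recovered(self):
        dist = self.planted_two_group_distance()
        _, labels = hclust_complete(dist, k=2)
        expected = {f"s{i}": (0 if i < 3 else 1) for i in range(6)}
        assert same_partition(labels, expected)

    def test_matches_brute_force_oracle(self):
        dist = self.planted_two_group_distance()
        for k in (2, 3):
            _, labels = hclust_complete(dist, k=k)
            oracle = brute_force_complete_cut(dist.data.to_numpy(), dist.ids, k)
            assert same_partition(labels, oracle)

    def test_two_samples_merge_at_their_distance(self):
        d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
        dend = hclust_complete(SampleDistanceMatrix(d))
        assert dend.linkage_matrix.shape == (1, 4)
        assert dend.linkage_matrix[0, 2] == pytest.approx(0.4)

    def test_cut_partition_invariant_to_input_order(self):
        dist = self.planted_two_group_distance()
        perm = [3, 0, 5, 1, 4, 2]
        ids = [dist.ids[i] for i in perm]
        permuted = SampleDistanceMatrix(dist.data.iloc[perm, perm])
        assert permuted.ids == ids
        _, l1 = hclust_complete(dist, k=2)
        _, l2 = hclust_complete(permuted, k=2)
        assert same_partition(l1, l2)

    def test_cut_beyond_leaf_count_is_error(self):
        dist = self.planted_two_group_distance()
        with pytest.raises(ValueError):
            hclust_complete(dist, k=7)

    def test_newick_output_is_parseable_with_all_leaves(self):
        dist = self.planted_two_group_distance()
        dend = hclust_complete(dist)
        tree = TreeNode.read([dend.to_newick()])
        assert {t.name for t in tree.tips()} == set(dist.ids)


class TestCooccurrence:
    def archetype_profiles(self, copies=3):
        # four co-occurrence archetypes over 6 time points
        shapes = {
            "early": [1, 10, 2, 1, 1, 1],
            "mid": [1, 2, 10, 8, 1, 1],
            "late": [1, 1, 1, 2, 6, 10],
            "dip": [10, 2, 1, 1, 5, 9],
        }
        rows, ids = [], []
        for name, shape in shapes.items():
            for i in range(copies):
                rows.append(np.array(shape, dtype=float) * (1 + 0.1 * i))
                ids.append(f"{name}_{i}")
        return make_abundance(rows, ids, list("abcdef"), kind="genus")

    def test_archetype_pure_recovery(self):
        profiles = self.archetype_profiles()
        labels = cooccurrence_clusters(profiles, k=4)
        for name in ("early", "mid", "late", "dip"):
            group = {labels[f"{name}_{i}"] for i in range(3)}
            assert len(group) == 1
        assert len(set(labels.values())) == 4

    def test_single_cluster_contains_everything(self):
        profiles = self.archetype_profiles(copies=1)
        labels = cooccurrence_clusters(profiles, k=1)
        assert set(labels.values()) == {0}

    def test_duplicated_profile_shares_label(self):
        profiles = self.archetype_profiles(copies=1)
        dup = make_abundance(
            np.vstack([profiles.data.to_numpy(), profiles.data.iloc[[0]].to_numpy()]),
            list(profiles.data.index) + ["early_copy"],
            list(profiles.data.columns),
            kind="genus",
        )
        labels = cooccurrence_clusters(dup, k=3)
        assert labels["early_0"] == labels["early_copy"]


class TestTopFeatures:
    def test_max_ranking_keeps_transient_bloomer(self):
        t = make_abundance(
            [[0.30, 0.30, 0.30], [0.05, 0.69, 0.05], [0.65, 0.01, 0.65]],
            ["steady", "bloomer", "dominant"],
            list("xyz"),
        )
        top2 = top_features(t, 2, ranking="max")
        assert set(top2.feature_ids) == {"bloomer", "dominant"}
        top2_mean = top_features(t, 2, ranking="mean")
        assert set(top2_mean.feature_ids) == {"steady", "dominant"}
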