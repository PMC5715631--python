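import numpy as np
import pytest
from scipy.spatial import distance as ssd
from scipy.stats import pearsonr

from genospace import (ClusteringError, Dendrogram, GenometricSpace,
                       bicluster, blob_space, cluster, cut, distance,
                       elbow_suggest, metadata_counts, to_newick)

from conftest import random_space
from oracles import naive_linkage_trace, threshold_partition

METRICS = ("EU", "MA", "EA", "CH", "CA", "PE")
LINKAGES = ("SINGLE", "AVERAGE", "COMPLETE")


def hand_dendrogram():
    """Five leaves, merge heights {1, 1, 1, 10}."""
    return Dendrogram(element_ids=("A", "B", "C", "D", "E"),
                      merges=((0, 1, 1.0), (2, 3, 1.0), (5, 6, 1.0),
                              (4, 7, 10.0)),
                      axis="rows", linkage="AVERAGE", metric="EU")


class TestDistance:
    @pytest.mark.parametrize("metric", METRICS)
    def test_identical_vectors_at_distance_zero(self, rng, metric):
        x = rng.uniform(1, 9, size=6)
        assert distance(x, x, metric) == pytest.approx(0.0, abs=1e-12)

    def test_earth_movers_prefix_sum_example(self):
        assert distance([1.0, 0.0], [0.0, 1.0], "EA") == 1.0
        assert distance([2.0, 0.0, 0.0], [0.0, 0.0, 2.0], "EA") == 4.0

    def test_canberra_zero_over_zero_terms_are_zero(self):
        assert distance([0.0, 0.0], [0.0, 0.0], "CA") == 0.0
        assert distance([0.0, 1.0], [0.0, 3.0], "CA") == pytest.approx(0.5)

    @pytest.mark.parametrize("metric, reference", [
        ("EU", ssd.euclidean), ("MA", ssd.cityblock),
        ("CH", ssd.chebyshev), ("CA", ssd.canberra),
    ])
    def test_minkowski_family_matches_scipy(self, rng, metric, reference):
        for _ in range(20):
            u = rng.uniform(-10, 10, size=7)
            v = rng.uniform(-10, 10, size=7)
            assert distance(u, v, metric) == pytest.approx(reference(u, v),
                                                           rel=1e-12)

    def test_pearson_distance_is_one_minus_r(self, rng):
        u = rng.uniform(0, 10, size=9)
        v = rng.uniform(0, 10, size=9)
        assert distance(u, v, "PE") == pytest.approx(1 - pearsonr(u, v)[0],
                                                     rel=1e-10)

    def test_pearson_rejects_zero_variance(self):
        with pytest.raises(ClusteringError, match="zero-variance"):
            distance([3.0, 3.0, 3.0], [1.0, 2.0, 3.0], "PE")

    def test_unknown_metric_rejected(self):
        with pytest.raises(ClusteringError):
            distance([1.0], [2.0], "L3")


class TestCluster:
    @pytest.mark.parametrize("linkage", LINKAGES)
    @pytest.mark.parametrize("metric", METRICS)
    def test_merge_trace_matches_naive_oracle(self, rng, linkage, metric):
        for _ in range(10):
            X = rng.uniform(0.5, 20, size=(8, 5))
            space = GenometricSpace.from_matrix(X)
            _, dendro = cluster(space, "rows", linkage, metric)
            leaf_d = [[distance(X[i], X[j], metric) for j in range(8)]
                      for i in range(8)]
            expected = naive_linkage_trace(leaf_d, linkage)
            for (li, ri, hi), (lo, ro, ho) in zip(dendro.merges, expected):
                assert (li, ri) == (lo, ro)
                assert hi == pytest.approx(ho, rel=1e-9)

    def test_identical_vectors_merge_first_at_height_zero(self):
        X = np.array([[5.0, 1.0], [0.0, 9.0], [5.0, 1.0], [9.0, 9.0]])
        _, dendro = cluster(GenometricSpace.from_matrix(X), "rows",
                            "AVERAGE", "EU")
        left, right, height = dendro.merges[0]
        assert (left, right, height) == (0, 2, 0.0)

    def test_thirtythree_columns_give_thirtytwo_merges(self, rng):
        space = random_space(rng, 5, 33)
        _, dendro = cluster(space, "columns", "SINGLE", "MA")
        assert dendro.n_leaves == 33
        assert len(dendro.merges) == 32

    def test_clustering_only_permutes_vectors(self, rng):
        space = random_space(rng, 9, 4)
        reordered, dendro = cluster(space, "rows", "COMPLETE", "EU")
        assert sorted(reordered.row_ids) == sorted(space.row_ids)
        original = {rid: row for rid, row in zip(space.row_ids, space.values)}
        for rid, row in zip(reordered.row_ids, reordered.values):
            np.testing.assert_array_equal(row, original[rid])
        assert tuple(reordered.row_ids) == dendro.leaves

    @pytest.mark.parametrize("metric", ["EU", "MA", "CH", "CA"])
    @pytest.mark.parametrize("linkage", LINKAGES)
    def test_heights_nondecreasing_for_true_metrics(self, rng, metric,
                                                    linkage):
        space = random_space(rng, 10, 5)
        _, dendro = cluster(space, "rows", linkage, metric)
        heights = dendro.heights
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_missing_cells_imputed_with_warning(self, rng):
        space = random_space(rng, 6, 4, missing=0.3)
        with pytest.warns(UserWarning, match="imputed"):
            cluster(space, "rows", "AVERAGE", "EU")

    def test_single_element_axis_rejected(self):
        space = GenometricSpace.from_matrix([[1.0, 2.0]])
        with pytest.raises(ClusteringError, match="at least 2"):
            cluster(space, "rows", "AVERAGE", "EU")


class TestBicluster:
    def test_row_order_matches_row_clustering(self, rng):
        space = random_space(rng, 8, 6)
        reordered, row_dendro, col_dendro = bicluster(space)
        rows_only, expected_dendro = cluster(space, "rows", "COMPLETE", "EU")
        assert reordered.row_ids == rows_only.row_ids
        assert row_dendro.merges == expected_dendro.merges

    def test_single_row_rejected(self):
        with pytest.raises(ClusteringError):
            bicluster(GenometricSpace.from_matrix([[1.0, 2.0]]))

    def test_planted_blocks_become_contiguous(self, rng):
        # block-diagonal: rows/cols interleaved on input
        base = np.kron(np.eye(3), np.ones((4, 4))) * 50
        noise = rng.normal(0, 0.1, size=base.shape)
        perm_r = rng.permutation(12)
        perm_c = rng.permutation(12)
        X = (base + noise)[np.ix_(perm_r, perm_c)]
        labels_r = (np.arange(12) // 4)[perm_r]
        space = GenometricSpace.from_matrix(X)
        reordered, _, _ = bicluster(space)
        order = [int(rid[1:]) for rid in reordered.row_ids]
        seen = [labels_r[i] for i in order]
        changes = sum(a != b for a, b in zip(seen, seen[1:]))
        assert changes == 2  # three contiguous blocks


class TestCut:
    def test_k_equals_leaves_gives_singletons(self):
        dendro = hand_dendrogram()
        patterns = cut(dendro, 5)
        assert patterns.counts == (1, 1, 1, 1, 1)

    def test_k_one_groups_everything(self):
        patterns = cut(hand_dendrogram(), 1)
        assert patterns.counts == (5,)
        assert set(patterns.membership.values()) == {0}

    def test_cut_matches_threshold_oracle(self, rng):
        for _ in range(15):
            space = random_space(rng, 10, 4)
            _, dendro = cluster(space, "rows", "AVERAGE", "EU")
            k = int(rng.integers(1, 11))
            patterns = cut(dendro, k)
            roots = threshold_partition(dendro.merges, 10, k)
            # same partition up to label renaming
            mapping = {}
            for eid, root in zip(dendro.element_ids, roots):
                pattern = patterns.membership[eid]
                assert mapping.setdefault(root, pattern) == pattern
            assert len(set(mapping.values())) == k

    def test_every_leaf_in_exactly_one_pattern(self, rng):
        space = random_space(rng, 12, 4)
        _, dendro = cluster(space, "rows", "COMPLETE", "MA")
        patterns = cut(dendro, 4)
        assert sorted(patterns.membership) == sorted(space.row_ids)
        assert sum(patterns.counts) == 12

    def test_representative_label_is_first_leaf_of_pattern(self):
        patterns = cut(hand_dendrogram(), 2)
        leaves = hand_dendrogram().leaves
        assert patterns.labels[0] == leaves[0]

    def test_centroids_are_pattern_means(self, rng):
        space = random_space(rng, 8, 3)
        reordered, dendro = cluster(space, "rows", "AVERAGE", "EU")
        patterns = cut(dendro, 3, space=reordered)
        for p in range(3):
            members = patterns.members(p)
            idx = [reordered.row_ids.index(m) for m in members]
            np.testing.assert_allclose(patterns.centroids[p],
                                       reordered.values[idx].mean(axis=0))

    def test_out_of_range_k_rejected(self):
        with pytest.raises(ClusteringError):
            cut(hand_dendrogram(), 0)
        with pytest.raises(ClusteringError):
            cut(hand_dendrogram(), 6)


class TestElbow:
    def test_hand_built_dendrogram_elbows_at_two(self):
        assert elbow_suggest(hand_dendrogram()) == 2
        assert elbow_suggest(hand_dendrogram(), k_max=4) == 2

    def test_identical_points_degenerate_to_one(self):
        X = np.ones((5, 3))
        _, dendro = cluster(GenometricSpace.from_matrix(X), "rows",
                            "AVERAGE", "EU")
        with pytest.warns(UserWarning, match="no elbow"):
            assert elbow_suggest(dendro) == 1

    def test_scale_invariance(self, rng):
        X = rng.uniform(0, 10, size=(12, 4))
        _, d1 = cluster(GenometricSpace.from_matrix(X), "rows", "AVERAGE",
                        "EU")
        _, d2 = cluster(GenometricSpace.from_matrix(X * 37.0), "rows",
                        "AVERAGE", "EU")
        assert elbow_suggest(d1) == elbow_suggest(d2)

    @pytest.mark.parametrize("g", [2, 4, 6])
    def test_recovers_planted_cluster_count(self, g):
        hits = 0
        for seed in range(10):
            space, _ = blob_space(g, points_per_cluster=8, n_features=4,
                                  separation=50.0, spread=1.0, seed=seed)
            _, dendro = cluster(space, "rows", "AVERAGE", "EU")
            hits += elbow_suggest(dendro) == g
        assert hits >= 9

    def test_too_few_leaves_rejected(self):
        dendro = Dendrogram(element_ids=("A", "B"), merges=((0, 1, 1.0),),
                            axis="rows", linkage="AVERAGE", metric="EU")
        with pytest.raises(ClusteringError):
            elbow_suggest(dendro)


class TestMetadataCounts:
    def test_pair_counted_in_its_pattern_only(self, rng):
        values = rng.uniform(0, 1, size=(3, 4))
        values[:, 2:] += 100  # two obvious column groups
        col_meta = (
            (("Antibody target", "CTCF"),),
            (("Antibody target", "CTCF"),),
            (("Antibody target", "POLR2A"),),
            (("Antibody target", "POLR2A"),),
        )
        space = GenometricSpace.from_matrix(values, col_meta=col_meta)
        _, dendro = cluster(space, "columns", "AVERAGE", "EU")
        table = metadata_counts(cut(dendro, 2), space)
        row = table.loc[("Antibody target", "POLR2A")]
        assert sorted(row.tolist()) == [0, 2]
        row = table.loc[("Antibody target", "CTCF")]
        assert sorted(row.tolist()) == [0, 2]

    def test_counts_conserved_across_patterns(self, rng):
        space = random_space(rng, 4, 9)
        _, dendro = cluster(space, "columns", "COMPLETE", "EU")
        patterns = cut(dendro, 3)
        table = metadata_counts(patterns, space)
        global_tally = {}
        for meta in space.col_meta:
            for pair in meta:
                global_tally[pair] = global_tally.get(pair, 0) + 1
        for pair, total in global_tally.items():
            assert table.loc[pair].sum() == total

    def test_matches_brute_force_tally(self, rng):
        space = random_space(rng, 4, 8)
        _, dendro = cluster(space, "columns", "SINGLE", "MA")
        patterns = cut(dendro, 4)
        table = metadata_counts(patterns, space)
        for (attribute, value), row in table.iterrows():
            for p in range(4):
                expected = sum(
                    1 for cid, meta in zip(space.col_ids, space.col_meta)
                    if patterns.membership[cid] == p
                    and (attribute, value) in meta)
                assert row[f"P-{p}"] == expected

    def test_row_patterns_use_region_attributes(self, rng):
        space = random_space(rng, 6, 4)
        _, dendro = cluster(space, "rows", "AVERAGE", "EU")
        table = metadata_counts(cut(dendro, 2), space)
        assert "name" in table.index.get_level_values("attribute")


class TestNewick:
    def test_two_leaf_tree_splits_height_evenly(self):
        dendro = Dendrogram(element_ids=("A", "B"), merges=((0, 1, 3.0),),
                            axis="rows", linkage="AVERAGE", metric="EU")
        assert to_newick(dendro) == "(A:1.5,B:1.5);"

    def test_output_reparses_and_roundtrips_leaf_names(self, rng):
        import dendropy

        space = random_space(rng, 7, 4)
        _, dendro = cluster(space, "rows", "AVERAGE", "EU")
        tree = dendropy.Tree.get(data=to_newick(dendro), schema="newick")
        names = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert names == set(space.row_ids)

    def test_normalized_leaf_depths_are_one(self, rng):
        import dendropy

        space = random_space(rng, 9, 5)
        _, dendro = cluster(space, "rows", "COMPLETE", "EU")
        tree = dendropy.Tree.get(data=to_newick(dendro, normalize=True),
                                 schema="newick")
        for leaf in tree.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(1.0, abs=1e-9)
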