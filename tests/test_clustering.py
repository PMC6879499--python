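"""Correlation clustering, multiscale-bootstrap AU support and tree tools."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from netscreen.clustering import (
    ClusterTree,
    compare_trees,
    correlation_dissimilarity,
    fit_au,
    hierarchical_cluster,
    multiscale_bootstrap,
    support_table,
    to_newick,
)


def feature_frame(values, items=None) -> pd.DataFrame:
    arr = np.asarray(values, dtype=float)
    items = items or [f"i{k}" for k in range(arr.shape[0])]
    return pd.DataFrame(arr, index=items)


def two_block_features(seed: int, n_features: int = 50) -> pd.DataFrame:
    """Two well-separated blocks of 6 items with mirrored feature patterns.

    Items in block a follow the pattern (+5, -5, +5, ...) over features,
    block b the negation, both with unit Gaussian noise, so within-block
    profiles are strongly positively correlated and between-block profiles
    strongly anticorrelated.
    """
    rng = np.random.default_rng(seed)
    pattern = 5.0 * np.where(np.arange(n_features) % 2 == 0, 1.0, -1.0)
    means = np.vstack([np.tile(pattern, (6, 1)), np.tile(-pattern, (6, 1))])
    x = means + rng.normal(0.0, 1.0, size=(12, n_features))
    return pd.DataFrame(x, index=[f"a{k}" for k in range(6)] + [f"b{k}" for k in range(6)])


class TestCorrelationDissimilarity:
    def test_identical_profiles_distance_zero(self):
        d = correlation_dissimilarity(feature_frame([[1, 2, 3], [1, 2, 3]]))
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_distance_two(self):
        d = correlation_dissimilarity(feature_frame([[1, 2, 3], [3, 2, 1]]))
        assert d.values[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_bounds_symmetry_diagonal(self):
        rng = np.random.default_rng(3)
        d = correlation_dissimilarity(feature_frame(rng.normal(size=(8, 20)))).values
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0.0)
        assert np.all((d >= 0.0) & (d <= 2.0))

    def test_zero_variance_item_named(self):
        with pytest.raises(ValueError, match="flat"):
            correlation_dissimilarity(
                feature_frame([[1, 1, 1], [1, 2, 3]], items=["flat", "ok"]))

    def test_needs_three_features(self):
        with pytest.raises(ValueError, match="3 features"):
            correlation_dissimilarity(feature_frame([[1, 2], [2, 1]]))


class TestHierarchicalCluster:
    def test_two_items_single_merge_at_distance(self):
        d = pd.DataFrame([[0.0, 0.6], [0.6, 0.0]], index=["A", "B"], columns=["A", "B"])
        t = hierarchical_cluster(d)
        assert t.linkage_matrix.shape == (1, 4)
        assert t.linkage_matrix[0, 2] == pytest.approx(0.6)

    def test_three_item_merge_order(self):
        # brute force over the 3 possible first merges: {A,B} at 0.1 wins,
        # then joins C at average distance 0.9
        d = pd.DataFrame(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]],
            index=list("ABC"), columns=list("ABC"))
        t = hierarchical_cluster(d, linkage="average")
        assert t.cluster_leafsets() == [frozenset("AB"), frozenset("ABC")]
        assert t.linkage_matrix[:, 2].tolist() == pytest.approx([0.1, 0.9])

    def test_deterministic_for_identical_input(self):
        rng = np.random.default_rng(5)
        x = feature_frame(rng.normal(size=(7, 15)))
        t1 = hierarchical_cluster(correlation_dissimilarity(x))
        t2 = hierarchical_cluster(correlation_dissimilarity(x))
        assert np.array_equal(t1.linkage_matrix, t2.linkage_matrix)

    def test_average_linkage_heights_monotone(self):
        rng = np.random.default_rng(11)
        for seed in range(5):
            x = feature_frame(np.random.default_rng(seed).normal(size=(10, 25)))
            t = hierarchical_cluster(correlation_dissimilarity(x))
            heights = t.linkage_matrix[:, 2]
            assert np.all(np.diff(heights) >= -1e-12)

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0.0, 0.5], [0.4, 0.0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_cluster(d)


class TestFitAu:
    def test_flat_half_bp_gives_au_half(self):
        """BP = 0.5 at every scale fits v = c = 0, hence AU = 0.5 exactly."""
        scales = np.round(np.arange(0.5, 1.41, 0.1), 1)
        fit = fit_au(scales, [0.5] * len(scales), n_boot=1000)
        assert fit["v"] == pytest.approx(0.0, abs=1e-12)
        assert fit["c"] == pytest.approx(0.0, abs=1e-12)
        assert fit["au"] == pytest.approx(0.5, abs=1e-12)

    def test_all_boundary_bp_degenerate(self):
        scales = [0.5, 1.0, 1.4]
        assert fit_au(scales, [1.0, 1.0, 1.0], 100)["au"] == 1.0
        assert fit_au(scales, [0.0, 0.0, 0.0], 100)["au"] == 0.0
        assert fit_au(scales, [1.0, 1.0, 1.0], 100)["degenerate"]

    def test_recovers_planted_probit_line(self):
        # construct BP_r from known (v, c) and check the fit inverts it
        v_true, c_true = -0.4, 0.25
        scales = np.round(np.arange(0.5, 1.41, 0.1), 1)
        sqrt_r = np.sqrt(scales)
        bp = 1 - norm.cdf(v_true * sqrt_r + c_true / sqrt_r)
        fit = fit_au(scales, bp, n_boot=10_000)
        assert fit["v"] == pytest.approx(v_true, abs=1e-6)
        assert fit["c"] == pytest.approx(c_true, abs=1e-6)
        assert fit["au"] == pytest.approx(1 - norm.cdf(v_true - c_true), abs=1e-6)

    def test_au_exceeds_raw_bp_for_supported_cluster(self):
        # a cluster whose BP rises toward 1 with the resampling scale is
        # strongly supported: AU must correct the scale-1 BP upward
        scales = np.round(np.arange(0.5, 1.41, 0.1), 1)
        bp = [0.915, 0.966, 0.972, 0.988, 0.993, 0.994, 0.998, 0.998, 0.999, 0.999]
        fit = fit_au(scales, bp, n_boot=1000)
        assert fit["au"] > 0.99
        assert fit["au"] >= fit["bp"]


class TestMultiscaleBootstrap:
    def test_seed_determinism(self):
        x = two_block_features(seed=0, n_features=20)
        _, s1 = multiscale_bootstrap(x, n_boot_per_scale=50, seed=123)
        _, s2 = multiscale_bootstrap(x, n_boot_per_scale=50, seed=123)
        pd.testing.assert_frame_equal(s1.table, s2.table)
        _, s3 = multiscale_bootstrap(x, n_boot_per_scale=50, seed=124)
        assert not s1.table.equals(s3.table)

    def test_support_bounded_and_root_is_one(self):
        x = feature_frame(np.random.default_rng(2).normal(size=(8, 30)))
        tree, support = multiscale_bootstrap(x, n_boot_per_scale=50, seed=1)
        assert ((support.table["au"] >= 0) & (support.table["au"] <= 1)).all()
        assert ((support.table["bp"] >= 0) & (support.table["bp"] <= 1)).all()
        assert support.table["au"].iloc[-1] == 1.0  # root cluster
        assert support.clusters[-1] == frozenset(tree.labels)

    def test_single_scale_reduces_to_classical_bootstrap(self):
        """With scales=(1.0,) the smoothed BP equals the raw bootstrap
        probability (within 2 binomial standard errors trivially: exactly)."""
        x = two_block_features(seed=4)
        _, support = multiscale_bootstrap(
            x, scales=(1.0,), n_boot_per_scale=200, seed=9)
        bp_raw = support.counts[1.0][0] / 200
        assert np.allclose(support.table["bp"].to_numpy(), bp_raw)
        assert np.allclose(support.table["au"].to_numpy(), bp_raw)

    def test_two_block_structure_gets_high_au(self):
        """Well-separated blocks must earn AU > 0.95 across seeds."""
        for seed in range(5):
            x = two_block_features(seed=seed)
            _, support = multiscale_bootstrap(x, n_boot_per_scale=100, seed=seed)
            blocks = [frozenset(f"a{k}" for k in range(6)),
                      frozenset(f"b{k}" for k in range(6))]
            for block in blocks:
                idx = support.clusters.index(block)
                assert support.table["au"].iloc[idx] > 0.95

    def test_tiny_scale_rejected(self):
        x = feature_frame(np.random.default_rng(0).normal(size=(5, 10)))
        with pytest.raises(ValueError, match="fewer than 3"):
            multiscale_bootstrap(x, scales=(0.1,), n_boot_per_scale=10, seed=0)


class TestCompareTrees:
    def test_identical_trees_agree_perfectly_at_every_k(self):
        x = feature_frame(np.random.default_rng(8).normal(size=(8, 20)))
        t = hierarchical_cluster(correlation_dissimilarity(x))
        for k in range(2, 8):
            rec = compare_trees(t, t, k)
            assert rec.adjusted_rand == 1.0
            assert rec.fowlkes_mallows == pytest.approx(1.0)
            assert rec.cophenetic_correlation == pytest.approx(1.0)

    def test_crossed_partitions_have_nonpositive_ari(self):
        # trees cutting {AB|CD} vs {AC|BD}: worse than chance agreement
        da = pd.DataFrame(
            [[0, .1, .9, .9], [.1, 0, .9, .9], [.9, .9, 0, .1], [.9, .9, .1, 0]],
            index=list("ABCD"), columns=list("ABCD"))
        db = da.reindex(index=list("ACBD"), columns=list("ACBD"))
        db.index = db.columns = list("ABCD")  # relabel -> partition {AC|BD}
        ta, tb = hierarchical_cluster(da), hierarchical_cluster(db)
        assert compare_trees(ta, tb, 2).adjusted_rand <= 0.0

    def test_random_trees_near_zero_ari_on_average(self):
        aris = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            xa = feature_frame(rng.normal(size=(12, 20)))
            xb = feature_frame(rng.normal(size=(12, 20)), items=list(xa.index))
            ta = hierarchical_cluster(correlation_dissimilarity(xa))
            tb = hierarchical_cluster(correlation_dissimilarity(xb))
            aris.append(compare_trees(ta, tb, 3).adjusted_rand)
        assert abs(np.mean(aris)) < 0.1

    def test_leaf_set_mismatch_rejected(self):
        da = pd.DataFrame(np.zeros((2, 2)), index=["A", "B"], columns=["A", "B"])
        db = pd.DataFrame(np.zeros((2, 2)), index=["A", "C"], columns=["A", "C"])
        with pytest.raises(ValueError, match="leaf"):
            compare_trees(hierarchical_cluster(da), hierarchical_cluster(db), 2)


class TestNewick:
    def test_two_leaf_ultrametric_halving(self):
        d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["A", "B"], columns=["A", "B"])
        t = hierarchical_cluster(d)
        assert to_newick(t) == "(A:0.2,B:0.2);"

    def test_roundtrip_topology_via_dendropy(self):
        import dendropy

        x = two_block_features(seed=6, n_features=15)
        tree, support = multiscale_bootstrap(x, n_boot_per_scale=20, seed=3)
        nwk = to_newick(tree, support)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(tree.labels)
        # clades of the parsed tree = clusters of the merge tree
        parsed_clades = {
            frozenset(leaf.taxon.label for leaf in node.leaf_iter())
            for node in parsed.preorder_internal_node_iter()
        }
        assert parsed_clades == set(tree.cluster_leafsets())

    def test_internal_labels_carry_au(self):
        x = two_block_features(seed=7, n_features=15)
        tree, support = multiscale_bootstrap(x, n_boot_per_scale=20, seed=5)
        nwk = to_newick(tree, support)
        import dendropy

        parsed = dendropy.Tree.get(data=nwk, schema="newick",
                                   suppress_internal_node_taxa=True)
        labels = [float(n.label) for n in parsed.preorder_internal_node_iter()
                  if n.label is not None]
        assert labels and all(0.0 <= v <= 1.0 for v in labels)

    def test_support_table_lists_all_clusters(self):
        x = two_block_features(seed=8, n_features=15)
        tree, support = multiscale_bootstrap(x, n_boot_per_scale=20, seed=2)
        table = support_table(tree, support)
        assert len(table) == tree.n_leaves - 1
        assert set(table.columns) >= {"cluster", "members", "size", "au", "bp"}
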