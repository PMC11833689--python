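"""ChAs statistic, distance-matched null, z-scores and ΔChAs."""

import numpy as np
import pytest

from chromage.assortativity import (
    DegenerateFeatureError,
    DistanceBinning,
    chas,
    chas_categorical,
    chas_zscore,
    chas_zscore_multi,
    delta_chas,
    permute_feature,
    randomize_distmatch,
)
from chromage.chromatin_network import NodeFeature, map_feature
from chromage.synthetic_data import SyntheticConfig, make_genome, make_network

from conftest import toy_network


def bruteforce_chas(net, values: dict[str, float]) -> float:
    """Pearson over the explicitly duplicated oriented edge list."""
    xs, ys = [], []
    for a, b in zip(net.edge_a, net.edge_b):
        va, vb = values.get(net.node_ids[a]), values.get(net.node_ids[b])
        if va is None or vb is None:
            continue
        xs += [va, vb]
        ys += [vb, va]
    return float(np.corrcoef(xs, ys)[0, 1])


def _feature(net, mapping, kind="binary"):
    return NodeFeature("f", kind, {net.node_ids[i]: v for i, v in mapping.items()})


class TestChas:
    def test_perfectly_assortative_pairs(self):
        net = toy_network([(0, 1), (2, 3)])
        f = _feature(net, {0: 1.0, 1: 1.0, 2: 0.0, 3: 0.0})
        assert chas(net, f) == pytest.approx(1.0)

    def test_path_with_mixed_labels(self):
        # oriented pairs (1,1),(1,1),(1,0),(0,1) -> Pearson -1/3
        net = toy_network([(0, 1), (1, 2)])
        f = _feature(net, {0: 1.0, 1: 1.0, 2: 0.0})
        assert chas(net, f) == pytest.approx(-1 / 3)

    def test_constant_feature_is_degenerate(self):
        net = toy_network([(0, 1), (1, 2)])
        with pytest.raises(DegenerateFeatureError):
            chas(net, _feature(net, {0: 1.0, 1: 1.0, 2: 1.0}))

    def test_undefined_endpoints_excluded(self):
        net = toy_network([(0, 1), (1, 2), (2, 3)])
        f = _feature(net, {0: 1.0, 1: 1.0, 2: 0.0})  # node 3 undefined
        assert chas(net, f) == pytest.approx(-1 / 3)

    def test_matches_bruteforce_on_random_graphs(self):
        from conftest import random_feature_network

        for seed in range(25):
            net, values = random_feature_network(seed)
            f = NodeFeature("f", "continuous", values)
            assert chas(net, f) == pytest.approx(bruteforce_chas(net, values), abs=1e-12)

    def test_bounded_in_unit_interval(self):
        from conftest import random_feature_network

        for seed in range(10):
            net, values = random_feature_network(seed, n_nodes=20, n_edges=60)
            assert -1.0 <= chas(net, NodeFeature("f", "continuous", values)) <= 1.0

    def test_node_relabeling_invariance(self):
        """Renaming node ids must not change the statistic."""
        net = toy_network([(0, 1), (1, 2), (0, 3), (2, 3)])
        values = {0: 0.9, 1: 0.1, 2: 0.7, 3: 0.4}
        base = chas(net, _feature(net, values))
        perm = [2, 0, 3, 1]
        relabeled = toy_network(
            [(perm[0], perm[1]), (perm[1], perm[2]), (perm[0], perm[3]), (perm[2], perm[3])]
        )
        f2 = _feature(relabeled, {perm[i]: v for i, v in values.items()})
        assert chas(relabeled, f2) == pytest.approx(base, abs=1e-12)


class TestChasCategorical:
    def test_planted_partition_is_exactly_one(self):
        net = toy_network([(0, 1), (2, 3), (4, 5)])
        assignment = {net.node_ids[i]: {c} for i, c in enumerate("AABBCC")}
        result = chas_categorical(net, assignment)
        assert all(v == pytest.approx(1.0, abs=1e-12) for v in result.values())

    def test_multilabel_node_contributes_to_both(self):
        net = toy_network([(0, 1), (1, 2)])
        assignment = {
            net.node_ids[0]: {"A"},
            net.node_ids[1]: {"A", "B"},
            net.node_ids[2]: {"B"},
        }
        result = chas_categorical(net, assignment)
        # indicator A: (1,1),(1,0); indicator B mirrors it
        assert result["A"] == pytest.approx(result["B"])

    def test_degenerate_category_is_nan_with_warning(self):
        net = toy_network([(0, 1)])
        assignment = {net.node_ids[0]: {"A"}, net.node_ids[1]: {"A"}}
        with pytest.warns(UserWarning):
            result = chas_categorical(net, assignment)
        assert np.isnan(result["A"])


@pytest.fixture(scope="module")
def medium_net():
    cfg = SyntheticConfig(n_genes=150, n_edges=400, p_within=0.0, seed=21)
    genes, ages = make_genome(cfg)
    return make_network(genes, ages, cfg), ages


class TestRandomizeDistmatch:
    def test_preserves_nodes_edges_and_distance_histogram(self, medium_net):
        net, _ = medium_net
        binning = DistanceBinning()
        cis = net.is_cis()
        before = np.bincount(binning.bin_of(net.edge_distance[cis]), minlength=200)
        for seed in range(5):
            r = randomize_distmatch(net, seed=seed)
            assert r.node_ids == net.node_ids
            assert r.n_edges == net.n_edges
            rcis = r.is_cis()
            after = np.bincount(binning.bin_of(r.edge_distance[rcis]), minlength=200)
            assert np.array_equal(before, after)
            assert rcis.sum() == cis.sum()

    def test_no_self_loops_or_duplicates(self, medium_net):
        net, _ = medium_net
        r = randomize_distmatch(net, seed=7)
        assert np.all(r.edge_a != r.edge_b)
        assert len(r.edge_keys()) == r.n_edges

    def test_requires_cis_edges(self):
        net = toy_network([(0, 1)], chroms=["chr1", "chr2"])
        with pytest.raises(ValueError):
            randomize_distmatch(net, seed=0)

    def test_seed_reproducibility(self, medium_net):
        net, _ = medium_net
        r1 = randomize_distmatch(net, seed=13)
        r2 = randomize_distmatch(net, seed=13)
        assert np.array_equal(r1.edge_a, r2.edge_a) and np.array_equal(r1.edge_b, r2.edge_b)

    def test_rejection_fallback_path_matches_invariants(self, medium_net, monkeypatch):
        """Force the large-network rejection sampler and check the same invariants."""
        import chromage.assortativity as asrt

        net, _ = medium_net
        net2 = net.with_edges(np.c_[net.edge_a, net.edge_b], net.edge_distance)
        monkeypatch.setattr(asrt, "_POOL_PAIR_LIMIT", 0)
        r = randomize_distmatch(net2, seed=3)
        binning = DistanceBinning()
        before = np.bincount(binning.bin_of(net.edge_distance[net.is_cis()]), minlength=200)
        after = np.bincount(binning.bin_of(r.edge_distance[r.is_cis()]), minlength=200)
        assert np.array_equal(before, after)
        assert len(r.edge_keys()) == r.n_edges


class TestChasZscore:
    def test_planted_network_is_significant(self):
        cfg = SyntheticConfig(n_genes=120, n_edges=350, p_within=1.0, seed=5)
        genes, ages = make_genome(cfg)
        net = make_network(genes, ages, cfg)
        uc = {g.gene_id: float(ages.category(g.gene_id) == "UC") for g in genes}
        f = map_feature(net, uc, "binary")
        result = chas_zscore(net, f, n_rand=40, seed=2)
        assert result.z > 2

    def test_zero_randomizations_rejected(self, medium_net):
        net, ages = medium_net
        f = map_feature(net, {g: 1.0 for g in list(net.genes)[:50]} | {g: 0.0 for g in list(net.genes)[50:]}, "binary")
        with pytest.raises(ValueError):
            chas_zscore(net, f, n_rand=0, seed=1)

    def test_bit_identical_for_fixed_seed(self, medium_net):
        net, ages = medium_net
        gene_ids = sorted(net.genes)
        f = map_feature(net, {g: float(i % 2) for i, g in enumerate(gene_ids)}, "binary")
        r1 = chas_zscore(net, f, n_rand=20, seed=77)
        r2 = chas_zscore(net, f, n_rand=20, seed=77)
        assert r1.z == r2.z and r1.null_mean == r2.null_mean and r1.null_sd == r2.null_sd

    def test_z_definition_holds(self, medium_net):
        net, _ = medium_net
        gene_ids = sorted(net.genes)
        f = map_feature(net, {g: float(i % 3 == 0) for i, g in enumerate(gene_ids)}, "binary")
        r = chas_zscore(net, f, n_rand=25, seed=3)
        assert r.z == pytest.approx((r.observed - r.null_mean) / r.null_sd)
        assert len(r.null_samples) == 25

    def test_null_randomization_centers_on_null_mean(self, medium_net):
        """ChAs of independently rewired networks matches the stored null."""
        net, _ = medium_net
        gene_ids = sorted(net.genes)
        f = map_feature(net, {g: float(i % 2) for i, g in enumerate(gene_ids)}, "binary")
        r = chas_zscore(net, f, n_rand=40, seed=5)
        other = [chas(randomize_distmatch(net, seed=1000 + i), f) for i in range(40)]
        se = np.std(other, ddof=1) / np.sqrt(len(other))
        assert abs(np.mean(other) - r.null_mean) < 3 * (se + r.null_sd / np.sqrt(r.n_rand))

    def test_permutation_null_available(self, medium_net):
        net, _ = medium_net
        gene_ids = sorted(net.genes)
        f = map_feature(net, {g: float(i % 2) for i, g in enumerate(gene_ids)}, "binary")
        r = chas_zscore(net, f, n_rand=30, seed=9, null="permute")
        assert np.isfinite(r.z)


class TestDeltaChas:
    def test_feature_driven_clustering_gives_positive_delta(self):
        rng = np.random.default_rng(4)
        n = 80
        group = {f"g{i}" for i in range(40)}
        feature = {f"g{i}" for i in range(20)}  # half of the group
        edges = set()
        while len(edges) < 60:  # clustering only among group ∩ feature
            a, b = rng.integers(0, 20, 2)
            if a != b:
                edges.add((min(a, b), max(a, b)))
        while len(edges) < 160:  # background anywhere
            a, b = rng.integers(0, n, 2)
            if a != b:
                edges.add((min(a, b), max(a, b)))
        net = toy_network(sorted(edges), n_nodes=n, genes=[(f"g{i}",) for i in range(n)])
        r = delta_chas(net, group, feature, n_rand=30, seed=6)
        assert r.delta > 0
        assert r.delta == pytest.approx(r.z_with - r.z_without)

    def test_feature_covering_whole_group_is_an_error(self):
        net = toy_network([(0, 1), (1, 2)], genes=[("a",), ("b",), ("c",)])
        with pytest.raises(ValueError, match="without"):
            delta_chas(net, {"a", "b"}, {"a", "b", "c"}, n_rand=5, seed=0)

    def test_empty_positive_subgroup_is_an_error(self):
        net = toy_network([(0, 1), (1, 2)], genes=[("a",), ("b",), ("c",)])
        with pytest.raises(ValueError, match="with"):
            delta_chas(net, {"a", "b"}, {"zzz"}, n_rand=5, seed=0)

    def test_shared_nulls_for_both_subgroups(self):
        """Common random numbers: both z-scores come from the same rewirings."""
        rng = np.random.default_rng(8)
        edges = set()
        while len(edges) < 120:
            a, b = rng.integers(0, 60, 2)
            if a != b:
                edges.add((min(a, b), max(a, b)))
        net = toy_network(sorted(edges), n_nodes=60, genes=[(f"g{i}",) for i in range(60)])
        group = {f"g{i}" for i in range(30)}
        feature = {f"g{i}" for i in range(0, 30, 2)}
        r1 = delta_chas(net, group, feature, n_rand=20, seed=42)
        r2 = delta_chas(net, group, feature, n_rand=20, seed=42)
        assert r1.delta == r2.delta


def test_permute_feature_preserves_multiset():
    f = NodeFeature("f", "binary", {f"n{i}": float(i % 2) for i in range(10)})
    p = permute_feature(f, np.random.default_rng(0))
    assert sorted(p.values.values()) == sorted(f.values.values())
    assert set(p.values) == set(f.values)


def test_shared_null_stream_consistency(medium_net):
    """chas_zscore_multi equals per-feature calls with the same seed."""
    net, _ = medium_net
    gene_ids = sorted(net.genes)
    f1 = map_feature(net, {g: float(i % 2) for i, g in enumerate(gene_ids)}, "binary", name="a")
    multi = chas_zscore_multi(net, {"a": f1}, n_rand=15, seed=4)
    single = chas_zscore(net, f1, n_rand=15, seed=4)
    assert multi["a"].z == single.z
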