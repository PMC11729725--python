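"""Pangenome partition, growth curves, path profiles and sample similarity."""

import itertools

import numpy as np
import pytest

from vgstats import (
    SimConfig,
    classify_nodes,
    growth_exact,
    growth_permutation,
    node2int,
    parse_gfa_text,
    path_pangenome_profile,
    sample_similarity_matrix,
    simulate_graph,
)
from vgstats.metrics_core import node_lengths, sample_node_incidence


def brute_force_growth(graph):
    """Average pan/core content over explicitly enumerated sample subsets."""
    samples, inc = sample_node_incidence(graph)
    lengths = node_lengths(graph).astype(float)
    s = len(samples)
    pan_n, pan_bp, core_n, core_bp = (np.zeros(s) for _ in range(4))
    for k in range(1, s + 1):
        subsets = list(itertools.combinations(range(s), k))
        for subset in subsets:
            union = inc[list(subset)].any(axis=0)
            inter = inc[list(subset)].all(axis=0)
            pan_n[k - 1] += union.sum()
            pan_bp[k - 1] += lengths[union].sum()
            core_n[k - 1] += inter.sum()
            core_bp[k - 1] += lengths[inter].sum()
        pan_n[k - 1] /= len(subsets)
        pan_bp[k - 1] /= len(subsets)
        core_n[k - 1] /= len(subsets)
        core_bp[k - 1] /= len(subsets)
    return pan_n, pan_bp, core_n, core_bp


class TestClassify:
    def test_toy1_core_and_private(self, toy1):
        cls = classify_nodes(toy1)
        by_id = dict(zip(cls.node_ids, cls.classes))
        assert by_id == {"1": "core", "2": "private", "3": "private", "4": "core"}
        assert cls.occupancy.tolist() == [2, 1, 1, 2]

    def test_degenerate_single_sample_reports_core(self, fixtures):
        cls = classify_nodes(parse_gfa_text(fixtures["single_sample"]))
        assert set(cls.classes) == {"core"}

    def test_same_sample_paths_keep_occupancy_one(self, fixtures):
        g = parse_gfa_text(fixtures["TOY1"] + "P\tx#2#c\t1+,2+,4+\t*\n")
        cls = classify_nodes(g)
        assert dict(zip(cls.node_ids, cls.occupancy))["2"] == 1
        assert dict(zip(cls.node_ids, cls.classes))["2"] == "private"

    def test_unvisited_node_is_absent(self, fixtures):
        cls = classify_nodes(parse_gfa_text(fixtures["isolated"]))
        assert dict(zip(cls.node_ids, cls.classes))["9"] == "absent"


class TestGrowthExact:
    def test_toy1_curve(self, toy1):
        curve = growth_exact(toy1)
        assert curve.pan_nodes.tolist() == [3.0, 4.0]
        assert curve.core_nodes.tolist() == [3.0, 2.0]
        assert curve.pan_bp.tolist() == [7.0, 8.0]
        assert curve.core_bp.tolist() == [7.0, 6.0]

    def test_pan_at_full_k_counts_visited_nodes(self, fixtures):
        g = parse_gfa_text(fixtures["isolated"])
        curve = growth_exact(g)
        cls = classify_nodes(g)
        assert curve.pan_nodes[-1] == (cls.occupancy >= 1).sum()

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_subset_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        config = SimConfig(
            n_samples=int(rng.integers(2, 7)),
            n_bubbles=int(rng.integers(5, 25)),
            allele_freq=float(rng.uniform(0.2, 0.8)),
            seed=seed,
        )
        g = parse_gfa_text(simulate_graph(config)[0])
        curve = growth_exact(g)
        pan_n, pan_bp, core_n, core_bp = brute_force_growth(g)
        np.testing.assert_allclose(curve.pan_nodes, pan_n, atol=1e-9)
        np.testing.assert_allclose(curve.pan_bp, pan_bp, atol=1e-9)
        np.testing.assert_allclose(curve.core_nodes, core_n, atol=1e-9)
        np.testing.assert_allclose(curve.core_bp, core_bp, atol=1e-9)

    def test_monotone_in_k(self):
        g = parse_gfa_text(simulate_graph(SimConfig(n_samples=5, n_bubbles=30, seed=3))[0])
        curve = growth_exact(g)
        assert (np.diff(curve.pan_nodes) >= -1e-12).all()
        assert (np.diff(curve.core_nodes) <= 1e-12).all()


class TestGrowthPermutation:
    def test_full_k_union_is_order_independent(self, toy1):
        curve = growth_permutation(toy1, replicates=10, seed=7)
        assert curve.pan_nodes[-1] == 4.0

    def test_converges_to_exact(self, toy1):
        curve = growth_permutation(toy1, replicates=2000, seed=1)
        assert abs(curve.pan_nodes[0] - 3.0) < 0.1

    def test_seed_determinism(self, toy1):
        a = growth_permutation(toy1, replicates=5, seed=42)
        b = growth_permutation(toy1, replicates=5, seed=42)
        np.testing.assert_array_equal(a.pan_bp, b.pan_bp)
        np.testing.assert_array_equal(a.core_bp, b.core_bp)


class TestPathProfile:
    def test_toy1_private_vs_shared_bp(self, toy1):
        table = path_pangenome_profile(toy1)
        assert table.loc["x"].tolist() == [1, 6]
        assert table.loc["y"].tolist() == [1, 6]

    def test_row_sums_equal_path_lengths(self, toy1):
        table = path_pangenome_profile(toy1)
        for path in toy1.paths:
            assert table.loc[path.name].sum() == toy1.path_length_bp(path)

    def test_single_sample_concentrates_at_one(self, fixtures):
        table = path_pangenome_profile(parse_gfa_text(fixtures["single_sample"]))
        assert table.shape[1] == 1
        assert (table.iloc[:, 0] > 0).all()


class TestSimilarity:
    def test_toy1_weighted_jaccard(self, toy1):
        sim = sample_similarity_matrix(toy1)
        assert sim.loc["x", "y"] == pytest.approx(0.75)
        assert sim.loc["x", "x"] == 1.0
        assert np.allclose(sim.values, sim.values.T)

    def test_identical_paths_different_samples(self, fixtures):
        g = parse_gfa_text(fixtures["TOY1"].replace("P\ty\t1+,3+,4+", "P\ty\t1+,2+,4+"))
        assert sample_similarity_matrix(g).loc["x", "y"] == 1.0

    def test_disjoint_components_similarity_zero(self):
        g = parse_gfa_text(
            "H\tVN:Z:1.0\nS\t1\tAAAA\nS\t2\tCC\nP\ta\t1+\t*\nP\tb\t2+\t*\n"
        )
        assert sample_similarity_matrix(g).loc["a", "b"] == 0.0

    def test_invariant_under_node2int(self, fixtures):
        text = fixtures["TOY1"]
        for old, new in [("1", "nA"), ("2", "nB"), ("3", "nC"), ("4", "nD")]:
            text = text.replace(f"\t{old}\t", f"\t{new}\t").replace(f"{old}+", f"{new}+")
        g, _ = node2int(parse_gfa_text(text))
        np.testing.assert_allclose(
            sample_similarity_matrix(g).values,
            sample_similarity_matrix(parse_gfa_text(fixtures["TOY1"])).values,
        )
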