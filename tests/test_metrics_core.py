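"""Primitive node/edge/step profiles and their conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vgstats import SimConfig, parse_gfa_text, simulate_graph
from vgstats.gfa_io import GFAValidationError
from vgstats.metrics_core import (
    connected_components,
    degree_profile,
    depth_profile,
    edge_depth_profile,
    jump_profile,
    nX,
)


class TestDegree:
    def test_toy1_attachments(self, toy1):
        deg = degree_profile(toy1)
        assert deg.degree.tolist() == [2, 2, 2, 2]
        assert deg.out_degree[0] == 2  # node 1 fans out to 2 and 3
        assert deg.in_degree[3] == 2  # node 4 collects from 2 and 3

    def test_isolated_node_degree_zero(self, fixtures):
        g = parse_gfa_text(fixtures["isolated"])
        deg = degree_profile(g)
        assert deg.degree[list(g.segments).index("9")] == 0

    def test_self_loop_counts_both_ends(self, fixtures):
        g = parse_gfa_text(fixtures["self_loop"])
        assert degree_profile(g).degree.tolist() == [2]


class TestDepth:
    def test_toy1_depth_and_similarity(self, toy1):
        dep = depth_profile(toy1)
        assert dep.depth.tolist() == [2, 1, 1, 2]
        assert dep.similarity.tolist() == [2, 1, 1, 2]
        assert not dep.both_orientations.any()

    def test_loop_multiplicity_vs_distinct_samples(self, fixtures):
        g = parse_gfa_text(fixtures["self_loop"])
        dep = depth_profile(g)
        assert dep.depth[0] == 2
        assert dep.similarity[0] == 1

    def test_unvisited_node_has_zero_depth(self, fixtures):
        g = parse_gfa_text(fixtures["isolated"])
        dep = depth_profile(g)
        assert dep.depth[list(g.segments).index("9")] == 0

    def test_inverted_traversal_sets_flag(self, fixtures):
        g = parse_gfa_text(
            fixtures["TOY1"].replace("P\ty\t1+,3+,4+", "P\ty\t1-,3+,4+")
        )
        dep = depth_profile(g)
        assert dep.both_orientations[0]


class TestEdgeDepth:
    def test_toy1_each_link_once(self, toy1):
        prof = edge_depth_profile(toy1)
        assert prof.edge_depth.tolist() == [1, 1, 1, 1]

    def test_additivity_with_extra_path(self, fixtures):
        g = parse_gfa_text(fixtures["TOY1"] + "P\tx#2#c\t1+,2+,4+\t*\n")
        prof = edge_depth_profile(g)
        by_key = dict(zip((l.key for l in prof.links), prof.edge_depth))
        assert by_key[("1", "+", "2", "+")] == 2

    def test_single_step_path_contributes_nothing(self, fixtures):
        g = parse_gfa_text(fixtures["single_node"])
        assert edge_depth_profile(g).edge_depth.size == 0

    def test_unbacked_adjacency_raises(self, fixtures):
        g = parse_gfa_text(
            fixtures["TOY1"].replace("P\tx\t1+,2+,4+", "P\tx\t1+,4+")
        )
        with pytest.raises(GFAValidationError, match="path x, step 0"):
            edge_depth_profile(g)


class TestJump:
    def test_toy1_jumps(self, toy1):
        jp = jump_profile(toy1, threshold=1000)
        assert jp.jumps["x"].tolist() == [1, 2]
        assert jp.jumps["y"].tolist() == [2, 1]
        assert int(jp.all_jumps.sum()) == 6
        assert jp.above_threshold == 0
        assert jp.sortedness == 1.0

    def test_large_jump_above_threshold(self):
        g = parse_gfa_text(
            "H\tVN:Z:1.0\nS\t1\tA\nS\t1000000\tC\n"
            "L\t1\t+\t1000000\t+\t0M\nP\tx\t1+,1000000+\t*\n"
        )
        jp = jump_profile(g, threshold=1000)
        assert jp.jumps["x"].tolist() == [999999]
        assert jp.above_threshold == 1

    def test_single_step_path_empty_jump_list(self, fixtures):
        jp = jump_profile(parse_gfa_text(fixtures["single_node"]))
        assert jp.jumps["x"].size == 0

    def test_non_numeric_ids_rejected(self):
        g = parse_gfa_text("H\tVN:Z:1.0\nS\ta\tA\nP\tx\ta+\t*\n")
        with pytest.raises(GFAValidationError, match="node2int"):
            jump_profile(g)

    def test_invariant_under_path_reversal(self, fixtures):
        fwd = parse_gfa_text(fixtures["TOY1"])
        rev = parse_gfa_text(
            fixtures["TOY1"]
            .replace("P\tx\t1+,2+,4+", "P\tx\t4-,2-,1-")
            .replace("P\ty\t1+,3+,4+", "P\ty\t4-,3-,1-")
        )
        a, b = jump_profile(fwd), jump_profile(rev)
        for name in ("x", "y"):
            assert a.jumps[name].tolist() == b.jumps[name][::-1].tolist()


class TestComponents:
    def test_toy1_single_component(self, toy1):
        _, count, largest = connected_components(toy1)
        assert (count, largest) == (1, 4)

    def test_isolated_node_makes_second_component(self, fixtures):
        _, count, largest = connected_components(parse_gfa_text(fixtures["isolated"]))
        assert (count, largest) == (2, 4)

    def test_empty_graph(self, fixtures):
        _, count, largest = connected_components(parse_gfa_text(fixtures["empty"]))
        assert (count, largest) == (0, 0)


class TestNX:
    @pytest.mark.parametrize(
        "lengths,x,expected",
        [([4, 2, 1, 1], 50, 4), ([4, 2, 1, 1], 90, 1), ([5], 10, 5), ([], 50, 0)],
    )
    def test_examples(self, lengths, x, expected):
        assert nX(lengths, x) == expected

    @given(st.lists(st.integers(1, 500), min_size=1, max_size=40))
    @settings(deadline=None)
    def test_against_linear_scan(self, lengths):
        x = 50
        ordered = sorted(lengths, reverse=True)
        total, cum = sum(ordered), 0
        for value in ordered:
            cum += value
            if cum >= total * x / 100:
                assert nX(lengths, x) == value
                break


class TestConservation:
    @pytest.mark.parametrize("seed", range(5))
    def test_simulated_graphs_obey_conservation_laws(self, seed):
        text, _ = simulate_graph(SimConfig(n_samples=3, n_bubbles=25, seed=seed))
        g = parse_gfa_text(text)
        total_steps = sum(p.step_count for p in g.paths)
        assert int(depth_profile(g).depth.sum()) == total_steps
        assert int(edge_depth_profile(g).edge_depth.sum()) == total_steps - len(g.paths)
        assert int(degree_profile(g).degree.sum()) == 2 * g.edge_count
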