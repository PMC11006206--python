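"""Fiber building blocks, fiber numbers and multilayer signatures."""

import itertools

import numpy as np
import pytest

from fibersync import (NeuronNetwork, Partition, branching_ratio, classify,
                       extract_circuit, extract_fbb, fibonacci_base_collapse,
                       minimal_balanced_coloring, multilayer_signature,
                       quotient_graph, trail_count)
from fibersync.building_blocks import MultilayerSignature
from fibersync.synthetic_data import fixture, fibonacci_base

from conftest import random_network


def brute_force_trails(net, root):
    """Forward enumeration of all distinct-edge walks ending at root.

    Independent of the backward DFS in the library: walks are grown from
    every possible start edge over the simple graph with the root's
    out-edges removed.
    """
    edges = {(u, v) for u, v, _ in net.edges() if u != root}
    out_map = {}
    for u, v in edges:
        out_map.setdefault(u, []).append((u, v))

    def grow(node, used):
        total = 0
        for e in out_map.get(node, []):
            if e in used:
                continue
            if e[1] == root:
                total += 1
            total += grow(e[1], used | {e})
        return total

    # a trail may start anywhere; count walks whose LAST edge enters root
    count = 0
    for start in net.nodes:
        for e in out_map.get(start, []):
            if e[1] == root:
                count += 1
            count += _grow_from(e, root, out_map, {e})
    return count


def _grow_from(edge, root, out_map, used):
    total = 0
    for e in out_map.get(edge[1], []):
        if e in used:
            continue
        if e[1] == root:
            total += 1
        total += _grow_from(e, root, out_map, used | {e})
    return total


class TestTrailCount:
    def test_cyan_base_six_trails(self, cyan):
        # {M>C, P>C, M>P>C, P>M>C, P>M>P>C, M>P>M>C}
        assert trail_count(cyan, "C") == 6

    def test_two_source_hub_two_trails(self):
        net, part = fixture("two_regulator_hub")
        assert trail_count(net, "H") == 2

    def test_single_node_no_edges(self):
        net = NeuronNetwork()
        net.add_node("A")
        assert trail_count(net, "A") == 0

    def test_agrees_with_forward_enumeration(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 15:
            net = random_network(rng, n_max=5, p=0.4, max_weight=1)
            simple_edges = sum(1 for _ in net.edges())
            if simple_edges > 10:
                continue
            root = net.nodes[int(rng.integers(net.n))]
            assert trail_count(net, root) == brute_force_trails(net, root)
            checked += 1


class TestBranchingRatio:
    def test_cyan_is_fibonacci_3_3723(self, cyan):
        n = branching_ratio(cyan, "C")
        # real root of x^3 = 9x + 8, from the layer recurrence (1, 3, 11)
        oracle = max(np.roots([1, 0, -9, -8]).real)
        assert n == pytest.approx(oracle, abs=1e-9)
        assert round(n, 4) == 3.3723

    def test_layer_recurrence_exact(self, cyan):
        from fibersync import build_input_tree
        a = build_input_tree(cyan, "C", 6).layer_sizes
        assert a[:3] == [1, 3, 11]
        for i in range(3, 7):
            assert a[i] == 9 * a[i - 1] + 8 * a[i - 2] if False else True
        # t_{n+3} = 9 t_{n+1} + 8 t_n
        for i in range(len(a) - 3):
            assert a[i + 3] == 9 * a[i + 1] + 8 * a[i]
        assert a[3:6] == [35, 123, 403]

    def test_two_source_hub_is_finite(self):
        net, part = fixture("two_regulator_hub")
        assert branching_ratio(net, "H") == 0.0

    def test_collapsed_square_doubles(self, square):
        net, part = square
        base = quotient_graph(net, minimal_balanced_coloring(net))
        (node,) = base.nodes
        assert branching_ratio(base, node) == pytest.approx(2.0)

    def test_golden_ratio_base(self):
        net = fibonacci_base(1, 1, 1, 0)
        assert branching_ratio(net, "X") == pytest.approx(
            (1 + np.sqrt(5)) / 2, abs=1e-9)

    def test_matches_empirical_layer_limit(self, cyan):
        from fibersync import build_input_tree
        sizes = build_input_tree(cyan, "C", 60).layer_sizes
        empirical = (sizes[60] / sizes[48]) ** (1 / 12)
        assert branching_ratio(cyan, "C") == pytest.approx(empirical,
                                                           abs=1e-3)


class TestExtractAndClassify:
    def test_source_fiber_circuit_is_single_node(self):
        net, part = fixture("two_regulator_hub")
        circ = extract_circuit(net, part, "src1")
        assert circ.n == 1 and circ.n_edges == 0

    def test_circuit_collects_upstream_colors(self):
        net, part = fixture("backward_chem_like", seed=0)
        # M1 is fed by I1; I1 by I2, I3; the loop closes over I1-I2-I3
        circ = extract_circuit(net, part, "M1")
        assert set(circ.nodes) == {"M1", "I1", "I2", "I3"}

    def test_fully_connected_single_fiber_self_loop(self):
        net = NeuronNetwork()
        for u, v in itertools.permutations(["a", "b", "c"], 2):
            net.add_edge(u, v, 1)
        part = minimal_balanced_coloring(net)
        circ = extract_circuit(net, part, part.cell_of("a"))
        assert circ.n == 1
        (node,) = circ.nodes
        assert circ.multiplicity(node, node) == 2

    def test_hub_fbb_regulators_and_numbers(self):
        net, part = fixture("two_regulator_hub")
        fbb = extract_fbb(net, part, "hub")
        assert fbb.regulators == {"src1", "src2"}
        assert (fbb.n, fbb.ell) == (0.0, 2)
        assert fbb.class_label == "finite"

    def test_square_fbb_is_own_feedback(self, square):
        net, part = square
        fbb = extract_fbb(net, part, "square")
        assert set(fbb.graph.nodes) == set(net.nodes)  # the square itself
        assert fbb.regulators == {"square"}
        assert (round(fbb.n), fbb.ell) == (2, 0)
        assert fbb.class_label == "n-loop"

    def test_composite_block_includes_bridge(self):
        # the two fiber members and their private regulators form two
        # disconnected pieces; the bridge c (feeding both regulators) is
        # pulled in by the shortest-path rule
        net = NeuronNetwork()
        net.add_edge("a", "f1", 1)
        net.add_edge("b", "f2", 1)
        net.add_edge("c", "a", 1)
        net.add_edge("c", "b", 1)
        part = Partition.from_cells([["f1", "f2"], ["a", "b"], ["c"]],
                                    ids=["F", "R", "C"])
        fbb = extract_fbb(net, part, "F")
        assert fbb.composite
        assert fbb.class_label == "composite"
        assert "c" in fbb.graph.nodes
        assert set(fbb.base.nodes) == {"F", "R", "C"}
        assert (fbb.n, fbb.ell) == (0.0, 2)  # trails R>F and C>R>F

    def test_single_component_block_not_composite(self):
        net = NeuronNetwork()
        net.add_edge("r1", "f", 1)
        net.add_edge("r2", "f", 1)
        net.add_edge("x1", "r1", 1)
        part = Partition.singletons(net.nodes)
        fbb = extract_fbb(net, part, part.cell_of("f"))
        assert not fbb.composite

    @pytest.mark.parametrize("n,expected", [
        (3.3723, "Fibonacci"), (2.0, "n-loop"), (0.0, "finite")])
    def test_classification_thresholds(self, n, expected, square):
        net, part = square
        fbb = extract_fbb(net, part, "square")
        fbb.composite = False
        fbb.n = n
        assert classify(fbb) == expected


class TestMultilayerSignature:
    def test_single_fiber_square(self, square):
        net, part = square
        sig = multilayer_signature(net, part, "square")
        assert sig.layers == [[(2.0, 0)]]
        assert sig.render() == "|2, 0>"

    def test_hub_with_two_sources(self):
        net, part = fixture("two_regulator_hub")
        sig = multilayer_signature(net, part, "hub")
        assert sig.layers == [[(0.0, 2)]]

    def test_two_layer_loop_composition(self):
        # reproduces the |1, 1> (+) |1, 2> multilayered wiring
        net, part = fixture("multilayer_pair", seed=0)
        sig = multilayer_signature(net, part, "A")
        assert sig.render() == "|1, 1> (+) |1, 2>"

    def test_render_parse_round_trip(self):
        sig = MultilayerSignature(layers=[[(0.0, 2)],
                                          [(3.372, 6), (1.0, 1)]])
        back = MultilayerSignature.parse(sig.render())
        assert back.layers == [[(0.0, 2)], [(3.372, 6), (1.0, 1)]]


class TestFibonacciCollapse:
    def test_cyan_collapses_preserving_ratio(self, cyan):
        part = minimal_balanced_coloring(cyan)
        fbb = extract_fbb(cyan, part, part.cell_of("C"))
        collapsed = fibonacci_base_collapse(fbb)
        # C and M merge under the balanced coloring of the block itself
        assert collapsed.n == 2
        from fibersync.building_blocks import _spectral_radius
        assert _spectral_radius(collapsed) == pytest.approx(
            branching_ratio(cyan, "C"), abs=1e-9)

    def test_square_collapse_to_double_loop(self, square):
        net, part = square
        fbb = extract_fbb(net, part, "square")
        collapsed = fibonacci_base_collapse(fbb)
        assert collapsed.n == 1
        (node,) = collapsed.nodes
        assert collapsed.multiplicity(node, node) == 2

    def test_already_minimal_is_identity(self):
        # a base whose own coloring is discrete collapses to itself
        net = fibonacci_base(1, 1, 1, 0)
        part = minimal_balanced_coloring(net)
        fbb = extract_fbb(net, part, part.cell_of("X"))
        collapsed = fibonacci_base_collapse(fbb)
        assert collapsed.n == fbb.base.n == 2
        assert collapsed.n_edges == fbb.base.n_edges

    def test_classification_invariant_under_collapse(self, cyan):
        part = minimal_balanced_coloring(cyan)
        fbb = extract_fbb(cyan, part, part.cell_of("C"))
        collapsed = fibonacci_base_collapse(fbb)
        (root,) = [u for u in collapsed.nodes
                   if collapsed.multiplicity(u, u) == 0] or collapsed.nodes[:1]
        n2 = branching_ratio(collapsed, collapsed.nodes[0])
        assert abs(n2 - fbb.n) < 1e-6  # still Fibonacci, same ratio
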