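"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pytest

from fibersync import NeuronNetwork, Partition
from fibersync.dynamics import ModelParams


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def cyan():
    from fibersync.synthetic_data import fixture
    net, _ = fixture("cyan_multigraph")
    return net


@pytest.fixture
def square():
    from fibersync.synthetic_data import fixture
    return fixture("bidirectional_square")


@pytest.fixture
def two_cycle():
    net = NeuronNetwork()
    net.add_edge("L", "R", 1)
    net.add_edge("R", "L", 1)
    return net


def random_network(rng, n_max=7, p=0.35, max_weight=2, directed=True):
    """Small random integer-weighted multigraph for property tests."""
    n = int(rng.integers(2, n_max + 1))
    names = [f"v{i}" for i in range(n)]
    net = NeuronNetwork(directed=directed)
    for u in names:
        net.add_node(u)
    for u, v in itertools.product(names, names):
        if not directed and u > v:
            continue
        if u == v and rng.random() > 0.15:
            continue
        if rng.random() < p:
            net.add_edge(u, v, int(rng.integers(1, max_weight + 1)))
    return net


def all_partitions(items):
    """Every set partition of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def brute_force_automorphisms(net):
    """All adjacency-preserving permutations by exhaustive enumeration."""
    nodes = net.nodes
    autos = []
    for perm in itertools.permutations(nodes):
        sigma = dict(zip(nodes, perm))
        if all(net.multiplicity(sigma[u], sigma[v]) == w
               for u, v, w in net.edges()) and \
           all(net.multiplicity(u, v) ==
               net.multiplicity(sigma[u], sigma[v])
               for u in nodes for v in nodes):
            autos.append(sigma)
    return autos


def explicit_tree_canonical(net, root, depth):
    """Canonical string of the explicit input tree (independent oracle).

    Builds the rooted tree by recursive in-neighbor expansion and encodes it
    bottom-up as a sorted-nested-tuple string, so two nodes have equal
    strings iff their trees admit a layer-preserving bijection.
    """
    def canon(node, d):
        if d == 0:
            return "()"
        kids = []
        for tail, mult in sorted(net.in_edges(node).items()):
            kids.extend([canon(tail, d - 1)] * int(mult))
        return "(" + ",".join(sorted(kids)) + ")"

    return canon(root, depth)


def compose(sigma, tau):
    return {u: sigma[tau[u]] for u in tau}


def group_closure(generators):
    """All elements of the group generated by the given permutations."""
    elems = {tuple(sorted(g.items())) for g in generators}
    frontier = list(generators)
    while frontier:
        nxt = []
        for a in frontier:
            for g in generators:
                c = compose(a, g)
                key = tuple(sorted(c.items()))
                if key not in elems:
                    elems.add(key)
                    nxt.append(c)
        frontier = nxt
    return [dict(e) for e in elems]
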