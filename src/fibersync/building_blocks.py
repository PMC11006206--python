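"""Fiber building blocks (FBBs) and their |n, l> fiber numbers.

Every fiber of a network induces a *circuit* (the backward-reachable part of
the base graph) and a *fiber building block*: the fiber, its immediate
regulators, the shortest non-self loops through it, and — when those rules
leave the subgraph disconnected — the shortest bridging paths (composite
blocks).  Each block is summarized by two fiber numbers:

``n``  the branching ratio, the limiting ratio a_{i+1}/a_i of input-tree
       layer sizes, equal to the spectral radius of the in-adjacency
       restricted to nodes that can reach the root.  An irrational n signals
       nested loops of several lengths — a "Fibonacci fiber".

``l``  the number of edge-simple trails terminating at the block's base root,
       counted on the simple (multiplicity-ignored) base with the root's
       out-edges removed.

Multilayered blocks compose elementary blocks across backward BFS layers with
the notation |n1,l1> (+) |n2,l2> + |n3,l3> ... where (+) separates layers and
+ joins blocks within one layer.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .graphs import NeuronNetwork, build_input_tree, quotient_graph
from .partitioning import Partition

__all__ = [
    "FiberBuildingBlock",
    "MultilayerSignature",
    "extract_circuit",
    "extract_fbb",
    "branching_ratio",
    "trail_count",
    "classify",
    "multilayer_signature",
    "fibonacci_base_collapse",
]

INTEGER_TOL = 1e-6  # relative tolerance for n-loop vs Fibonacci detection
TRAIL_EDGE_CAP = 64  # enumeration cap for trail counting


@dataclass
class FiberBuildingBlock:
    """A fiber plus the wiring that determines its input-tree topology."""

    main_fiber: str
    graph: NeuronNetwork            # total-space subgraph of the block
    base: NeuronNetwork             # base-graph subgraph (one node per fiber)
    root: str                       # base node of the main fiber
    regulators: Set[str] = field(default_factory=set)  # base cell ids
    composite: bool = False
    n: float = 0.0
    ell: int = 0
    class_label: str = "finite"

    @property
    def fiber_numbers(self) -> Tuple[float, int]:
        return self.n, self.ell

    def render(self) -> str:
        return _render_pair(self.n, self.ell)


def _render_pair(n: float, ell: int) -> str:
    if abs(n - round(n)) <= INTEGER_TOL * max(1.0, abs(n)):
        n_str = str(int(round(n)))
    else:
        n_str = f"{n:.3f}"
    return f"|{n_str}, {ell}>"


@dataclass
class MultilayerSignature:
    """Ordered layers of |n, l> pairs; (+) between layers, + within one."""

    layers: List[List[Tuple[float, int]]]

    def render(self) -> str:
        parts = []
        for layer in self.layers:
            parts.append(" + ".join(_render_pair(n, ell) for n, ell in layer))
        return " (+) ".join(parts)

    @classmethod
    def parse(cls, text: str) -> "MultilayerSignature":
        layers = []
        for chunk in text.split("(+)"):
            pairs = []
            for token in chunk.split("+"):
                m = re.match(r"\s*\|\s*([0-9.]+)\s*,\s*(\d+)\s*>\s*$", token)
                if not m:
                    raise ValueError(f"cannot parse fiber number {token!r}")
                pairs.append((float(m.group(1)), int(m.group(2))))
            layers.append(pairs)
        return cls(layers)


# ---------------------------------------------------------------------------
# circuits and block synthesis (all in the base graph)


def _backward_reachable(net: NeuronNetwork, root: str) -> Set[str]:
    seen = {root}
    stack = [root]
    while stack:
        v = stack.pop()
        for tail in net.in_edges(v):
            if tail not in seen:
                seen.add(tail)
                stack.append(tail)
    return seen


def extract_circuit(net: NeuronNetwork, part: Partition,
                    fiber: str) -> NeuronNetwork:
    """Base-graph subgraph of everything feeding (transitively) into a fiber."""
    if fiber not in part.cell_ids:
        raise KeyError(f"unknown fiber {fiber!r}")
    base = quotient_graph(net, part)
    return base.subgraph(_backward_reachable(base, fiber))


def _shortest_loop_through(net: NeuronNetwork, root: str
                           ) -> Tuple[Optional[int], Set[str]]:
    """Length and node set of all shortest non-self loops through ``root``."""
    dist = {root: 0}
    queue = [root]
    parents: Dict[str, List[str]] = {}
    while queue:
        nxt = []
        for v in queue:
            for h in sorted(net.out_edges(v)):
                if h == root:
                    continue  # closing edges handled below
                if h not in dist:
                    dist[h] = dist[v] + 1
                    parents[h] = [v]
                    nxt.append(h)
                elif dist.get(h) == dist[v] + 1:
                    parents[h].append(v)
        queue = nxt
    candidates = [u for u in sorted(net.nodes)
                  if net.multiplicity(u, root) > 0 and u != root
                  and u in dist]
    if not candidates:
        return None, set()
    best = min(dist[u] for u in candidates)
    nodes: Set[str] = {root}
    for u in candidates:
        if dist[u] != best:
            continue
        frontier = {u}
        while frontier:  # all shortest predecessor chains back to root
            nodes |= frontier
            frontier = {p for x in frontier for p in parents.get(x, [])
                        if p not in nodes}
    return best + 1, nodes


def _shortest_loop_nodes(net: NeuronNetwork,
                         members: Sequence[str]) -> Set[str]:
    """Nodes of the shortest non-self loops through any fiber member;
    ties across members all included (lexicographic node order is implicit
    in the deterministic BFS)."""
    results = {}
    for m in members:
        length, nodes = _shortest_loop_through(net, m)
        if length is not None:
            results[m] = (length, nodes)
    if not results:
        return set()
    best = min(length for length, _ in results.values())
    out: Set[str] = set()
    for length, nodes in results.values():
        if length == best:
            out |= nodes
    return out


def _weak_components(base: NeuronNetwork) -> List[Set[str]]:
    seen: Set[str] = set()
    comps = []
    for start in base.nodes:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for w in list(base.out_edges(v)) + list(base.in_edges(v)):
                if w not in comp:
                    comp.add(w)
                    stack.append(w)
        seen |= comp
        comps.append(comp)
    return comps


def _bridge_nodes(base: NeuronNetwork, comps: List[Set[str]]) -> Set[str]:
    """Shortest undirected-path bridges between disconnected rule-1..3 parts."""
    added: Set[str] = set()
    # BFS over the undirected view from each component
    for i in range(len(comps) - 1):
        src, dst = comps[i], comps[i + 1]
        prev: Dict[str, Optional[str]] = {u: None for u in src}
        queue = sorted(src)
        found = None
        while queue and found is None:
            nxt = []
            for v in queue:
                for w in sorted(set(base.out_edges(v)) | set(base.in_edges(v))):
                    if w not in prev:
                        prev[w] = v
                        if w in dst:
                            found = w
                            break
                        nxt.append(w)
                if found:
                    break
            queue = nxt
        if found is None:
            continue  # genuinely unreachable; leave disconnected
        x: Optional[str] = found
        while x is not None:
            added.add(x)
            x = prev[x]
    return added


def extract_fbb(net: NeuronNetwork, part: Partition,
                fiber: str) -> FiberBuildingBlock:
    """Synthesize the fiber building block of ``fiber``.

    Rules, applied in the total space: (1) every node of the fiber; (2) their
    immediate in-neighbors (the regulators); (3) the shortest non-self loops
    through a fiber node; (4) when rules 1-3 leave the subgraph disconnected,
    the shortest paths bridging the pieces — such blocks are *composite*.
    Fiber numbers are computed on the block's base (the quotient restricted
    to the cells present in the block).
    """
    if fiber not in part.cell_ids:
        raise KeyError(f"unknown fiber {fiber!r}")
    members = part.cells_by_id[fiber]
    chosen: Set[str] = set(members)
    rule2: Set[str] = set()
    for m in members:
        rule2 |= set(net.in_edges(m))
    chosen |= rule2
    loop_nodes = _shortest_loop_nodes(net, members)           # rule 3
    chosen |= loop_nodes
    sub = net.subgraph(chosen)
    comps = _weak_components(sub)
    composite = False
    if len(comps) > 1:                                        # rule 4
        chosen |= _bridge_nodes(net, comps)
        composite = True
    total_sub = net.subgraph(chosen)

    base = quotient_graph(net, part)
    cells_present = {part.cell_of(u) for u in chosen}
    block_base = base.subgraph(cells_present)

    regulators = {part.cell_of(u) for u in rule2} - {fiber}
    # the fiber is its own regulator when members send edges back into it
    if any(part.cell_of(u) == fiber for u in rule2):
        regulators.add(fiber)

    fbb = FiberBuildingBlock(main_fiber=fiber, graph=total_sub,
                             base=block_base, root=fiber,
                             regulators=regulators, composite=composite)
    fbb.n = branching_ratio(fbb, fiber)
    fbb.ell = trail_count(fbb, fiber)
    fbb.class_label = classify(fbb)
    return fbb


# ---------------------------------------------------------------------------
# fiber numbers


def _as_base(obj) -> NeuronNetwork:
    return obj.base if isinstance(obj, FiberBuildingBlock) else obj


def branching_ratio(fbb, root: str, max_depth: int = 60,
                    tol: float = 1e-3) -> float:
    """Limiting input-tree layer-size growth rate of ``root``.

    Computed as the spectral radius of the weighted in-adjacency restricted to
    nodes that can reach the root (0 for finite trees), cross-validated
    against the empirical layer-size ratio at ``max_depth`` — raw consecutive
    ratios oscillate (3.18, 3.51, 3.28 ... on nested-loop blocks) so odd/even
    averaged ratios are used for the empirical check.
    """
    base = _as_base(fbb)
    if root not in base:
        raise KeyError(root)
    reach = sorted(_backward_reachable(base, root))
    a = base.adjacency_matrix(order=reach)
    radius = float(max(abs(np.linalg.eigvals(a)))) if len(reach) else 0.0
    if radius < 1e-9:
        return 0.0
    tree = build_input_tree(base, root, max_depth)
    sizes = tree.layer_sizes
    if sizes[-1] == 0:
        return 0.0  # finite input tree despite off-root cycles
    # raw consecutive ratios oscillate; a 12-step geometric mean cancels any
    # periodic modulation of period dividing 12
    k = min(12, max_depth - 1)
    empirical = float((sizes[max_depth] / sizes[max_depth - k]) ** (1.0 / k))
    if abs(empirical - radius) > tol * max(1.0, radius):
        raise ArithmeticError(
            f"branching ratio did not converge: spectral {radius:.6f} vs "
            f"empirical {empirical:.6f} at depth {max_depth}")
    return radius


def trail_count(fbb, root: str) -> int:
    """Number of edge-simple trails terminating at ``root``.

    Counted on the simple (multiplicity-ignored) base with the root's
    out-edges removed — the convention that reproduces the printed trail
    enumeration of nested-loop blocks, where trails do not pass through the
    root even when it has out-edges.
    """
    base = _as_base(fbb)
    if root not in base:
        raise KeyError(root)
    edges = {(u, v) for u, v, _ in base.edges() if u != root}
    if len(edges) > TRAIL_EDGE_CAP:
        raise RuntimeError(
            f"trail enumeration capped at {TRAIL_EDGE_CAP} edges "
            f"(got {len(edges)})")
    in_map: Dict[str, List[Tuple[str, str]]] = {}
    for u, v in edges:
        in_map.setdefault(v, []).append((u, v))

    def count_back(node: str, used: Set[Tuple[str, str]]) -> int:
        total = 0
        for e in in_map.get(node, []):
            if e in used:
                continue
            used.add(e)
            total += 1 + count_back(e[0], used)
            used.discard(e)
        return total

    return count_back(root, set())


def classify(fbb: FiberBuildingBlock, tol: float = INTEGER_TOL) -> str:
    """finite (n=0), n-loop (integer n>=1), Fibonacci (irrational n), or
    composite when the bridging rule fired."""
    if fbb.composite:
        return "composite"
    n = fbb.n
    if n == 0:
        return "finite"
    if abs(n - round(n)) <= tol * max(1.0, abs(n)) and round(n) >= 1:
        return "n-loop"
    return "Fibonacci"


def multilayer_signature(net: NeuronNetwork, part: Partition,
                         fiber: str) -> MultilayerSignature:
    """Layered |n, l> composition of the circuit feeding ``fiber``.

    Layer 1 is the elementary block of the main fiber; deeper layers collect,
    at their first (shallowest) backward BFS distance, the elementary blocks
    of the induced fibers.  Pure-source fibers (blocks with no edges) carry no
    structure beyond the regulator trails already counted downstream and are
    skipped.
    """
    circuit = extract_circuit(net, part, fiber)
    # backward BFS distance from the main fiber in the circuit base
    dist = {fiber: 0}
    queue = [fiber]
    while queue:
        nxt = []
        for v in queue:
            for tail in sorted(circuit.in_edges(v)):
                if tail not in dist:
                    dist[tail] = dist[v] + 1
                    nxt.append(tail)
        queue = nxt
    blocks = {c: extract_fbb(net, part, c) for c in dist}
    layers: List[List[Tuple[float, int]]] = [[blocks[fiber].fiber_numbers]]
    for d in range(1, max(dist.values()) + 1 if dist else 1):
        layer = []
        for c in sorted(x for x, dd in dist.items() if dd == d):
            fb = blocks[c]
            if fb.base.n_edges == 0:
                continue  # pure source, already a regulator downstream
            layer.append(fb.fiber_numbers)
        if layer:
            layers.append(layer)
    return MultilayerSignature(layers=layers)


def fibonacci_base_collapse(fbb: FiberBuildingBlock,
                            tol: float = 1e-6) -> NeuronNetwork:
    """Quotient the block's base under its own minimal balanced coloring.

    Nested-loop blocks often collapse to a two-node Fibonacci base with a
    self-loop; the dominant eigenvalue (branching ratio) is preserved, which
    is asserted.  Already-minimal blocks return an isomorphic copy.
    """
    from .partitioning import minimal_balanced_coloring

    base = fbb.base
    part = minimal_balanced_coloring(base)
    collapsed = quotient_graph(base, part)
    before = _spectral_radius(base)
    after = _spectral_radius(collapsed)
    if abs(before - after) > tol * max(1.0, before):
        raise ArithmeticError(
            f"collapse changed the dominant eigenvalue: {before} -> {after}")
    return collapsed


def _spectral_radius(net: NeuronNetwork) -> float:
    if net.n == 0:
        return 0.0
    return float(max(abs(np.linalg.eigvals(net.adjacency_matrix()))))
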