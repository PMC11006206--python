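"""Planted-symmetry network generators and worked-example fixtures.

The study networks (small directed chemical-synapse circuits of 22-30 neurons
and undirected gap-junction circuits of 20-29 neurons, each with a handful of
fibers, left-right interneuron pairs in their own size-2 cells, and small
integer edge weights) are emulated here by *random lifts*: a base graph B on
k cells is chosen with a discrete minimal balanced coloring, and every node of
cell i receives exactly B[j][i] in-edges from cell j.  Because the input tree
of a lifted node equals the input tree of its base cell, the planted partition
is guaranteed to be the minimal balanced coloring whenever the base coloring
is discrete — which the generator certifies before returning.

Undirected lifts use deterministic circulant / round-robin wirings so that a
simultaneous cyclic rotation of every cell is a graph automorphism; on those
draws the orbit partition provably equals the fiber partition, mirroring the
gap-junction networks of the worm.  The ``*_like`` fixtures are clearly
synthetic stand-ins at the connectome's node/fiber counts, not the real
repaired circuits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graphs import NeuronNetwork
from .partitioning import Partition, minimal_balanced_coloring

__all__ = [
    "PlantedFiberSpec",
    "planted_fiber_graph",
    "fixture",
    "perturb_weights",
]


class SpecError(ValueError):
    """Infeasible planted-fiber specification."""


@dataclass
class PlantedFiberSpec:
    """Base graph + cell sizes defining a random lift.

    ``base[j][i]`` is the in-multiplicity every node of cell i receives from
    cell j (tails chosen in cell j).  ``pair_cells`` marks size-2 cells that
    play the role of left-right interneuron pairs.
    """

    cell_sizes: Sequence[int]
    base: Sequence[Sequence[int]]       # k x k, base[j][i] = mult j -> i
    directed: bool = True
    cell_names: Optional[Sequence[str]] = None
    pair_cells: Sequence[int] = field(default_factory=tuple)
    allow_multiplicity: bool = True
    seed: int = 0
    max_retries: int = 20

    @property
    def k(self) -> int:
        return len(self.cell_sizes)

    def node_names(self) -> List[List[str]]:
        names = []
        for c in range(self.k):
            stem = (self.cell_names[c] if self.cell_names
                    else f"F{c:02d}")
            names.append([f"{stem}n{i:02d}"
                          for i in range(self.cell_sizes[c])])
        return names

    def validate(self) -> None:
        k = self.k
        if len(self.base) != k or any(len(row) != k for row in self.base):
            raise SpecError("base matrix shape does not match cell count")
        for j in range(k):
            for i in range(k):
                b = self.base[j][i]
                if b < 0:
                    raise SpecError("negative base multiplicity")
                if b > self.cell_sizes[j] and not self.allow_multiplicity:
                    raise SpecError(
                        f"cell {i} needs {b} in-edges from cell {j} of size "
                        f"{self.cell_sizes[j]} without multiplicity allowance")
        for c in self.pair_cells:
            if self.cell_sizes[c] != 2:
                raise SpecError("pair cells must have size 2")
        if not self.directed:
            for j in range(self.k):
                for i in range(j, self.k):
                    lhs = self.cell_sizes[i] * self.base[j][i]
                    rhs = self.cell_sizes[j] * self.base[i][j]
                    if lhs != rhs:
                        raise SpecError(
                            f"undirected edge budget mismatch between cells "
                            f"{j} and {i}: {lhs} != {rhs}")
                d = self.base[i][i]
                s = self.cell_sizes[i]
                if d and (d >= s or (d * s) % 2):
                    raise SpecError(
                        f"cell {i}: cannot realize a {d}-regular simple "
                        f"graph on {s} nodes")
            for i in range(j + 1, self.k):
                total = self.cell_sizes[i] * self.base[j][i]
                if total:
                    lcm = (self.cell_sizes[i] * self.cell_sizes[j]
                           // math.gcd(self.cell_sizes[i],
                                       self.cell_sizes[j]))
                    if total % lcm:
                        raise SpecError(
                            f"cells {j}-{i}: edge budget {total} is not a "
                            f"multiple of lcm {lcm}; the rotation-invariant "
                            f"wiring would be non-uniform")


def _lift_directed(spec: PlantedFiberSpec, rng: np.random.Generator
                   ) -> NeuronNetwork:
    net = NeuronNetwork(directed=True)
    names = spec.node_names()
    for cell in names:
        for u in cell:
            net.add_node(u)
    for i in range(spec.k):
        for head in names[i]:
            for j in range(spec.k):
                b = spec.base[j][i]
                if b == 0:
                    continue
                pool = [u for u in names[j] if u != head]
                if i == j and b > len(pool) and not spec.allow_multiplicity:
                    raise SpecError(
                        f"cell {i}: within-cell in-degree {b} infeasible")
                if not pool:
                    net.add_edge(head, head, b)  # size-1 cell: self-loops
                elif b <= len(pool):
                    tails = rng.choice(len(pool), size=b, replace=False)
                    for t in tails:
                        net.add_edge(pool[t], head, 1)
                else:
                    base_each, extra = divmod(b, len(pool))
                    for t, u in enumerate(pool):
                        w = base_each + (1 if t < extra else 0)
                        if w:
                            net.add_edge(u, head, w)
    return net


def _undirected_internal(net: NeuronNetwork, cell: List[str], d: int) -> None:
    s = len(cell)
    edges = set()
    offsets = list(range(1, d // 2 + 1))
    if d % 2:
        offsets.append(s // 2)
    for off in offsets:
        for a in range(s):
            b = (a + off) % s
            e = (min(a, b), max(a, b))
            edges.add(e)
    for a, b in sorted(edges):
        net.add_edge(cell[a], cell[b], 1)


def _undirected_between(net: NeuronNetwork, cell_a: List[str],
                        cell_b: List[str], deg_a_to_each_b: int) -> None:
    """Round-robin bi-regular bipartite wiring (rotation-invariant)."""
    sa, sb = len(cell_a), len(cell_b)
    total = sb * deg_a_to_each_b  # edges counting multiplicity
    weights: Dict[Tuple[int, int], int] = {}
    for e in range(total):
        key = (e % sa, e % sb)
        weights[key] = weights.get(key, 0) + 1
    for (a, b), w in sorted(weights.items()):
        net.add_edge(cell_a[a], cell_b[b], w)


def _lift_undirected(spec: PlantedFiberSpec) -> NeuronNetwork:
    net = NeuronNetwork(directed=False)
    names = spec.node_names()
    for cell in names:
        for u in cell:
            net.add_node(u)
    for i in range(spec.k):
        d = spec.base[i][i]
        if d:
            _undirected_internal(net, names[i], d)
    for j in range(spec.k):
        for i in range(j + 1, spec.k):
            b = spec.base[j][i]  # in-mult each node of cell i gets from cell j
            if b:
                _undirected_between(net, names[j], names[i], b)
    return net


def planted_fiber_graph(spec: PlantedFiberSpec
                        ) -> Tuple[NeuronNetwork, Partition]:
    """Random lift of the base with certified planted minimal coloring.

    Deterministic per seed.  Draws whose minimal balanced coloring differs
    from the planted partition (possible only if the base coloring is not
    discrete) are resampled up to ``max_retries`` times, then rejected.
    """
    spec.validate()
    names = spec.node_names()
    planted = Partition.from_cells(
        names, ids=[spec.cell_names[c] if spec.cell_names else f"F{c:02d}"
                    for c in range(spec.k)])
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.max_retries):
        net = _lift_undirected(spec) if not spec.directed \
            else _lift_directed(spec, rng)
        recovered = minimal_balanced_coloring(net)
        if recovered == planted:
            return net, planted
        if not spec.directed:
            break  # deterministic construction; retrying cannot help
    raise SpecError(
        "could not realize a lift whose minimal balanced coloring equals the "
        "planted partition; the base graph likely has merging cells")


# ---------------------------------------------------------------------------
# named fixtures


def _cyan_multigraph() -> NeuronNetwork:
    """Three-node nested-loop multigraph with branching ratio 3.3723...

    In-multiplicities: C<-M:1, C<-P:2, M<-C:1, M<-P:2, P<-C:2, P<-M:2; its
    input-tree layer sizes from C follow t(n+3) = 9 t(n+1) + 8 t(n) seeded
    (1, 3, 11).
    """
    net = NeuronNetwork(directed=True)
    for tail, head, w in [("M", "C", 1), ("P", "C", 2), ("C", "M", 1),
                          ("P", "M", 2), ("C", "P", 2), ("M", "P", 2)]:
        net.add_edge(tail, head, w)
    return net


def _two_regulator_hub() -> Tuple[NeuronNetwork, Partition]:
    # the two sources play the role of two *distinct* regulator fibers (as
    # in the worked first-layer block), hence the singleton cells
    net = NeuronNetwork(directed=True)
    net.add_edge("S1", "H", 1)
    net.add_edge("S2", "H", 1)
    part = Partition.from_cells([["H"], ["S1"], ["S2"]],
                                ids=["hub", "src1", "src2"])
    return net, part


def _bidirectional_square() -> Tuple[NeuronNetwork, Partition]:
    net = NeuronNetwork(directed=False)
    ring = ["Q1", "Q2", "Q3", "Q4"]
    for a, b in zip(ring, ring[1:] + ring[:1]):
        net.add_edge(a, b, 1)
    part = Partition.from_cells([ring], ids=["square"])
    return net, part


def fibonacci_base(a: int, b: int, c: int, d: int) -> NeuronNetwork:
    """Two-node base with self-loops a, d and cross-multiplicities c (X->Y),
    b (Y->X); fibonacci_base(1, 1, 1, 0) grows at the golden ratio."""
    net = NeuronNetwork(directed=True)
    net.add_node("X")
    net.add_node("Y")
    if a:
        net.add_edge("X", "X", a)
    if b:
        net.add_edge("Y", "X", b)
    if c:
        net.add_edge("X", "Y", c)
    if d:
        net.add_edge("Y", "Y", d)
    return net


def _multilayer_pair_spec(seed: int) -> PlantedFiberSpec:
    # two looping fibers A <-> B plus a pure source; the elementary blocks
    # compose as |1, 1> (+) |1, 2>
    return PlantedFiberSpec(
        cell_sizes=[2, 2, 2],
        base=[  # rows = tail cell, cols = head cell (in-mult per head node)
            [0, 1, 0],   # A -> B
            [1, 0, 0],   # B -> A
            [0, 1, 0],   # S -> B
        ],
        directed=True,
        cell_names=["A", "B", "S"],
        seed=seed,
    )


def _forward_chem_like_spec(seed: int) -> PlantedFiberSpec:
    # 22 neurons, 4 fibers: one driver interneuron pair and three motor cells
    return PlantedFiberSpec(
        cell_sizes=[2, 8, 6, 6],
        base=[
            [0, 2, 1, 0],   # P drives M1 (both members) and M2
            [0, 1, 0, 0],   # M1 internal loop
            [0, 0, 2, 1],   # M2 internal loop, M2 -> M3
            [0, 0, 0, 1],   # M3 internal loop
        ],
        directed=True,
        cell_names=["P", "M1", "M2", "M3"],
        pair_cells=[0],
        seed=seed,
    )


def _backward_chem_like_spec(seed: int) -> PlantedFiberSpec:
    # 30 neurons, 10 fibers: five interneuron pairs (nested-loop core like
    # the cyan block) plus five motor fibers
    return PlantedFiberSpec(
        cell_sizes=[2, 2, 2, 2, 2, 4, 4, 4, 4, 4],
        base=[
            # I1 I2 I3 I4 I5 M1 M2 M3 M4 M5     (entries: in-mult per head)
            # the I1/I2 loop multiplicities are deliberately asymmetric so
            # the nested-loop core has pairwise distinct input trees
            [0, 2, 2, 2, 0, 2, 1, 0, 0, 0],   # I1 (C-like)
            [1, 0, 2, 0, 0, 0, 0, 2, 0, 0],   # I2 (M-like)
            [2, 1, 0, 0, 0, 0, 0, 0, 0, 0],   # I3 (P-like)
            [0, 0, 0, 0, 2, 0, 0, 0, 0, 0],   # I4
            [0, 0, 0, 0, 0, 0, 0, 0, 2, 2],   # I5
            [0, 0, 0, 0, 0, 1, 0, 0, 0, 0],   # M1 internal
            [0, 0, 0, 0, 0, 0, 2, 0, 0, 0],   # M2 internal
            [0, 0, 0, 0, 0, 0, 0, 1, 0, 0],   # M3 internal
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],   # M4 (sink fiber)
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 1],   # M5 internal
        ],
        directed=True,
        cell_names=["I1", "I2", "I3", "I4", "I5",
                    "M1", "M2", "M3", "M4", "M5"],
        pair_cells=[0, 1, 2, 3, 4],
        seed=seed,
    )


def _gap_like_spec(seed: int, backward: bool = False) -> PlantedFiberSpec:
    if not backward:
        # 20 neurons, 6 fibers (one singleton), undirected
        sizes = [2, 1, 5, 4, 4, 4]
        base = [
            # P  S  M1 M2 M3 M4
            [0, 2, 2, 0, 0, 2],   # P - S, P - M1, P - M4
            [1, 0, 0, 1, 0, 0],   # S - M2
            [5, 0, 2, 0, 0, 0],   # M1 internal ring
            [0, 4, 0, 2, 1, 0],   # M2 internal ring, M2 - M3
            [0, 0, 0, 1, 2, 0],   # M3 internal ring
            [4, 0, 0, 0, 0, 3],   # M4 internal K4
        ]
    else:
        # 29 neurons, 6 fibers, undirected
        sizes = [2, 1, 6, 8, 6, 6]
        base = [
            [0, 2, 2, 0, 0, 2],
            [1, 0, 0, 1, 0, 0],
            [6, 0, 2, 0, 0, 0],
            [0, 8, 0, 2, 4, 0],
            [0, 0, 0, 3, 2, 0],
            [6, 0, 0, 0, 0, 3],
        ]
    return PlantedFiberSpec(
        cell_sizes=sizes, base=base, directed=False,
        cell_names=["P", "S", "M1", "M2", "M3", "M4"],
        pair_cells=[0], seed=seed)


FIXTURE_NAMES = (
    "cyan_multigraph", "two_regulator_hub", "bidirectional_square",
    "multilayer_pair", "forward_chem_like", "backward_chem_like",
    "gap_like", "backward_gap_like",
)


def fixture(name: str, seed: int = 0, **kwargs
            ) -> Tuple[NeuronNetwork, Optional[Partition]]:
    """Named worked-example networks and connectome-scale stand-ins.

    Returns (network, partition) where the partition is the planted/known
    fiber partition, or None when no canonical partition is defined.
    """
    if name == "cyan_multigraph":
        return _cyan_multigraph(), None
    if name == "two_regulator_hub":
        return _two_regulator_hub()
    if name == "bidirectional_square":
        return _bidirectional_square()
    if name == "fibonacci_base":
        return fibonacci_base(*kwargs.get("abcd", (1, 1, 1, 0))), None
    if name == "multilayer_pair":
        return planted_fiber_graph(_multilayer_pair_spec(seed))
    if name == "forward_chem_like":
        return planted_fiber_graph(_forward_chem_like_spec(seed))
    if name == "backward_chem_like":
        return planted_fiber_graph(_backward_chem_like_spec(seed))
    if name == "gap_like":
        return planted_fiber_graph(_gap_like_spec(seed))
    if name == "backward_gap_like":
        return planted_fiber_graph(_gap_like_spec(seed, backward=True))
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def perturb_weights(net: NeuronNetwork, std: float,
                    seed: int = 0) -> NeuronNetwork:
    """Subtract N(0, std^2) noise from every nonzero weight, independently.

    Edge support is preserved (weights become real but are never zeroed or
    created); std = 0 returns an identical copy.  Symmetry analysis should
    run on the unperturbed integer network.
    """
    if std < 0:
        raise ValueError("std must be >= 0")
    out = net.copy()
    if std == 0:
        return out
    rng = np.random.default_rng(seed)
    if net.directed:
        for u, v, w in net.edges():
            out._succ[u][v] = w - rng.normal(0.0, std)
            out._pred[v][u] = out._succ[u][v]
    else:
        seen = set()
        for u, v, w in net.edges():
            key = frozenset((u, v))
            if key in seen and u != v:
                continue
            seen.add(key)
            neww = w - rng.normal(0.0, std)
            out._succ[u][v] = neww
            out._pred[v][u] = neww
            if u != v:
                out._succ[v][u] = neww
                out._pred[u][v] = neww
    return out
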