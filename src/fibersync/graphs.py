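"""Core multigraph model for neuronal wiring.

A :class:`NeuronNetwork` is a directed multigraph with positive integer edge
multiplicities (the number of synaptic contacts between two neurons).  Gap
junction networks are undirected; an undirected edge is stored as two opposed
directed edges with equal multiplicity, so every algorithm downstream only has
to reason about directed in-edges.  Edge weights become real-valued only after
a controlled weight perturbation (see :mod:`fibersync.synthetic_data`); all
symmetry analysis is meant to run on integer-weighted networks.

The module also builds *input trees* — the rooted layered tree of all walks
terminating at a node — and quotient (base) graphs under a balanced partition.
Nodes with isomorphic input trees belong to the same fiber and admit exactly
synchronized dynamics under any admissible ODE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "NeuronNetwork",
    "InputTree",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
    "build_input_tree",
    "input_trees_isomorphic",
    "quotient_graph",
]


class FormatError(ValueError):
    """Raised for malformed network files (non-integer or negative weights)."""


class NeuronNetwork:
    """Directed multigraph with integer (or, post-perturbation, real) weights.

    Parameters
    ----------
    directed:
        If False the network is a gap-junction style undirected graph and
        every added edge is symmetrized.
    """

    def __init__(self, directed: bool = True):
        self.directed = directed
        self._succ: Dict[str, Dict[str, float]] = {}
        self._pred: Dict[str, Dict[str, float]] = {}
        #: optional per-edge sign (+1 excitatory, -1 inhibitory), default +1
        self.edge_sign: Dict[Tuple[str, str], int] = {}

    # -- construction ------------------------------------------------------

    def add_node(self, node: str) -> None:
        node = str(node)
        self._succ.setdefault(node, {})
        self._pred.setdefault(node, {})

    def add_edge(self, tail: str, head: str, weight: float = 1,
                 sign: int = 1) -> None:
        """Add ``weight`` to the multiplicity of tail->head.

        In undirected mode the opposite edge is updated as well, keeping the
        multiplicity symmetry m(u->v) == m(v->u).
        """
        if weight <= 0:
            raise FormatError(f"edge weight must be positive, got {weight!r}")
        tail, head = str(tail), str(head)
        self.add_node(tail)
        self.add_node(head)
        self._succ[tail][head] = self._succ[tail].get(head, 0) + weight
        self._pred[head][tail] = self._pred[head].get(tail, 0) + weight
        if sign != 1:
            self.edge_sign[(tail, head)] = sign
        if not self.directed and tail != head:
            self._succ[head][tail] = self._succ[head].get(tail, 0) + weight
            self._pred[tail][head] = self._pred[tail].get(head, 0) + weight
            if sign != 1:
                self.edge_sign[(head, tail)] = sign

    def set_weight(self, tail: str, head: str, weight: float) -> None:
        """Overwrite the multiplicity of an existing edge (may be real)."""
        if (head not in self._succ.get(tail, {})):
            raise KeyError(f"no edge {tail}->{head}")
        self._succ[tail][head] = weight
        self._pred[head][tail] = weight

    # -- inspection --------------------------------------------------------

    @property
    def nodes(self) -> List[str]:
        """Nodes in sorted (deterministic) order."""
        return sorted(self._succ)

    @property
    def n(self) -> int:
        return len(self._succ)

    def __contains__(self, node: str) -> bool:
        return node in self._succ

    def edges(self) -> Iterable[Tuple[str, str, float]]:
        for u in self.nodes:
            for v in sorted(self._succ[u]):
                yield u, v, self._succ[u][v]

    @property
    def n_edges(self) -> int:
        """Number of directed edges counting multiplicity."""
        return int(round(sum(w for _, _, w in self.edges())))

    def multiplicity(self, tail: str, head: str) -> float:
        return self._succ.get(tail, {}).get(head, 0)

    def in_edges(self, node: str) -> Mapping[str, float]:
        """Mapping tail -> multiplicity of in-edges of ``node``."""
        if node not in self._pred:
            raise KeyError(node)
        return self._pred[node]

    def out_edges(self, node: str) -> Mapping[str, float]:
        if node not in self._succ:
            raise KeyError(node)
        return self._succ[node]

    def in_degree(self, node: str, weighted: bool = True) -> float:
        preds = self.in_edges(node)
        return sum(preds.values()) if weighted else len(preds)

    def out_degree(self, node: str, weighted: bool = True) -> float:
        succs = self.out_edges(node)
        return sum(succs.values()) if weighted else len(succs)

    def sign(self, tail: str, head: str) -> int:
        return self.edge_sign.get((tail, head), 1)

    # -- derived views -----------------------------------------------------

    def copy(self) -> "NeuronNetwork":
        g = NeuronNetwork(directed=self.directed)
        for u in self._succ:
            g.add_node(u)
        g._succ = {u: dict(d) for u, d in self._succ.items()}
        g._pred = {u: dict(d) for u, d in self._pred.items()}
        g.edge_sign = dict(self.edge_sign)
        return g

    def binarized(self) -> "NeuronNetwork":
        """Clamp all multiplicities to 1 (binary-adjacency view)."""
        g = self.copy()
        g._succ = {u: {v: 1 for v in d} for u, d in self._succ.items()}
        g._pred = {u: {v: 1 for v in d} for u, d in self._pred.items()}
        return g

    def subgraph(self, nodes: Iterable[str]) -> "NeuronNetwork":
        """Induced subgraph on ``nodes`` (keeps directedness and signs)."""
        keep = set(nodes)
        missing = keep - set(self._succ)
        if missing:
            raise KeyError(f"unknown nodes: {sorted(missing)}")
        g = NeuronNetwork(directed=self.directed)
        for u in keep:
            g.add_node(u)
        for u in keep:
            for v, w in self._succ[u].items():
                if v in keep:
                    g._succ[u][v] = w
                    g._pred[v][u] = w
                    if (u, v) in self.edge_sign:
                        g.edge_sign[(u, v)] = self.edge_sign[(u, v)]
        return g

    def adjacency_matrix(self, order: Optional[List[str]] = None):
        """Weighted adjacency A with A[i, j] = multiplicity(order[i] -> order[j])."""
        import numpy as np

        order = order or self.nodes
        idx = {u: i for i, u in enumerate(order)}
        a = np.zeros((len(order), len(order)))
        for u, v, w in self.edges():
            if u in idx and v in idx:
                a[idx[u], idx[v]] = w
        return a

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v, w in self.edges():
            g.add_edge(u, v, weight=w, sign=self.sign(u, v))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, directed: Optional[bool] = None
                      ) -> "NeuronNetwork":
        directed = g.is_directed() if directed is None else directed
        net = cls(directed=directed)
        for u in g.nodes:
            net.add_node(str(u))
        seen = set()
        for u, v, data in g.edges(data=True):
            if not directed:
                key = frozenset((str(u), str(v)))
                if key in seen and u != v:
                    continue
                seen.add(key)
            net.add_edge(str(u), str(v), data.get("weight", 1),
                         data.get("sign", 1))
        return net

    def validate(self) -> None:
        for u, d in self._succ.items():
            for v, w in d.items():
                if w <= 0:
                    raise FormatError(f"non-positive weight on {u}->{v}")
                if not self.directed and self._succ.get(v, {}).get(u) != w:
                    raise FormatError(
                        f"undirected network asymmetric on {u}<->{v}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "directed" if self.directed else "undirected"
        return f"<NeuronNetwork {kind} n={self.n} edges={self.n_edges}>"


# ---------------------------------------------------------------------------
# file I/O


def _parse_weight(token: str) -> int:
    try:
        w = int(token)
    except ValueError:
        try:
            f = float(token)
        except ValueError:
            raise FormatError(f"weight {token!r} is not a number") from None
        if f != int(f):
            raise FormatError(f"weight {token!r} is not an integer")
        w = int(f)
    if w <= 0:
        raise FormatError(f"weight must be a positive integer, got {w}")
    return w


def read_edge_list(path: str | Path, directed: bool = True) -> NeuronNetwork:
    """Read a whitespace/TSV edge list ``tail head [weight]``.

    Duplicate rows have their multiplicities summed (with a logged warning);
    an empty file yields an empty network.
    """
    net = NeuronNetwork(directed=directed)
    seen = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'tail head [weight]'")
        tail, head = parts[0], parts[1]
        weight = _parse_weight(parts[2]) if len(parts) > 2 else 1
        key = (tail, head)
        if key in seen:
            logger.warning("%s:%d: duplicate edge %s->%s, multiplicities summed",
                           path, lineno, tail, head)
        seen.add(key)
        net.add_edge(tail, head, weight)
    return net


def write_edge_list(net: NeuronNetwork, path: str | Path) -> None:
    lines = []
    seen = set()
    for u, v, w in net.edges():
        if not net.directed:
            key = frozenset((u, v))
            if key in seen and u != v:
                continue
            seen.add(key)
        w_out = int(w) if float(w).is_integer() else w
        lines.append(f"{u}\t{v}\t{w_out}")
    # isolated nodes are not representable in an edge list; warn if present
    touched = {x for u, v, _ in net.edges() for x in (u, v)}
    for u in net.nodes:
        if u not in touched:
            logger.warning("node %s is isolated and omitted from edge list", u)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_graphml(path: str | Path, directed: Optional[bool] = None
                 ) -> NeuronNetwork:
    g = nx.read_graphml(str(path))
    net = NeuronNetwork.from_networkx(g, directed=directed)
    for u, v, w in net.edges():
        if float(w) != int(float(w)) or w <= 0:
            raise FormatError(f"non-integer/negative weight on {u}->{v}")
    return net


def write_graphml(net: NeuronNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), str(path))


# ---------------------------------------------------------------------------
# input trees


@dataclass
class InputTree:
    """Layered multiset view of all walks terminating at ``root``.

    ``layers[i]`` maps a network node to the number of times it appears in
    layer ``i`` of the tree, i.e. the number of walks of length ``i`` from
    that node to the root.  ``layer_sizes[i]`` is the total number of nodes
    in layer ``i`` (``a_i``); layer 0 is the root alone.
    """

    root: str
    layers: List[Dict[str, int]] = field(default_factory=list)

    @property
    def layer_sizes(self) -> List[int]:
        return [sum(layer.values()) for layer in self.layers]

    @property
    def depth(self) -> int:
        return len(self.layers) - 1


def build_input_tree(net: NeuronNetwork, root: str, depth: int) -> InputTree:
    """Expand the input tree of ``root`` down to ``depth`` layers.

    Layer i+1 is the in-neighbor expansion (with multiplicity) of layer i:
    a node u appears in layer i+1 once for every walk of length i+1 from u
    to the root, so counts are exact integers even when layers grow
    geometrically.
    """
    if root not in net:
        raise KeyError(root)
    if depth < 0:
        raise ValueError("depth must be >= 0")
    layers: List[Dict[str, int]] = [{root: 1}]
    for _ in range(depth):
        nxt: Dict[str, int] = {}
        for node, count in layers[-1].items():
            for tail, mult in net.in_edges(node).items():
                nxt[tail] = nxt.get(tail, 0) + count * int(round(mult))
        layers.append(nxt)
    return InputTree(root=root, layers=layers)


def _refinement_colors(net: NeuronNetwork, rounds: int,
                       weighted: bool = True) -> List[Dict[str, int]]:
    """Color refinement on in-neighborhoods, one entry per round.

    Round 0 colors every node identically; round r+1 recolors by the multiset
    of (in-neighbor color, multiplicity) pairs.  Two nodes share a color after
    r rounds exactly when their input trees are isomorphic to depth r, which
    is the workhorse identity behind both the isomorphism test and the
    minimal balanced coloring.
    """
    colors = {u: 0 for u in net.nodes}
    history = [dict(colors)]
    for _ in range(rounds):
        sigs = {}
        for u in net.nodes:
            # total in-multiplicity per (color, sign) class: a weight-2 edge
            # contributes two indistinguishable child subtrees, exactly like
            # two single edges from same-colored tails
            totals: Dict[tuple, float] = {}
            for tail, mult in net.in_edges(u).items():
                m = mult if weighted else 1
                key = (colors[tail], net.sign(tail, u))
                totals[key] = totals.get(key, 0) + m
            sigs[u] = (colors[u], tuple(sorted(totals.items())))
        palette = {s: i for i, s in enumerate(sorted(set(sigs.values())))}
        new = {u: palette[sigs[u]] for u in net.nodes}
        history.append(new)
        if len(set(new.values())) == len(set(colors.values())):
            colors = new
            break
        colors = new
    return history


def input_trees_isomorphic(net: NeuronNetwork, u: str, v: str,
                           depth: Optional[int] = None) -> bool:
    """True iff the input trees of u and v admit a layer-preserving bijection.

    Decided by canonical bottom-up color refinement rather than explicit
    bijection search; the default depth n-1 is enough to distinguish any two
    non-isomorphic (infinite) input trees.
    """
    if u not in net or v not in net:
        raise KeyError(f"unknown node in ({u!r}, {v!r})")
    if u == v:
        return True
    if depth is None:
        depth = max(net.n - 1, 0)
    history = _refinement_colors(net, depth)
    last = history[-1]
    return last[u] == last[v]


# ---------------------------------------------------------------------------
# quotient (base) graphs


class UnbalancedPartitionError(ValueError):
    """Partition is not equitable; carries a witness node pair."""

    def __init__(self, v: str, v2: str, cell: str):
        self.witness = (v, v2, cell)
        super().__init__(
            f"partition not balanced: nodes {v!r} and {v2!r} receive "
            f"different in-multiplicity from cell {cell!r}")


def quotient_graph(net: NeuronNetwork, part) -> NeuronNetwork:
    """Collapse every cell of a balanced partition onto one base node.

    The multiplicity from base cell X to base cell Y equals the in-multiplicity
    any single representative of Y receives from members of X — well defined
    exactly because the partition is balanced, which is enforced.
    """
    from .partitioning import is_equitable

    ok, witness = is_equitable(net, part)
    if not ok:
        v, v2, cell = witness
        raise UnbalancedPartitionError(v, v2, cell)
    # the base of an undirected graph is in general directed: cells of
    # different sizes exchange different per-node in-multiplicities
    base = NeuronNetwork(directed=True)
    for cell_id in part.cell_ids:
        base.add_node(cell_id)
    for cell_id in part.cell_ids:
        rep = part.cells_by_id[cell_id][0]
        received: Dict[str, float] = {}
        for tail, mult in net.in_edges(rep).items():
            src = part.cell_of(tail)
            received[src] = received.get(src, 0) + mult
        for src, mult in received.items():
            base._succ[src][cell_id] = mult
            base._pred[cell_id][src] = mult
    return base
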