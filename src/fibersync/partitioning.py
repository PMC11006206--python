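"""Balanced colorings (fibers) and automorphism orbits.

The minimal balanced coloring — the coarsest equitable partition — is found by
iterated color refinement on in-neighborhoods: all nodes start with one color
and are recolored by the multiset of colored inputs they receive until the
number of colors stabilizes.  Its cells are the fibers of the minimal graph
fibration; nodes in a fiber have isomorphic input trees and synchronize under
admissible dynamics.

Orbits come from the automorphism group: permutations P with P A P^-1 = A on
the weighted adjacency.  A generating set is found by an in-house backtracking
search along a stabilizer chain, pruned by a symmetric (in+out) refinement
coloring; orbits are the connected components of node -> image links over the
generators.  Every orbit is contained in a fiber, never the other way round.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .graphs import NeuronNetwork

__all__ = [
    "Partition",
    "AutomorphismSet",
    "is_equitable",
    "minimal_balanced_coloring",
    "automorphisms",
    "orbit_partition",
]

MAX_AUTOMORPHISM_NODES = 64


class CapabilityError(RuntimeError):
    """Problem size exceeds what the in-house search is intended for."""


@dataclass(frozen=True)
class Partition:
    """Assignment of nodes to disjoint, covering cells (colors)."""

    mapping: Mapping[str, str]

    @classmethod
    def from_cells(cls, cells: Sequence[Sequence[str]],
                   ids: Optional[Sequence[str]] = None) -> "Partition":
        if ids is None:
            ordered = sorted((sorted(c) for c in cells), key=lambda c: c[0])
            return cls({u: f"c{i}" for i, cell in enumerate(ordered)
                        for u in cell})
        mapping = {}
        for cid, cell in zip(ids, cells):
            for u in cell:
                mapping[str(u)] = str(cid)
        return cls(mapping)

    @classmethod
    def singletons(cls, nodes: Sequence[str]) -> "Partition":
        return cls.from_cells([[u] for u in nodes])

    def cell_of(self, node: str) -> str:
        return self.mapping[node]

    @property
    def nodes(self) -> List[str]:
        return sorted(self.mapping)

    @property
    def cells_by_id(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for u in sorted(self.mapping):
            out.setdefault(self.mapping[u], []).append(u)
        return out

    @property
    def cells(self) -> List[List[str]]:
        """Cells as sorted node lists, ordered by their smallest member."""
        return sorted(self.cells_by_id.values(), key=lambda c: c[0])

    @property
    def cell_ids(self) -> List[str]:
        by_id = self.cells_by_id
        return sorted(by_id, key=lambda cid: by_id[cid][0])

    @property
    def k(self) -> int:
        return len(set(self.mapping.values()))

    def same_cell(self, u: str, v: str) -> bool:
        return self.mapping[u] == self.mapping[v]

    def as_frozen(self) -> frozenset:
        return frozenset(frozenset(c) for c in self.cells)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.as_frozen() == other.as_frozen()

    def __hash__(self) -> int:
        return hash(self.as_frozen())

    def refines(self, other: "Partition") -> bool:
        """True iff every cell of self is a subset of a cell of other."""
        return all(len({other.mapping[u] for u in cell}) == 1
                   for cell in self.cells)

    # two-column TSV (node, color) serialization
    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{u}\t{self.mapping[u]}" for u in self.nodes]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Partition":
        mapping = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            node, color = line.split("\t")
            mapping[node] = color
        return cls(mapping)


def is_equitable(net: NeuronNetwork, part: Partition
                 ) -> Tuple[bool, Optional[Tuple[str, str, str]]]:
    """Check the balanced-coloring condition.

    Every node of a cell C_i must receive the same in-multiplicity from each
    cell C_j.  Returns (True, None) or (False, (v, v', C_j)) with a witness
    pair disagreeing on inputs from C_j.
    """
    missing = set(net.nodes) - set(part.mapping)
    if missing:
        raise KeyError(f"partition does not cover nodes {sorted(missing)}")

    def profile(v: str) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for tail, mult in net.in_edges(v).items():
            src = part.cell_of(tail)
            out[src] = out.get(src, 0) + mult
        return out

    for cell in part.cells:
        ref = profile(cell[0])
        for v in cell[1:]:
            p = profile(v)
            if p != ref:
                bad = sorted(set(ref) ^ set(p)
                             | {c for c in set(ref) & set(p) if ref[c] != p[c]})
                return False, (cell[0], v, bad[0])
    return True, None


def minimal_balanced_coloring(net: NeuronNetwork,
                              respect_weights: bool = True) -> Partition:
    """Coarsest equitable partition by iterated in-neighborhood refinement.

    ``respect_weights=False`` analyses the binary (clamped) adjacency; the
    refinement then counts distinct colored inputs instead of multiplicities.
    Deterministic: nodes are processed in sorted order and colors are
    canonically relabelled each round.
    """
    if net.n == 0:
        raise ValueError("empty network")
    from .graphs import _refinement_colors

    work = net if respect_weights else net.binarized()
    history = _refinement_colors(work, rounds=net.n + 1, weighted=True)
    colors = history[-1]
    cells: Dict[int, List[str]] = {}
    for u in sorted(colors):
        cells.setdefault(colors[u], []).append(u)
    return Partition.from_cells(list(cells.values()))


# ---------------------------------------------------------------------------
# automorphisms


@dataclass
class AutomorphismSet:
    """Generating set of weight-preserving adjacency automorphisms."""

    generators: List[Dict[str, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.generators)

    def __len__(self) -> int:
        return len(self.generators)

    @property
    def identity(self) -> Dict[str, str]:
        return self.generators[0]


def _is_automorphism(net: NeuronNetwork, perm: Mapping[str, str]) -> bool:
    nodes = net.nodes
    if sorted(perm) != nodes or sorted(perm.values()) != nodes:
        return False
    for u in nodes:
        for v, w in net.out_edges(u).items():
            if net.multiplicity(perm[u], perm[v]) != w:
                return False
            if net.sign(u, v) != net.sign(perm[u], perm[v]):
                return False
    return True


def _symmetric_colors(net: NeuronNetwork) -> Dict[str, int]:
    """Automorphism-invariant coloring refined on in- AND out-multisets."""
    colors = {u: 0 for u in net.nodes}
    for _ in range(net.n + 1):
        sigs = {}
        for u in net.nodes:
            ins = tuple(sorted((colors[t], m, net.sign(t, u))
                               for t, m in net.in_edges(u).items()))
            outs = tuple(sorted((colors[h], m, net.sign(u, h))
                                for h, m in net.out_edges(u).items()))
            sigs[u] = (colors[u], ins, outs)
        palette = {s: i for i, s in enumerate(sorted(set(sigs.values())))}
        new = {u: palette[sigs[u]] for u in net.nodes}
        if len(set(new.values())) == len(set(colors.values())):
            return new
        colors = new
    return colors


def _extend(net: NeuronNetwork, order: List[str], colors: Dict[str, int],
            assigned: Dict[str, str], used: set, level: int
            ) -> Optional[Dict[str, str]]:
    """Backtracking completion of a partial automorphism (depth-first)."""
    if level == len(order):
        return dict(assigned)
    u = order[level]
    for cand in order:
        if cand in used or colors[cand] != colors[u]:
            continue
        if net.multiplicity(u, u) != net.multiplicity(cand, cand):
            continue
        ok = True
        for a, img in assigned.items():
            if (net.multiplicity(u, a) != net.multiplicity(cand, img)
                    or net.multiplicity(a, u) != net.multiplicity(img, cand)
                    or net.sign(u, a) != net.sign(cand, img)
                    or net.sign(a, u) != net.sign(img, cand)):
                ok = False
                break
        if not ok:
            continue
        assigned[u] = cand
        used.add(cand)
        full = _extend(net, order, colors, assigned, used, level + 1)
        if full is not None:
            return full
        del assigned[u]
        used.discard(cand)
    return None


def automorphisms(net: NeuronNetwork) -> AutomorphismSet:
    """Generating set of Aut(G) via a stabilizer-chain backtracking search.

    For each node v (in sorted order) and each refinement-compatible target
    u != v, one automorphism fixing all earlier nodes and mapping v -> u is
    sought; the transversal elements so collected generate the full group.
    The identity is always included.  Intended scale is <= 64 nodes.
    """
    if net.n > MAX_AUTOMORPHISM_NODES:
        raise CapabilityError(
            f"automorphism search capped at {MAX_AUTOMORPHISM_NODES} nodes "
            f"(got {net.n})")
    order = net.nodes
    colors = _symmetric_colors(net)
    identity = {u: u for u in order}
    gens: List[Dict[str, str]] = [identity]
    for i, v in enumerate(order):
        for u in order:
            if u == v or colors[u] != colors[v]:
                continue
            assigned = {order[j]: order[j] for j in range(i)}
            if any(assigned.get(x) == u for x in assigned):
                continue
            used = set(list(assigned.values()))
            if u in used:
                continue
            # force v -> u then complete
            ok = True
            for a, img in assigned.items():
                if (net.multiplicity(v, a) != net.multiplicity(u, img)
                        or net.multiplicity(a, v) != net.multiplicity(img, u)):
                    ok = False
                    break
            if not ok or net.multiplicity(v, v) != net.multiplicity(u, u):
                continue
            assigned[v] = u
            used.add(u)
            full = _extend(net, order, colors, assigned, used, i + 1)
            if full is not None:
                gens.append(full)
    return AutomorphismSet(generators=gens)


def orbit_partition(net: NeuronNetwork) -> Partition:
    """Orbits of the automorphism group via union-find over generator images.

    Orbits of the generated group are exactly the connected components of
    the links {w, sigma(w)} over all generators, so no explicit group closure
    is needed.  Always an equitable partition.
    """
    gens = automorphisms(net)
    parent = {u: u for u in net.nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for sigma in gens:
        for w, img in sigma.items():
            union(w, img)
    cells: Dict[str, List[str]] = {}
    for u in net.nodes:
        cells.setdefault(find(u), []).append(u)
    return Partition.from_cells(list(cells.values()))
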