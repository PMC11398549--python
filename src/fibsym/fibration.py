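"""Fibration and group symmetries of directed graphs.

Fibers — classes of the coarsest balanced coloring (equitable partition) — are
computed by iterated refinement on in-neighbor color multisets; nodes in one
fiber have isomorphic input trees and provably synchronize under any dynamics
admissible with the graph.  Automorphisms (global symmetries) are found by a
backtracking search pruned with the fiber partition; their orbits always refine
the fiber partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from fibsym.graphs_io import BaseGraph, NodeColoring, PartitionError, ROIGraph

__all__ = [
    "coarsest_balanced_coloring",
    "is_balanced",
    "BalanceReport",
    "input_tree",
    "InputTree",
    "base_graph",
    "automorphism_group",
    "PermutationGroup",
    "orbits",
]


# ---------------------------------------------------------------------------
# Balanced colorings


def coarsest_balanced_coloring(graph: ROIGraph) -> NodeColoring:
    """Coarsest balanced coloring (minimal equitable partition) of ``graph``.

    Starts from the monochrome coloring and repeatedly splits classes by the
    multiset of in-neighbor colors until a fixed point; the fixed point of
    this refinement is the unique coarsest balanced coloring, i.e. the fiber
    partition of the symmetry fibration.
    """
    if graph.n == 0:
        raise ValueError("empty graph has no coloring")
    color = {v: 0 for v in graph.nodes}
    in_nbrs = {v: graph.in_neighbors(v) for v in graph.nodes}
    while True:
        # signature: (current color, sorted multiset of in-neighbor colors)
        sigs = {
            v: (color[v], tuple(sorted(color[u] for u in in_nbrs[v])))
            for v in graph.nodes
        }
        relabel: dict[tuple, int] = {}
        new_color = {}
        for v in graph.nodes:  # first-seen order keeps ids canonical
            s = sigs[v]
            if s not in relabel:
                relabel[s] = len(relabel)
            new_color[v] = relabel[s]
        if len(relabel) == len(set(color.values())):
            break
        color = new_color
    classes: dict[int, set[str]] = {}
    for v in graph.nodes:
        classes.setdefault(color[v], set()).add(v)
    return NodeColoring.from_classes(classes.values(), graph.nodes)


@dataclass(frozen=True)
class BalanceReport:
    """Verdict of a balance check plus the violating triples.

    Each violation ``(p, q, color)`` names two same-class nodes whose
    in-neighbor counts from ``color`` differ.
    """

    balanced: bool
    violations: tuple[tuple[str, str, int], ...]

    def __bool__(self) -> bool:
        return self.balanced


def is_balanced(graph: ROIGraph, coloring: NodeColoring) -> BalanceReport:
    """Check that same-colored nodes receive identical in-neighbor color counts."""
    if coloring.node_set() != set(graph.nodes):
        raise PartitionError("coloring is over a different node set than the graph")
    cmap = coloring.as_mapping()
    k = coloring.k

    def profile(v: str) -> tuple[int, ...]:
        counts = [0] * k
        for u in graph.in_neighbors(v):
            counts[cmap[u]] += 1
        return tuple(counts)

    violations: list[tuple[str, str, int]] = []
    for cls in coloring.classes:
        members = sorted(cls, key=graph.index)
        ref, ref_profile = members[0], profile(members[0])
        for q in members[1:]:
            qp = profile(q)
            if qp != ref_profile:
                for color in range(k):
                    if qp[color] != ref_profile[color]:
                        violations.append((ref, q, color))
    return BalanceReport(not violations, tuple(violations))


# ---------------------------------------------------------------------------
# Input trees


@dataclass(frozen=True)
class InputTree:
    """Depth-truncated input tree of a node.

    The children of every tree node are the in-neighbors of the corresponding
    graph node; depth-``d`` trees encode all walks of length <= d terminating
    at the root.  ``encoding`` is canonical: child encodings are sorted, so it
    is invariant under child reordering, and two nodes have equal encodings at
    depth |V|-1 iff they lie in the same fiber.
    """

    root: str
    depth: int
    encoding: str


def input_tree(graph: ROIGraph, node: str, depth: int | None = None) -> InputTree:
    """Build the input tree of ``node`` truncated at ``depth`` (default |V|-1)."""
    if node not in graph.nodes:
        raise KeyError(f"unknown node {node!r}")
    if depth is None:
        depth = graph.n - 1
    if depth < 0:
        raise ValueError("depth must be >= 0")
    in_nbrs = {v: graph.in_neighbors(v) for v in graph.nodes}

    # memoized bottom-up: encoding of every node at each level
    enc = {v: "()" for v in graph.nodes}
    for _ in range(depth):
        enc = {v: "(" + "".join(sorted(enc[u] for u in in_nbrs[v])) + ")" for v in graph.nodes}
    return InputTree(node, depth, enc[node])


# ---------------------------------------------------------------------------
# Base graph (quotient)


def base_graph(graph: ROIGraph, coloring: NodeColoring) -> BaseGraph:
    """Collapse each fiber to one node of the base, keeping in-arc multiplicities.

    Requires ``coloring`` to be balanced; multiplicities are then identical for
    every member of a class, and each node's in-degree equals the sum of the
    base in-multiplicities of its class (lifted in-degree conservation).
    """
    report = is_balanced(graph, coloring)
    if not report:
        p, q, color = report.violations[0]
        raise PartitionError(
            f"coloring is not balanced: nodes {p} and {q} receive different "
            f"in-counts from color {color}"
        )
    cmap = coloring.as_mapping()
    mult: dict[tuple[int, int], int] = {}
    for t, cls in enumerate(coloring.classes):
        rep = next(iter(cls))  # any member; balance makes this well-defined
        for u in graph.in_neighbors(rep):
            key = (cmap[u], t)
            mult[key] = mult.get(key, 0) + 1
    return BaseGraph(coloring.classes, mult)


# ---------------------------------------------------------------------------
# Automorphisms and orbits


@dataclass(frozen=True)
class PermutationGroup:
    """Automorphism group given by a generator list (node-label bijections)."""

    generators: tuple[dict[str, str], ...]
    nodes: tuple[str, ...]

    def order(self) -> int:
        """Group order via closure (BFS over generator products)."""
        identity = tuple(self.nodes)

        def apply(perm: dict[str, str], elem: tuple[str, ...]) -> tuple[str, ...]:
            return tuple(perm[x] for x in elem)

        seen = {identity}
        frontier = [identity]
        while frontier:
            nxt = []
            for elem in frontier:
                for g in self.generators:
                    img = apply(g, elem)
                    if img not in seen:
                        seen.add(img)
                        nxt.append(img)
            frontier = nxt
        return len(seen)

    def elements(self) -> list[dict[str, str]]:
        identity = tuple(self.nodes)

        def apply(perm: dict[str, str], elem: tuple[str, ...]) -> tuple[str, ...]:
            return tuple(perm[x] for x in elem)

        seen = {identity}
        frontier = [identity]
        while frontier:
            nxt = []
            for elem in frontier:
                for g in self.generators:
                    img = apply(g, elem)
                    if img not in seen:
                        seen.add(img)
                        nxt.append(img)
            frontier = nxt
        return [dict(zip(self.nodes, elem)) for elem in sorted(seen)]

    def contains(self, perm: dict[str, str]) -> bool:
        target = tuple(perm[x] for x in self.nodes)
        return any(
            tuple(e[x] for x in self.nodes) == target for e in self.elements()
        )


def cycle_notation(perm: dict[str, str]) -> str:
    """Serialize a permutation in cycle notation, e.g. ``(WA_L SMG_L)(WA_R SMG_R)``."""
    seen: set[str] = set()
    cycles = []
    for start in perm:
        if start in seen or perm[start] == start:
            seen.add(start)
            continue
        cyc = [start]
        seen.add(start)
        x = perm[start]
        while x != start:
            cyc.append(x)
            seen.add(x)
            x = perm[x]
        cycles.append("(" + " ".join(cyc) + ")")
    return "".join(cycles) if cycles else "()"


def automorphism_group(graph: ROIGraph, max_nodes: int = 16) -> PermutationGroup:
    """Automorphism group of ``graph`` by pruned backtracking search.

    Candidates for the image of a node are restricted to its fiber (an
    automorphism preserves the coarsest balanced coloring class-wise, since
    orbits refine fibers and the coarsest coloring is canonical), and partial
    maps are rejected as soon as they break adjacency.  All automorphisms are
    enumerated; the non-identity ones are returned as generators.

    The search is exponential in the worst case, hence the ``max_nodes`` cap.
    """
    if graph.n > max_nodes:
        raise ValueError(
            f"automorphism search capped at {max_nodes} nodes (graph has {graph.n}); "
            "raise max_nodes explicitly to override"
        )
    nodes = graph.nodes
    fiber_of = coarsest_balanced_coloring(graph).as_mapping()
    arcset = graph.arcs

    # order nodes to fail fast: large fibers last
    order = sorted(nodes, key=lambda v: (sum(1 for u in nodes if fiber_of[u] == fiber_of[v]), v))

    autos: list[dict[str, str]] = []
    mapping: dict[str, str] = {}
    used: set[str] = set()

    def consistent(v: str, w: str) -> bool:
        for u, img in mapping.items():
            if ((u, v) in arcset) != ((img, w) in arcset):
                return False
            if ((v, u) in arcset) != ((w, img) in arcset):
                return False
        return True

    def backtrack(i: int) -> None:
        if i == len(order):
            autos.append(dict(mapping))
            return
        v = order[i]
        for w in nodes:
            if w in used or fiber_of[w] != fiber_of[v]:
                continue
            if not consistent(v, w):
                continue
            mapping[v] = w
            used.add(w)
            backtrack(i + 1)
            del mapping[v]
            used.discard(w)

    backtrack(0)
    identity = {v: v for v in nodes}
    gens = tuple(a for a in autos if a != identity)
    return PermutationGroup(gens, nodes)


def orbits(group: PermutationGroup, nodes: Sequence[str] | None = None) -> NodeColoring:
    """Orbital partition of the node set under ``group`` (union-find closure)."""
    if nodes is None:
        nodes = group.nodes
    nodeset = set(nodes)
    parent = {v: v for v in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for g in group.generators:
        if set(g) != nodeset or set(g.values()) != nodeset:
            raise ValueError("generator is not a bijection on the node set")
        for v in nodes:
            union(v, g[v])
    classes: dict[str, set[str]] = {}
    for v in nodes:
        classes.setdefault(find(v), set()).add(v)
    return NodeColoring.from_classes(classes.values(), nodes)


def permutation_space(n: int) -> int:
    """Size of the raw search space of node permutations, n!."""
    return math.factorial(n)
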