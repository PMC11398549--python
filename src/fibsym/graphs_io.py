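"""Graph and partition data model, file I/O, and the baseline connectome.

Graphs are simple, unweighted, directed: an anatomically undirected white-matter
track is represented as two opposite arcs, expanded at load time.  Node order is
stable and defines row/column order for every matrix built downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "ROIGraph",
    "NodeColoring",
    "BaseGraph",
    "GraphLoadError",
    "PartitionError",
    "load_edge_list",
    "write_edge_list",
    "baseline_connectome",
    "read_partition",
    "write_partition",
]


class GraphLoadError(ValueError):
    """Raised when an edge-list file violates the graph invariants."""


class PartitionError(ValueError):
    """Raised when a set of classes is not a partition of the node set."""


@dataclass(frozen=True)
class ROIGraph:
    """Labeled simple directed graph of ROIs and tracks.

    Parameters
    ----------
    nodes
        ROI labels in a fixed order; this order defines matrix row/column
        order throughout the package.
    arcs
        Set of ordered ``(source, target)`` pairs.  No self-arcs, no
        duplicates, endpoints must be declared nodes.
    name
        Free-text identifier used in reports.
    """

    nodes: tuple[str, ...]
    arcs: frozenset[tuple[str, str]]
    name: str = ""

    def __post_init__(self) -> None:
        nodeset = set(self.nodes)
        if len(nodeset) != len(self.nodes):
            raise GraphLoadError("duplicate node labels")
        for u, v in self.arcs:
            if u == v:
                raise GraphLoadError(f"self-arc {u}->{v} not allowed")
            if u not in nodeset or v not in nodeset:
                raise GraphLoadError(f"arc {u}->{v} references undeclared node")

    @classmethod
    def from_arcs(
        cls,
        arcs: Iterable[tuple[str, str]],
        nodes: Sequence[str] | None = None,
        name: str = "",
    ) -> "ROIGraph":
        """Build a graph from arcs; node order is first-appearance unless given."""
        arcs = list(arcs)
        if nodes is None:
            seen: dict[str, None] = {}
            for u, v in arcs:
                seen.setdefault(u)
                seen.setdefault(v)
            nodes = list(seen)
        return cls(tuple(nodes), frozenset(arcs), name)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.arcs)

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def in_neighbors(self, node: str) -> list[str]:
        return [u for (u, v) in self.arcs if v == node]

    def in_degree(self, node: str) -> int:
        return sum(1 for (_, v) in self.arcs if v == node)

    def has_arc(self, u: str, v: str) -> bool:
        return (u, v) in self.arcs

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(name=self.name)
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def remove_arcs(self, arcs: Iterable[tuple[str, str]], name: str | None = None) -> "ROIGraph":
        arcs = set(arcs)
        missing = arcs - set(self.arcs)
        if missing:
            raise GraphLoadError(f"cannot remove non-existent arcs: {sorted(missing)}")
        return ROIGraph(self.nodes, self.arcs - arcs, name if name is not None else self.name)

    def add_arcs(self, arcs: Iterable[tuple[str, str]], name: str | None = None) -> "ROIGraph":
        arcs = set(arcs)
        clash = arcs & set(self.arcs)
        if clash:
            raise GraphLoadError(f"cannot add duplicate arcs: {sorted(clash)}")
        return ROIGraph(self.nodes, self.arcs | arcs, name if name is not None else self.name)


@dataclass(frozen=True)
class NodeColoring:
    """Partition of ROIs into color classes (fibers / CS clusters).

    Canonical form: classes sorted by the smallest node index of the owning
    graph's node order; color ids 0..K-1 follow that order.
    """

    classes: tuple[frozenset[str], ...]

    @classmethod
    def from_classes(
        cls, classes: Iterable[Iterable[str]], node_order: Sequence[str] | None = None
    ) -> "NodeColoring":
        sets = [frozenset(c) for c in classes]
        total = sum(len(s) for s in sets)
        union: set[str] = set().union(*sets) if sets else set()
        if total != len(union):
            raise PartitionError("classes overlap or contain duplicates")
        if node_order is not None:
            if union != set(node_order):
                raise PartitionError("classes do not cover the node set exactly")
            pos = {n: i for i, n in enumerate(node_order)}
        else:
            pos = {n: n for n in union}  # lexicographic fallback
        sets.sort(key=lambda s: min(pos[n] for n in s))
        return cls(tuple(sets))

    @property
    def k(self) -> int:
        return len(self.classes)

    def color_of(self, node: str) -> int:
        for i, c in enumerate(self.classes):
            if node in c:
                return i
        raise KeyError(node)

    def node_set(self) -> frozenset[str]:
        return frozenset().union(*self.classes) if self.classes else frozenset()

    def as_mapping(self) -> dict[str, int]:
        return {n: i for i, c in enumerate(self.classes) for n in c}

    def refines(self, other: "NodeColoring") -> bool:
        """True if every class of self lies inside one class of other."""
        return all(any(c <= d for d in other.classes) for c in self.classes)

    def canonical(self, node_order: Sequence[str]) -> "NodeColoring":
        return NodeColoring.from_classes(self.classes, node_order)


@dataclass(frozen=True)
class BaseGraph:
    """Quotient of a graph by a balanced coloring.

    One node per color class; ``multiplicity[(S, T)]`` is the number of
    in-arcs any member of class ``T`` receives from class ``S`` (well-defined
    exactly when the coloring is balanced).
    """

    classes: tuple[frozenset[str], ...]
    multiplicity: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.classes)

    def in_multiplicities(self, target_class: int) -> dict[int, int]:
        return {
            s: m for (s, t), m in self.multiplicity.items() if t == target_class and m > 0
        }


# ---------------------------------------------------------------------------
# Edge-list TSV I/O


def load_edge_list(text: str, name: str = "") -> ROIGraph:
    """Parse an edge-list TSV into an :class:`ROIGraph`.

    Each data row is ``source<TAB>target<TAB>mode`` with mode ``directed`` or
    ``undirected``; undirected rows expand to two opposite arcs.  ``#`` starts
    a comment.  A special comment ``# nodes: a,b,c`` fixes the node order;
    otherwise first-appearance order is used.
    """
    arcs: list[tuple[str, str]] = []
    arcset: set[tuple[str, str]] = set()
    node_order: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("# nodes:"):
            node_order = [t.strip() for t in line[len("# nodes:"):].split(",") if t.strip()]
            continue
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise GraphLoadError(f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}")
        u, v, mode = (p.strip() for p in parts)
        if mode not in ("directed", "undirected"):
            raise GraphLoadError(f"line {lineno}: unknown mode {mode!r}")
        if u == v:
            raise GraphLoadError(f"line {lineno}: self-arc {u}->{v}")
        new = [(u, v)] if mode == "directed" else [(u, v), (v, u)]
        for arc in new:
            if arc in arcset:
                raise GraphLoadError(f"line {lineno}: duplicate arc {arc[0]}->{arc[1]}")
            arcset.add(arc)
            arcs.append(arc)
    return ROIGraph.from_arcs(arcs, nodes=node_order, name=name)


def write_edge_list(graph: ROIGraph) -> str:
    """Serialize a graph to edge-list TSV.

    Opposite arc pairs are merged back into single ``undirected`` rows; the
    node order is preserved in a ``# nodes:`` header so round trips are exact.
    """
    lines = [f"# nodes: {','.join(graph.nodes)}"]
    done: set[tuple[str, str]] = set()
    for u, v in sorted(graph.arcs, key=lambda a: (graph.index(a[0]), graph.index(a[1]))):
        if (u, v) in done:
            continue
        if (v, u) in graph.arcs:
            lines.append(f"{u}\t{v}\tundirected")
            done.add((v, u))
        else:
            lines.append(f"{u}\t{v}\tdirected")
        done.add((u, v))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Baseline connectome fixture

#: Fixed ROI order used for every matrix involving the language network.
BASELINE_NODES: tuple[str, ...] = (
    "SMA",
    "PreMA_L", "PreMA_R",
    "BA_L", "BA_R",
    "SMG_L", "SMG_R",
    "AG_L", "AG_R",
    "WA_L", "WA_R",
)

# Dorsal-stream tracks, per hemisphere X in {L, R}:
#   arcuate fasciculus direct segment        BA_X  -- WA_X
#   arcuate/SLF to inferior parietal         BA_X  -- SMG_X, BA_X -- AG_X
#   arcuate posterior segment                SMG_X -- WA_X
#   superior longitudinal fasciculus         PreMA_X -- SMG_X, PreMA_X -- AG_X
#   dorsal pathway I                         PreMA_X -- WA_X
#   frontal aslant tract                     SMA   -- BA_X
# plus homotopic callosal connections for every bilateral ROI pair and the
# directed premotor -> SMA projections.  This reconstruction is synthetic in
# the sense that no machine-readable edge list is published; it is validated
# by reproducing the known five-fiber/five-orbit symmetry of the network and
# removal-only feasibility of the resting-state and task colorings.
_BASELINE_UNDIRECTED: tuple[tuple[str, str], ...] = tuple(
    [(f"BA_{x}", f"WA_{x}") for x in "LR"]
    + [(f"BA_{x}", f"SMG_{x}") for x in "LR"]
    + [(f"SMG_{x}", f"WA_{x}") for x in "LR"]
    + [(f"BA_{x}", f"AG_{x}") for x in "LR"]
    + [(f"PreMA_{x}", f"SMG_{x}") for x in "LR"]
    + [(f"PreMA_{x}", f"AG_{x}") for x in "LR"]
    + [(f"PreMA_{x}", f"WA_{x}") for x in "LR"]
    + [("SMA", f"BA_{x}") for x in "LR"]
    + [(f"{roi}_L", f"{roi}_R") for roi in ("PreMA", "BA", "AG", "WA", "SMG")]
)

_BASELINE_DIRECTED: tuple[tuple[str, str], ...] = (
    ("PreMA_L", "SMA"),
    ("PreMA_R", "SMA"),
)


def baseline_connectome() -> ROIGraph:
    """The 11-ROI dorsal-stream baseline language connectome.

    Nodes are the dorsal-stream ROIs of the dual-stream model of language
    (supplementary motor area, premotor, Broca, supramarginal, angular and
    Wernicke areas, bilateral except SMA); arcs are the known white-matter
    tracks (AF/SLF system, FAT, dorsal pathway I, homotopic callosal
    connections) with every undirected track expanded to two arcs: 44 arcs
    in total (21 undirected tracks + 2 directed premotor->SMA arcs).
    """
    arcs: list[tuple[str, str]] = []
    for u, v in _BASELINE_UNDIRECTED:
        arcs.append((u, v))
        arcs.append((v, u))
    arcs.extend(_BASELINE_DIRECTED)
    return ROIGraph(BASELINE_NODES, frozenset(arcs), name="dorsal-stream baseline connectome")


#: Target coloring observed in resting state: a pentagonal cluster of
#: {SMA, PreMA, WA} plus bilateral Broca, angular and supramarginal pairs.
RS_COLORING_CLASSES: tuple[tuple[str, ...], ...] = (
    ("SMA", "PreMA_L", "PreMA_R", "WA_L", "WA_R"),
    ("BA_L", "BA_R"),
    ("SMG_L", "SMG_R"),
    ("AG_L", "AG_R"),
)

#: Target coloring observed during the language tasks: Broca left is recruited
#: by SMA, Broca right by the Wernicke pair (lateralization).
TASK_COLORING_CLASSES: tuple[tuple[str, ...], ...] = (
    ("SMA", "BA_L"),
    ("PreMA_L", "PreMA_R"),
    ("BA_R", "WA_L", "WA_R"),
    ("SMG_L", "SMG_R"),
    ("AG_L", "AG_R"),
)


def rs_coloring() -> NodeColoring:
    """Resting-state target coloring on the baseline node order."""
    return NodeColoring.from_classes(RS_COLORING_CLASSES, BASELINE_NODES)


def task_coloring() -> NodeColoring:
    """Language-task target coloring on the baseline node order."""
    return NodeColoring.from_classes(TASK_COLORING_CLASSES, BASELINE_NODES)


# ---------------------------------------------------------------------------
# Partition JSON I/O


def write_partition(coloring: NodeColoring) -> str:
    """Serialize a coloring to partition JSON: ``{"classes": [[...], ...]}``."""
    return json.dumps(
        {"classes": [sorted(c) for c in coloring.classes]}, indent=2, sort_keys=True
    ) + "\n"


def read_partition(text: str, node_order: Sequence[str] | None = None) -> NodeColoring:
    """Parse partition JSON; raises :class:`PartitionError` on overlap/missing nodes."""
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as e:
        raise PartitionError(f"invalid JSON: {e}") from e
    if not isinstance(obj, dict) or "classes" not in obj:
        raise PartitionError("partition JSON must be an object with a 'classes' key")
    return NodeColoring.from_classes(obj["classes"], node_order)
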