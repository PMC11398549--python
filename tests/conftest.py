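import numpy as np
import pytest

from fibsym.graphs_io import NodeColoring, ROIGraph, baseline_connectome


@pytest.fixture(scope="session")
def baseline() -> ROIGraph:
    return baseline_connectome()


def random_digraph(rng: np.random.Generator, n_min: int = 3, n_max: int = 7,
                   p: float | None = None) -> ROIGraph:
    """Random simple digraph with first-appearance node order."""
    n = int(rng.integers(n_min, n_max + 1))
    nodes = [f"v{i}" for i in range(n)]
    if p is None:
        p = float(rng.uniform(0.15, 0.6))
    arcs = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    return ROIGraph.from_arcs(arcs, nodes)


def random_coloring(rng: np.random.Generator, graph: ROIGraph,
                    k_max: int = 3) -> NodeColoring:
    k = int(rng.integers(1, min(k_max, graph.n) + 1))
    assign = {v: int(rng.integers(0, k)) for v in graph.nodes}
    classes: dict[int, set[str]] = {}
    for v, c in assign.items():
        classes.setdefault(c, set()).add(v)
    return NodeColoring.from_classes(classes.values(), graph.nodes)
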