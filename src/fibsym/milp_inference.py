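"""MILP inference of the sub-connectome sustaining a target coloring.

Given a baseline directed graph G = (V, E) and a target coloring S of its
nodes (the cluster-synchronization pattern observed functionally), find the
minimum-cost perturbation of G — removing arcs, optionally also adding
non-arcs — such that S is a balanced coloring of the perturbed graph:

    min  alpha * sum r_ij  +  beta * sum a_ij

subject to, for every same-color pair p, q and every color S*,
equal surviving+added in-arcs into p and q from S* (the balance constraint),
in-degree >= 1 for every node, and — optionally — indicator constraints
(binary s_pq^R with big-M n = |V|) forcing every cross-color pair to be
imbalanced on at least one color, a necessary (not sufficient) condition for
the coloring to be *minimal* balanced.

Removal-only infeasibility is the falsification branch of the structure-
function hypothesis: if no sub-graph of the baseline supports the observed
coloring, the hypothesis that function selects routes from a fixed structural
highway is wrong for that data.

The solver backend is HiGHS via :func:`scipy.optimize.milp` (single-threaded
and deterministic).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from fibsym.graphs_io import NodeColoring, PartitionError, ROIGraph
from fibsym.fibration import coarsest_balanced_coloring, is_balanced, automorphism_group, orbits

__all__ = [
    "MILPProblem",
    "InferenceResult",
    "ValidationReport",
    "build_milp",
    "solve_milp",
    "validate_inference",
    "brute_force_min_removal",
]

REMOVAL_ONLY = "removal_only"
REMOVAL_AND_ADDITION = "removal_and_addition"


@dataclass
class MILPProblem:
    """Assembled MILP instance with its variable index maps.

    ``r_index`` maps each existing arc to its removal variable, ``a_index``
    each orderable non-arc to its addition variable (empty in removal-only
    mode), and ``s_index`` maps (p, q, color) to the imbalance indicators of
    the minimality constraints.
    """

    graph: ROIGraph
    coloring: NodeColoring
    mode: str
    alpha: float
    beta: float
    minimality: bool
    tie_undirected: bool
    r_index: dict[tuple[str, str], int]
    a_index: dict[tuple[str, str], int]
    s_index: dict[tuple[str, str, int], int]
    n_vars: int
    c: np.ndarray
    A: sparse.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    extra_cuts: list[tuple[dict[int, float], float]] = field(default_factory=list)


@dataclass(frozen=True)
class ValidationReport:
    """Post-hoc verification of an inference result."""

    balanced: bool
    coarsest_matches: bool
    coarsest_classes: int
    min_in_degree: int
    orbit_count: int | None
    minimality_caveat: str = (
        "the MILP minimality constraints are necessary but not sufficient; "
        "coarsest_matches is the authoritative check"
    )

    @property
    def ok(self) -> bool:
        return self.balanced and self.coarsest_matches and self.min_in_degree >= 1


@dataclass(frozen=True)
class InferenceResult:
    """Outcome of a MILP solve.

    ``status`` is ``optimal``, ``infeasible`` (the falsification branch in
    removal-only mode) or ``capped`` (solver stopped early; best bound kept).
    """

    status: str
    removed: frozenset[tuple[str, str]]
    added: frozenset[tuple[str, str]]
    objective: float | None
    perturbed: ROIGraph | None
    validation: ValidationReport | None
    solver_message: str = ""


def _in_expr(
    graph: ROIGraph,
    problem_r: dict[tuple[str, str], int],
    problem_a: dict[tuple[str, str], int],
    source_class: frozenset[str],
    target: str,
) -> tuple[dict[int, float], float]:
    """Linear expression for the perturbed in-degree of ``target`` from a class.

    Returns (coeffs keyed by variable index, constant term):
    sum over arcs i->target, i in class, of (1 - r) plus sum of a over
    non-arcs i->target, i in class.
    """
    coeffs: dict[int, float] = {}
    const = 0.0
    for i in source_class:
        if i == target:
            continue
        arc = (i, target)
        if arc in problem_r:
            const += 1.0
            coeffs[problem_r[arc]] = coeffs.get(problem_r[arc], 0.0) - 1.0
        elif arc in problem_a:
            coeffs[problem_a[arc]] = coeffs.get(problem_a[arc], 0.0) + 1.0
    return coeffs, const


def build_milp(
    graph: ROIGraph,
    coloring: NodeColoring,
    mode: str = REMOVAL_ONLY,
    alpha: float = 1.0,
    beta: float = 1.0,
    minimality: bool = True,
    tie_undirected: bool = False,
) -> MILPProblem:
    """Assemble the MILP for a graph and target coloring.

    Parameters
    ----------
    mode
        ``removal_only`` (default, the falsifiable variant) or
        ``removal_and_addition``.
    alpha, beta
        Nonnegative objective weights for removals and additions.
    minimality
        Emit the cross-color imbalance indicator constraints (necessary but
        not sufficient for the coloring to be coarsest).
    tie_undirected
        Force the two directions of an anatomically undirected track to be
        removed (or kept) together.
    """
    if coloring.node_set() != set(graph.nodes):
        raise PartitionError("coloring does not partition the graph's node set")
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be nonnegative")
    if mode not in (REMOVAL_ONLY, REMOVAL_AND_ADDITION):
        raise ValueError(f"unknown mode {mode!r}")

    arcs = sorted(graph.arcs, key=lambda a: (graph.index(a[0]), graph.index(a[1])))
    r_index = {arc: i for i, arc in enumerate(arcs)}
    a_index: dict[tuple[str, str], int] = {}
    if mode == REMOVAL_AND_ADDITION:
        nonedges = [
            (u, v)
            for u in graph.nodes
            for v in graph.nodes
            if u != v and (u, v) not in graph.arcs
        ]
        a_index = {arc: len(r_index) + i for i, arc in enumerate(nonedges)}

    s_index: dict[tuple[str, str, int], int] = {}
    cross_pairs: list[tuple[str, str]] = []
    if minimality:
        base = len(r_index) + len(a_index)
        k = coloring.k
        for si, ci in enumerate(coloring.classes):
            for sj in range(si + 1, k):
                for p in sorted(ci, key=graph.index):
                    for q in sorted(coloring.classes[sj], key=graph.index):
                        cross_pairs.append((p, q))
        for p, q in cross_pairs:
            for color in range(coloring.k):
                s_index[(p, q, color)] = base + len(s_index)
                s_index[(q, p, color)] = base + len(s_index)

    n_vars = len(r_index) + len(a_index) + len(s_index)
    c = np.zeros(n_vars)
    for idx in r_index.values():
        c[idx] = alpha
    for idx in a_index.values():
        c[idx] = beta

    rows: list[dict[int, float]] = []
    lbs: list[float] = []
    ubs: list[float] = []

    def add_row(coeffs: dict[int, float], lo: float, hi: float) -> None:
        rows.append(coeffs)
        lbs.append(lo)
        ubs.append(hi)

    n = graph.n
    # (i) balance: equal in-counts from every class for every same-color pair
    for cls in coloring.classes:
        members = sorted(cls, key=graph.index)
        for p, q in itertools.combinations(members, 2):
            for src in coloring.classes:
                cp, kp = _in_expr(graph, r_index, a_index, src, p)
                cq, kq = _in_expr(graph, r_index, a_index, src, q)
                coeffs = dict(cp)
                for idx, val in cq.items():
                    coeffs[idx] = coeffs.get(idx, 0.0) - val
                if not coeffs and kp != kq:
                    # structurally unequal with no variable to fix it: emit an
                    # infeasible constant row so the solver reports infeasible
                    add_row({0: 0.0}, 1.0, 1.0)
                    continue
                rhs = kq - kp
                add_row(coeffs, rhs, rhs)

    # (ii) in-degree >= 1.  A node with no baseline in-arcs is a free-running
    # source (in removal-only mode it could never satisfy the floor at all),
    # so the constraint protects only nodes whose baseline in-degree is
    # positive; this also keeps the two modes comparable.
    all_nodes_class = frozenset(graph.nodes)
    for p in graph.nodes:
        if graph.in_degree(p) == 0:
            continue
        coeffs, const = _in_expr(graph, r_index, a_index, all_nodes_class, p)
        add_row(coeffs, 1.0 - const, np.inf)

    # (iii) minimality indicators
    if minimality:
        for p, q in cross_pairs:
            for color, src in enumerate(coloring.classes):
                cp, kp = _in_expr(graph, r_index, a_index, src, p)
                cq, kq = _in_expr(graph, r_index, a_index, src, q)
                # in_R(p) - in_R(q) >= s_pqR - n * s_qpR
                coeffs = dict(cp)
                for idx, val in cq.items():
                    coeffs[idx] = coeffs.get(idx, 0.0) - val
                coeffs[s_index[(p, q, color)]] = coeffs.get(s_index[(p, q, color)], 0.0) - 1.0
                coeffs[s_index[(q, p, color)]] = coeffs.get(s_index[(q, p, color)], 0.0) + n
                add_row(coeffs, kq - kp, np.inf)
                # symmetric
                coeffs = dict(cq)
                for idx, val in cp.items():
                    coeffs[idx] = coeffs.get(idx, 0.0) - val
                coeffs[s_index[(q, p, color)]] = coeffs.get(s_index[(q, p, color)], 0.0) - 1.0
                coeffs[s_index[(p, q, color)]] = coeffs.get(s_index[(p, q, color)], 0.0) + n
                add_row(coeffs, kp - kq, np.inf)
                # at most one direction flagged per color
                add_row(
                    {s_index[(p, q, color)]: 1.0, s_index[(q, p, color)]: 1.0}, -np.inf, 1.0
                )
            # at least one color registers an imbalance (reconstructed
            # necessary-minimality constraint)
            coeffs = {}
            for color in range(coloring.k):
                coeffs[s_index[(p, q, color)]] = 1.0
                coeffs[s_index[(q, p, color)]] = 1.0
            add_row(coeffs, 1.0, np.inf)

    if tie_undirected:
        for (u, v), idx in r_index.items():
            if (v, u) in r_index and graph.index(u) < graph.index(v):
                add_row({idx: 1.0, r_index[(v, u)]: -1.0}, 0.0, 0.0)

    data, ri, ci = [], [], []
    for row_idx, coeffs in enumerate(rows):
        for col, val in coeffs.items():
            if val != 0.0:
                ri.append(row_idx)
                ci.append(col)
                data.append(val)
    A = sparse.csr_matrix((data, (ri, ci)), shape=(len(rows), n_vars))
    return MILPProblem(
        graph=graph,
        coloring=coloring,
        mode=mode,
        alpha=alpha,
        beta=beta,
        minimality=minimality,
        tie_undirected=tie_undirected,
        r_index=r_index,
        a_index=a_index,
        s_index=s_index,
        n_vars=n_vars,
        c=c,
        A=A,
        lb=np.array(lbs),
        ub=np.array(ubs),
    )


def _solve_once(problem: MILPProblem, time_limit: float | None):
    rows = [(problem.A, problem.lb, problem.ub)]
    if problem.extra_cuts:
        data, ri, ci, lo, hi = [], [], [], [], []
        for row_idx, (coeffs, lb) in enumerate(problem.extra_cuts):
            for col, val in coeffs.items():
                ri.append(row_idx)
                ci.append(col)
                data.append(val)
            lo.append(lb)
            hi.append(np.inf)
        Acut = sparse.csr_matrix(
            (data, (ri, ci)), shape=(len(problem.extra_cuts), problem.n_vars)
        )
        rows.append((Acut, np.array(lo), np.array(hi)))
    constraints = [LinearConstraint(A, lo, hi) for A, lo, hi in rows]
    options = {"presolve": True}
    if time_limit is not None:
        options["time_limit"] = time_limit
    return milp(
        c=problem.c,
        constraints=constraints,
        integrality=np.ones(problem.n_vars),
        bounds=Bounds(0.0, 1.0),
        options=options,
    )


def solve_milp(
    problem: MILPProblem,
    time_limit: float | None = None,
    max_nogood_retries: int = 5,
    compute_orbits: bool = True,
) -> InferenceResult:
    """Solve the MILP and validate the perturbed graph.

    If the optimum's coloring is balanced but not *coarsest* (the minimality
    indicators are only a necessary condition), a no-good cut excluding the
    incumbent perturbation is added and the solve repeats, up to
    ``max_nogood_retries`` times; the last incumbent is returned either way,
    with the failure recorded in the validation report.
    """
    last: InferenceResult | None = None
    for _ in range(max_nogood_retries + 1):
        res = _solve_once(problem, time_limit)
        if res.status == 2:  # infeasible
            return InferenceResult(
                status="infeasible",
                removed=frozenset(),
                added=frozenset(),
                objective=None,
                perturbed=None,
                validation=None,
                solver_message=(
                    "no removal/addition pattern makes the target coloring "
                    "balanced — in removal-only mode this falsifies the "
                    "hypothesis that the baseline supports the observed "
                    "synchronization; " + str(res.message)
                ),
            )
        if res.status != 0 or res.x is None:
            return InferenceResult(
                status="capped",
                removed=frozenset(),
                added=frozenset(),
                objective=float(res.mip_dual_bound) if hasattr(res, "mip_dual_bound") else None,
                perturbed=None,
                validation=None,
                solver_message=str(res.message),
            )
        x = np.round(res.x).astype(int)
        removed = frozenset(arc for arc, idx in problem.r_index.items() if x[idx] == 1)
        added = frozenset(arc for arc, idx in problem.a_index.items() if x[idx] == 1)
        perturbed = problem.graph.remove_arcs(removed).add_arcs(
            added, name=f"{problem.graph.name} (perturbed)"
        )
        validation = validate_inference(
            problem.graph, perturbed, problem.coloring, compute_orbits=compute_orbits
        )
        objective = problem.alpha * len(removed) + problem.beta * len(added)
        last = InferenceResult(
            status="optimal",
            removed=removed,
            added=added,
            objective=float(objective),
            perturbed=perturbed,
            validation=validation,
            solver_message=str(res.message),
        )
        if validation.coarsest_matches:
            return last
        # exclude this incumbent over the r/a variables and retry
        coeffs: dict[int, float] = {}
        ones = 0
        for idx in list(problem.r_index.values()) + list(problem.a_index.values()):
            if x[idx] == 1:
                coeffs[idx] = -1.0
                ones += 1
            else:
                coeffs[idx] = 1.0
        problem.extra_cuts.append((coeffs, 1.0 - ones))
    return last  # retries exhausted; validation carries the failure


def validate_inference(
    baseline: ROIGraph,
    perturbed: ROIGraph,
    coloring: NodeColoring,
    compute_orbits: bool = True,
) -> ValidationReport:
    """Re-verify a solution outside the solver.

    Checks (a) the target coloring is balanced on the perturbed graph, (b) it
    equals the coarsest balanced coloring (the authoritative minimality
    check), (c) minimum in-degree >= 1, and reports (d) the orbit count of
    the perturbed graph, informational only.
    """
    bal = is_balanced(perturbed, coloring)
    coarsest = coarsest_balanced_coloring(perturbed)
    target = coloring.canonical(perturbed.nodes)
    matches = coarsest.classes == target.classes
    constrained = [v for v in perturbed.nodes if baseline.in_degree(v) > 0]
    min_indeg = min((perturbed.in_degree(v) for v in constrained), default=1)
    orbit_count = None
    if compute_orbits and perturbed.n <= 16:
        orbit_count = orbits(automorphism_group(perturbed)).k
    return ValidationReport(
        balanced=bool(bal),
        coarsest_matches=matches,
        coarsest_classes=coarsest.k,
        min_in_degree=min_indeg,
        orbit_count=orbit_count,
    )


def brute_force_min_removal(
    graph: ROIGraph,
    coloring: NodeColoring,
    max_arcs: int = 16,
) -> list[frozenset[tuple[str, str]]]:
    """All minimum-size removal sets making the coloring balanced (oracle).

    Exhaustively enumerates removal subsets in increasing size, keeping those
    for which the perturbed graph is balanced under the coloring with
    in-degree >= 1 everywhere.  Exponential in |E|, hence the cap; used to
    certify MILP optima and probe optimum uniqueness on small instances.
    """
    if graph.m > max_arcs:
        raise ValueError(
            f"brute force capped at {max_arcs} arcs (graph has {graph.m})"
        )
    arcs = sorted(graph.arcs)
    # in-degree filter applies only to nodes that had in-arcs to begin with
    # (removal cannot help a baseline source node)
    constrained = [v for v in graph.nodes if graph.in_degree(v) > 0]
    for k in range(graph.m + 1):
        winners = []
        for subset in itertools.combinations(arcs, k):
            g2 = graph.remove_arcs(subset)
            if any(g2.in_degree(v) == 0 for v in constrained):
                continue
            if is_balanced(g2, coloring):
                winners.append(frozenset(subset))
        if winners:
            return winners
    return []
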