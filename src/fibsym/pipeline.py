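"""Pipeline orchestration: series -> PLV -> CS -> MILP -> symmetry report.

Every stage of the structure-from-function analysis is an ordinary library
call; this module chains them, writes each stage's artifact, and summarizes
the symmetry change between the baseline connectome and the inferred network
(the symmetry-breaking read-out: fiber and orbit counts before and after).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from fibsym.graphs_io import (
    NodeColoring,
    ROIGraph,
    baseline_connectome,
    load_edge_list,
    read_partition,
    write_edge_list,
    write_partition,
)
from fibsym.fibration import (
    automorphism_group,
    coarsest_balanced_coloring,
    cycle_notation,
    orbits,
)
from fibsym.milp_inference import (
    REMOVAL_ONLY,
    InferenceResult,
    build_milp,
    solve_milp,
)
from fibsym.synchrony import (
    PLVMatrix,
    cs_to_coloring,
    detect_cs,
    group_average,
    instantaneous_phase,
    plv_matrix,
    surrogate_pvalues,
)

__all__ = ["PipelineConfig", "SymmetryReport", "run_pipeline", "render_report"]

log = logging.getLogger("fibsym")


@dataclass
class PipelineConfig:
    """Configuration of a full run; defaults mirror the target fMRI regime.

    Exactly one of ``series_paths`` (per-subject time-series CSVs) or
    ``target_partition_path`` (a printed coloring, skipping the PLV stages)
    must be given.  ``baseline_path`` empty means the packaged dorsal-stream
    connectome.
    """

    baseline_path: str = ""
    series_paths: list[str] = field(default_factory=list)
    target_partition_path: str = ""
    band: tuple[float, float] | None = (0.01, 0.1)
    tr: float = 2.5
    n_perm: int = 1000
    run_surrogates: bool = False
    alpha_sig: float = 0.05
    milp_mode: str = REMOVAL_ONLY
    alpha: float = 1.0
    beta: float = 1.0
    minimality: bool = True
    seed: int = 0
    out_dir: str = "fibsym_out"

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(text) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            if key == "band" and val is not None:
                val = (float(val[0]), float(val[1]))
            setattr(cfg, key, val)
        return cfg


@dataclass
class SymmetryReport:
    """Fiber/orbit structure of each analyzed network plus the deltas."""

    networks: dict[str, dict[str, Any]]
    deltas: dict[str, Any]
    inference: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "networks": self.networks,
            "deltas": self.deltas,
            "inference": self.inference,
        }


def analyze_symmetry(graph: ROIGraph) -> dict[str, Any]:
    """Fibers, orbits and automorphism generators of one network."""
    fibers = coarsest_balanced_coloring(graph)
    group = automorphism_group(graph)
    orb = orbits(group)
    return {
        "name": graph.name,
        "n_nodes": graph.n,
        "n_arcs": graph.m,
        "fiber_count": fibers.k,
        "fibers": [sorted(c) for c in fibers.classes],
        "orbit_count": orb.k,
        "orbits": [sorted(c) for c in orb.classes],
        "automorphism_generators": sorted(
            cycle_notation(g) for g in group.generators
        ),
        "group_order": group.order(),
    }


def _coloring_from_series(
    cfg: PipelineConfig, out: Path
) -> tuple[NodeColoring, PLVMatrix]:
    mats = []
    labels: tuple[str, ...] | None = None
    for path in cfg.series_paths:
        df = pd.read_csv(path)
        if labels is None:
            labels = tuple(df.columns)
        elif tuple(df.columns) != labels:
            raise ValueError(f"ROI labels in {path} differ from the first subject")
        ps = instantaneous_phase(df.values, labels, dt=cfg.tr, band=cfg.band)
        mats.append(plv_matrix(ps))
        if cfg.run_surrogates:
            res = surrogate_pvalues(
                df.values, labels, dt=cfg.tr, n_perm=cfg.n_perm,
                seed=cfg.seed, band=cfg.band, alpha=cfg.alpha_sig,
            )
            n_sig = sum(res.significant.values())
            log.info("%s: %d/%d pairs significant (max-statistic)", path,
                     n_sig, len(res.significant))
    avg = group_average(mats)
    pd.DataFrame(avg.values, index=list(avg.labels), columns=list(avg.labels)).to_csv(
        out / "plv_group_average.csv"
    )
    cs = detect_cs(avg)
    (out / "clusters.json").write_text(
        json.dumps(
            {
                "cliques": [sorted(c) for c in cs.cliques],
                "cluster_plv": list(cs.cluster_plvs),
                "singletons": sorted(cs.singletons),
            },
            indent=2,
        )
    )
    return cs_to_coloring(cs, avg.labels), avg


def run_pipeline(cfg: PipelineConfig) -> SymmetryReport:
    """Execute the configured stages and write every artifact to ``out_dir``.

    Stages: load series -> phases -> per-subject PLV -> group average ->
    (optional) surrogate mask -> CS detection -> coloring -> MILP inference
    against the baseline -> validation -> symmetry report.  A run starting
    from a printed target coloring skips the PLV stages.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("seed=%d out=%s", cfg.seed, out)

    stage = "load baseline"
    try:
        if cfg.baseline_path:
            baseline = load_edge_list(
                Path(cfg.baseline_path).read_text(), name=cfg.baseline_path
            )
        else:
            baseline = baseline_connectome()

        stage = "target coloring"
        if cfg.target_partition_path:
            coloring = read_partition(
                Path(cfg.target_partition_path).read_text(), baseline.nodes
            )
        elif cfg.series_paths:
            coloring, _ = _coloring_from_series(cfg, out)
        else:
            raise ValueError("config must provide series_paths or target_partition_path")
        (out / "target_partition.json").write_text(write_partition(coloring))

        stage = "milp inference"
        problem = build_milp(
            baseline,
            coloring,
            mode=cfg.milp_mode,
            alpha=cfg.alpha,
            beta=cfg.beta,
            minimality=cfg.minimality,
        )
        result = solve_milp(problem)
        _write_inference(out, baseline, result)
        if result.status != "optimal":
            raise RuntimeError(
                f"MILP returned {result.status}: {result.solver_message}"
            )

        stage = "symmetry analysis"
        nets = {
            "baseline": analyze_symmetry(baseline),
            "inferred": analyze_symmetry(result.perturbed),
        }
    except Exception as exc:  # noqa: BLE001 — re-raise with stage context
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    deltas = _symmetry_deltas(nets["baseline"], nets["inferred"])
    inference = {
        "status": result.status,
        "objective": result.objective,
        "n_removed": len(result.removed),
        "n_added": len(result.added),
        "validation": {
            "balanced": result.validation.balanced,
            "coarsest_matches": result.validation.coarsest_matches,
            "coarsest_classes": result.validation.coarsest_classes,
            "min_in_degree": result.validation.min_in_degree,
            "orbit_count": result.validation.orbit_count,
        },
    }
    report = SymmetryReport(networks=nets, deltas=deltas, inference=inference)
    (out / "report.json").write_text(render_report(report, "json"))
    (out / "report.txt").write_text(render_report(report, "text"))
    return report


def _symmetry_deltas(base: dict[str, Any], inf: dict[str, Any]) -> dict[str, Any]:
    return {
        "fiber_count_change": inf["fiber_count"] - base["fiber_count"],
        "orbit_count_change": inf["orbit_count"] - base["orbit_count"],
        "fibration_broken": inf["fiber_count"] > base["fiber_count"],
        "fibration_enhanced": inf["fiber_count"] < base["fiber_count"],
        "group_broken": inf["orbit_count"] > base["orbit_count"],
        "group_equals_fibration_baseline": base["fibers"] == base["orbits"],
        "group_equals_fibration_inferred": inf["fibers"] == inf["orbits"],
    }


def _write_inference(out: Path, baseline: ROIGraph, result: InferenceResult) -> None:
    lines = [f"{u}\t{v}" for u, v in sorted(result.removed)]
    (out / "removed_arcs.tsv").write_text("\n".join(lines) + ("\n" if lines else ""))
    lines = [f"{u}\t{v}" for u, v in sorted(result.added)]
    (out / "added_arcs.tsv").write_text("\n".join(lines) + ("\n" if lines else ""))
    if result.perturbed is not None:
        (out / "perturbed_graph.tsv").write_text(write_edge_list(result.perturbed))
    if result.validation is not None:
        (out / "validation.json").write_text(
            json.dumps(
                {
                    "status": result.status,
                    "objective": result.objective,
                    "balanced": result.validation.balanced,
                    "coarsest_matches": result.validation.coarsest_matches,
                    "coarsest_classes": result.validation.coarsest_classes,
                    "min_in_degree": result.validation.min_in_degree,
                    "orbit_count": result.validation.orbit_count,
                    "minimality_caveat": result.validation.minimality_caveat,
                },
                indent=2,
                sort_keys=True,
            )
        )


def render_report(report: SymmetryReport, fmt: str = "text") -> str:
    """Deterministic serialization of a symmetry report (text or JSON)."""
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    if fmt != "text":
        raise ValueError(f"unknown format {fmt!r}")
    lines = ["Symmetry report", "==============="]
    for name in sorted(report.networks):
        net = report.networks[name]
        lines += [
            "",
            f"[{name}] {net['name']} ({net['n_nodes']} nodes, {net['n_arcs']} arcs)",
            f"  fibers ({net['fiber_count']}): "
            + "; ".join(",".join(c) for c in net["fibers"]),
            f"  orbits ({net['orbit_count']}): "
            + "; ".join(",".join(c) for c in net["orbits"]),
            f"  automorphism group order: {net['group_order']}",
        ]
        if net["fibers"] == net["orbits"]:
            lines.append("  group symmetry = fibration symmetry")
    if report.deltas:
        lines += ["", "Deltas (baseline -> inferred)"]
        for key in sorted(report.deltas):
            lines.append(f"  {key}: {report.deltas[key]}")
    if report.inference:
        lines += [
            "",
            "Inference",
            f"  status: {report.inference.get('status')}",
            f"  objective: {report.inference.get('objective')}",
            f"  removed: {report.inference.get('n_removed')}"
            f"  added: {report.inference.get('n_added')}",
        ]
    return "\n".join(lines) + "\n"
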