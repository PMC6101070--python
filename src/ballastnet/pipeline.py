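"""End-to-end orchestration: simulate/ingest -> risk -> graph -> score -> trigger.

Stages run in a fixed order, each persisting its artifact to the output
directory before the next starts, so a failed run leaves everything up
to the failing stage on disk:

========  ==================  =========================================
stage     artifact            contents
========  ==================  =========================================
simulate  ports.csv,          synthetic world (when configured)
          ais.csv,
          ballast.csv,
          truth_voyages.csv
ingest    routes.csv          one row per extracted voyage
risk      route_risks.csv     source, dest, p_inv, n_voyages, distance
graph     sin.graphml         the species invasion network
score     shells.csv          s-shell index and threshold per port
trigger   report.csv,         ranked composite-risk report + manifest
          manifest.json
========  ==================  =========================================

The same configuration and seed always produce byte-identical artifacts.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import ingest as ing
from .ingest import (DEFAULT_IN_PORT_STATUSES, DEFAULT_MIN_DWELL_HOURS,
                     DEFAULT_RADIUS_KM, DEFAULT_VOLUME_M3, Port, Voyage)
from .risk import RiskKernelParams, RouteRisk, route_invasion_risk
from .score import (DecompositionParams, ShellAssignment, s_core_decompose,
                    weighted_out_degree)
from .sin import build_sin, invaded_risks_from_sin, write_sin
from .trigger import TriggerParams, trigger_report
from .world import WorldSpec, generate_ais_stream, generate_ports, generate_voyages

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "PipelineStageError", "run_pipeline",
           "compute_route_risks", "write_route_risks_csv", "read_route_risks_csv"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it, ``__cause__`` says why."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Everything one run needs.  Either ``world`` (simulate inputs) or
    the three input paths (``ais_path``, ``ports_path``, optionally
    ``ballast_path``) must be given.  ``seed``, when set, overrides the
    world spec's seed so one knob drives a fully deterministic run."""

    out_dir: str
    world: WorldSpec | None = None
    ais_path: str | None = None
    ports_path: str | None = None
    ballast_path: str | None = None
    kernel: RiskKernelParams = field(default_factory=RiskKernelParams)
    decomposition: DecompositionParams = field(default_factory=DecompositionParams)
    trigger: TriggerParams = field(default_factory=TriggerParams)
    radius_km: float = DEFAULT_RADIUS_KM
    min_dwell_hours: float = DEFAULT_MIN_DWELL_HOURS
    in_port_statuses: frozenset[int] = DEFAULT_IN_PORT_STATUSES
    default_volume_m3: float = DEFAULT_VOLUME_M3
    top_n: int = 100
    normalization: str = "minmax"
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.world is None and (self.ais_path is None or self.ports_path is None):
            raise ValueError("need either a world spec or ais_path + ports_path")
        if self.world is not None and self.seed is not None:
            object.__setattr__(self, "world",
                               dataclasses.replace(self.world, seed=self.seed))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML mapping; nested blocks
        ``world``, ``kernel``, ``decomposition``, ``trigger`` map onto
        their parameter dataclasses."""
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = dict(raw)
        for key, typ in (("world", WorldSpec), ("kernel", RiskKernelParams),
                         ("decomposition", DecompositionParams),
                         ("trigger", TriggerParams)):
            if kwargs.get(key) is not None:
                kwargs[key] = typ(**kwargs[key])
        if "in_port_statuses" in kwargs:
            kwargs["in_port_statuses"] = frozenset(int(s) for s
                                                   in kwargs["in_port_statuses"])
        return cls(**kwargs)

    def to_jsonable(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["in_port_statuses"] = sorted(self.in_port_statuses)
        return d


@dataclass
class PipelineResult:
    report: pd.DataFrame
    ranked: pd.DataFrame
    graph: Any
    shells: ShellAssignment
    invaded_risks: dict[str, float]
    voyages: list[Voyage]
    route_risks: list[RouteRisk]
    out_dir: Path


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def compute_route_risks(
    voyages, ports: Mapping[str, Port], kernel: RiskKernelParams
) -> list[RouteRisk]:
    routes = ing.aggregate_routes(voyages, ports)
    return [route_invasion_risk(r, ports[r.source_port], ports[r.dest_port], kernel)
            for r in routes]


def write_route_risks_csv(route_risks, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "dest", "p_inv", "n_voyages", "distance_km"])
        for rr in route_risks:
            w.writerow([rr.source_port, rr.dest_port, repr(rr.p_inv),
                        rr.n_voyages, repr(rr.distance_km)])


def read_route_risks_csv(path) -> list[RouteRisk]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(RouteRisk(row["source"], row["dest"], float(row["p_inv"]),
                                 (), int(row["n_voyages"]),
                                 float(row["distance_km"])))
    return out


def _write_shells_csv(graph, shells: ShellAssignment,
                      params: DecompositionParams, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["port_id", "shell_index", "s_threshold",
                    "out_degree", "weighted_out_degree"])
        for pid in sorted(shells.shell_of):
            k = shells.shell_of[pid]
            w.writerow([pid, k, repr(shells.thresholds[k]),
                        graph.out_degree(pid),
                        repr(weighted_out_degree(graph, pid, params))])


def _write_report_csv(report: pd.DataFrame, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(report.columns.tolist())
        for row in report.itertuples(index=False):
            w.writerow([repr(v) if isinstance(v, float) else v for v in row])


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage, persisting artifacts to ``config.out_dir``.

    Raises :class:`PipelineStageError` naming the failing stage; partial
    outputs from completed stages are left in place for debugging.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digests: dict[str, str] = {}
    counts: dict[str, int] = {}

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineStageError(name, exc) from exc
                logger.info("stage %s: done", name)
        return _Ctx()

    with _stage("simulate" if config.world else "load"):
        if config.world is not None:
            ports = generate_ports(config.world)
            truth, ballast = generate_voyages(ports, config.world)
            ais = generate_ais_stream(truth, ports, config.world)
            ing.write_ports_csv(ports, out / "ports.csv")
            ing.write_ballast_csv(ballast, out / "ballast.csv")
            ing.write_ais_csv(ais, out / "ais.csv")
            ing.write_voyages_csv(truth, out / "truth_voyages.csv")
            for f in ("ports.csv", "ballast.csv", "ais.csv"):
                digests[f] = _digest(out / f)
        else:
            ports = ing.read_ports_csv(config.ports_path)
            ais = ing.parse_ais_records(config.ais_path)
            ballast = (ing.read_ballast_csv(config.ballast_path)
                       if config.ballast_path else [])
            for label, p in (("ports", config.ports_path), ("ais", config.ais_path),
                             ("ballast", config.ballast_path)):
                if p:
                    digests[label] = _digest(Path(p))
        counts["ais_records"] = len(ais)
        counts["ports"] = len(ports)

    with _stage("ingest"):
        calls = ing.detect_port_calls(ais, ports, config.radius_km,
                                      config.min_dwell_hours,
                                      config.in_port_statuses)
        voyages = ing.build_voyages(calls, ballast, config.default_volume_m3)
        ing.write_voyages_csv(voyages, out / "routes.csv")
        counts["port_calls"] = len(calls)
        counts["voyages"] = len(voyages)

    with _stage("risk"):
        route_risks = compute_route_risks(voyages, ports, config.kernel)
        write_route_risks_csv(route_risks, out / "route_risks.csv")
        counts["routes"] = len(route_risks)

    with _stage("graph"):
        graph = build_sin(ports, route_risks)
        write_sin(graph, out / "sin.graphml", format="graphml")
        invaded = invaded_risks_from_sin(graph)
        counts["sin_edges"] = graph.number_of_edges()

    with _stage("score"):
        shells = s_core_decompose(graph, config.decomposition)
        _write_shells_csv(graph, shells, config.decomposition, out / "shells.csv")
        counts["shells"] = shells.n_shells

    with _stage("trigger"):
        report, ranked = trigger_report(ports, invaded, shells, config.trigger,
                                        config.top_n, config.normalization)
        _write_report_csv(report, out / "report.csv")
        manifest = {
            "config": config.to_jsonable(),
            "input_digests": digests,
            "row_counts": counts,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(report, ranked, graph, shells, invaded,
                          voyages, route_risks, out)
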