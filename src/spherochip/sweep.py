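"""Full-factorial sweep orchestration.

Each (geometry, flow scenario) pair is an independent, deterministic job:
build the voxel grid, solve steady flow, march the drug transport, reduce
to the five design metrics.  Jobs run in parallel worker processes with no
shared state, so results are bit-identical for any worker count; records
are persisted per design under the output root and a manifest tracks
completion so an interrupted sweep resumes where it stopped.

The whole pipeline contains no random number generation; a ``seed`` key is
accepted in sweep configs but unused (reserved).
"""

from __future__ import annotations

import json
import traceback
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import SolverOptions
from .design_space import DesignPoint, FactorTable, enumerate_designs
from .flow import FlowBC, FlowField, FluidProperties, SpheroidProperties, solve_flow
from .geometry import DomainGrid, GeometryConfig, build_domain
from .metrics import (DesignMatrix, METRIC_NAMES, build_design_matrix,
                      classify_transport_mode, compute_metrics)
from .transport import ConcentrationHistory, TransportProperties, solve_transport

#: Named flow scenarios: (q1, q2) in ml/h.
SCENARIOS = {"equal": (0.01, 0.01), "unequal": (0.02, 0.01)}


def default_checkpoints(t_end_s: float, every_s: float = 600.0) -> list[float]:
    n = max(1, int(round(t_end_s / every_s)))
    return [every_s * k for k in range(1, n + 1) if every_s * k <= t_end_s + 1e-9]


def simulate_design(design: DesignPoint, geom: GeometryConfig | None = None,
                    solver: SolverOptions | None = None,
                    fluid: FluidProperties | None = None,
                    props: TransportProperties | None = None,
                    ) -> tuple[DomainGrid, FlowField, ConcentrationHistory]:
    """One end-to-end run: grid, steady flow, transport history."""
    solver = solver or SolverOptions()
    fluid = fluid or FluidProperties()
    props = props or TransportProperties()
    grid = build_domain(design, geom, spacing_um=solver.resolution_um)
    bc = FlowBC(q1_ml_h=0.0 if design.topology == "SSC" else design.q1,
                q2_ml_h=design.q2)
    flow = solve_flow(grid, fluid, SpheroidProperties(porosity=design.phi),
                      bc, tol=solver.tolerance)
    history = solve_transport(
        grid, flow, props, t_end_s=solver.t_end_s, dt_s=solver.dt_s,
        checkpoints_s=default_checkpoints(solver.t_end_s, solver.checkpoint_every_s),
        bc=bc)
    return grid, flow, history


@dataclass
class SweepConfig:
    table: FactorTable
    geom: GeometryConfig = field(default_factory=GeometryConfig)
    solver: SolverOptions = field(default_factory=SolverOptions)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    props: TransportProperties = field(default_factory=TransportProperties)
    scenarios: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SCENARIOS))
    workers: int = 1
    out_root: Path = Path("sweep_out")
    subset: slice | None = None   # slice of the geometry list
    seed: int | None = None       # reserved; the pipeline is deterministic

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("worker count must be >= 1")
        self.out_root = Path(self.out_root)


def geometry_list(table: FactorTable) -> list[DesignPoint]:
    """Unique geometry/porosity combinations (flow rates stripped), in
    enumeration order."""
    seen, out = set(), []
    for d in enumerate_designs(table):
        if d.name not in seen:
            seen.add(d.name)
            out.append(d)
    return out


def _record_key(name: str, scenario: str) -> str:
    return f"{name}@{scenario}"


def _run_one(args) -> tuple[str, dict]:
    """Worker entry: simulate one (geometry, scenario) job; never raises."""
    (design_kw, scenario, q1, q2, geom, solver, fluid, props) = args
    design = DesignPoint(**{**design_kw, "q1": q1, "q2": q2})
    key = _record_key(design.name, scenario)
    try:
        grid, flow, history = simulate_design(design, geom, solver, fluid, props)
        mv = compute_metrics(grid, flow, history, props)
        record = {
            "status": "complete",
            "name": design.name,
            "scenario": scenario,
            "q1_ml_h": q1 if design.topology == "DSC" else 0.0,
            "q2_ml_h": q2,
            "topology": design.topology,
            "metrics": mv.as_dict(),
            "mode": classify_transport_mode(mv).value,
            "flow_residual": flow.residual,
            "core_trace": {
                "t_s": history.probe_times[::60].tolist(),
                "c_mol_m3": history.probes["core"][::60].tolist(),
            },
        }
    except Exception as exc:  # per-design failures are recorded, not fatal
        record = {"status": "failed", "name": design.name, "scenario": scenario,
                  "error": f"{type(exc).__name__}: {exc}",
                  "traceback": traceback.format_exc()}
    return key, record


@dataclass
class ResultStore:
    """Per-design records on disk, keyed by design name + flow scenario."""

    root: Path

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        self.root.mkdir(parents=True, exist_ok=True)

    @property
    def manifest_path(self) -> Path:
        return self.root / "manifest.json"

    def manifest(self) -> dict[str, str]:
        if self.manifest_path.exists():
            return json.loads(self.manifest_path.read_text())
        return {}

    def _write_manifest(self, m: dict[str, str]) -> None:
        self.manifest_path.write_text(json.dumps(m, indent=1, sort_keys=True))

    def record_path(self, key: str) -> Path:
        return self.root / key / "record.json"

    def load(self, key: str) -> dict:
        return json.loads(self.record_path(key).read_text())

    def is_complete(self, key: str) -> bool:
        p = self.record_path(key)
        return p.exists() and json.loads(p.read_text()).get("status") == "complete"

    def save(self, key: str, record: dict) -> None:
        p = self.record_path(key)
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(record, indent=1, sort_keys=True))
        m = self.manifest()
        m[key] = record.get("status", "failed")
        self._write_manifest(m)

    def completed_keys(self) -> list[str]:
        return sorted(k for k, v in self.manifest().items() if v == "complete")


def run_sweep(config: SweepConfig, force: bool = False) -> ResultStore:
    """Run every (geometry, scenario) job of the configured subset.

    Completed records are skipped unless ``force``; failures are logged in
    the store and do not abort the sweep.
    """
    store = ResultStore(config.out_root)
    geoms = geometry_list(config.table)
    if config.subset is not None:
        geoms = geoms[config.subset]

    jobs = []
    for g in geoms:
        for scen, (q1, q2) in config.scenarios.items():
            key = _record_key(g.name, scen)
            if not force and store.is_complete(key):
                continue
            design_kw = {"wl": g.wl, "wr": g.wr, "hl": g.hl, "hr": g.hr,
                         "radius": g.radius, "phi": g.phi}
            jobs.append((design_kw, scen, q1, q2, config.geom, config.solver,
                         config.fluid, config.props))

    if config.workers == 1:
        results = map(_run_one, jobs)
        for key, record in results:
            store.save(key, record)
    else:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            for key, record in pool.map(_run_one, jobs):
                store.save(key, record)
    return store


def collect(store: ResultStore, scenario: str,
            evaluation: str | float = "window") -> DesignMatrix:
    """Assemble the raw metric matrix of one scenario, in enumeration order."""
    keys = [k for k in store.completed_keys() if k.endswith(f"@{scenario}")]
    if not keys:
        raise ValueError(f"no complete records for scenario {scenario!r}")
    rows, names = [], []
    for k in keys:
        rec = store.load(k)
        names.append(rec["name"])
        rows.append([rec["metrics"][m] for m in METRIC_NAMES])
    raw = pd.DataFrame(rows, index=pd.Index(names, name="name"),
                       columns=list(METRIC_NAMES)).sort_index()
    return build_design_matrix(raw, scenario=scenario, evaluation=evaluation)


def results_table(store: ResultStore, scenario: str) -> pd.DataFrame:
    """Flat results CSV content: factors, raw + normalized metrics, mode."""
    dm = collect(store, scenario)
    recs = {}
    for k in store.completed_keys():
        if k.endswith(f"@{scenario}"):
            r = store.load(k)
            recs[r["name"]] = r
    rows = []
    for name in dm.raw.index:
        r = recs[name]
        row = {"name": name, "scenario": scenario,
               "q1_ml_h": r["q1_ml_h"], "q2_ml_h": r["q2_ml_h"],
               "topology": r["topology"], "mode": r["mode"]}
        row.update({m: dm.raw.loc[name, m] for m in METRIC_NAMES})
        row.update({f"{m}_norm": dm.normalized.loc[name, m] for m in METRIC_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
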