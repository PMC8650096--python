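"""Design metrics, transport-mode classification and clustered heatmaps.

Each simulated design is reduced to five volume-averaged quantities over
the spheroid region — concentration, velocity magnitude, shear rate,
advective-flux magnitude and diffusive-flux magnitude.  The flow
quantities are steady; the concentration and flux metrics are averaged
over the perfusion window (trapezoidal rule over the stored checkpoints),
which characterizes the whole uptake transient.  Evaluating them instead
at a single instant is supported (``evaluation=<seconds>``) but is
degenerate at long horizons: with no reaction the drug field saturates at
the inlet concentration and every concentration gradient — hence the
diffusive flux — decays to zero.

A transport mode is *dominant* when the volume-averaged flux of one mode
is at least ten times the other; otherwise the scenario is mixed.  Metrics
are min-max normalized per column across the design space and the designs
hierarchically clustered (Euclidean distance, complete/farthest-point
linkage) to build the design heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .flow import FlowField, FluidProperties, shear_rate_field
from .geometry import DomainGrid, Region
from .transport import ConcentrationHistory, TransportProperties, flux_fields

METRIC_NAMES = ("concentration", "velocity", "shear_rate",
                "advective_flux", "diffusive_flux")

#: Flux ratio at or above which one transport mode is declared dominant.
DOMINANCE_RATIO = 10.0


class TransportMode(str, Enum):
    ADVECTION_DOMINANT = "ADVECTION_DOMINANT"
    DIFFUSION_DOMINANT = "DIFFUSION_DOMINANT"
    MIXED = "MIXED"


@dataclass(frozen=True)
class MetricVector:
    """The five spheroid-averaged metrics (SI units)."""

    concentration: float    # mol/m^3
    velocity: float         # m/s
    shear_rate: float       # 1/s
    advective_flux: float   # mol/m^2/s
    diffusive_flux: float   # mol/m^2/s

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


@dataclass
class LinkageTree:
    """Agglomerative merge list (scipy linkage format) and heatmap row order."""

    merges: np.ndarray      # (n-1, 4): left, right, height, size
    leaf_order: list[int]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class DesignMatrix:
    """Designs x five metrics, raw and min-max normalized."""

    raw: pd.DataFrame          # index: design names; columns: METRIC_NAMES
    normalized: pd.DataFrame
    scenario: str = "equal"
    evaluation: str | float = "window"


def volume_average(field: np.ndarray, grid: DomainGrid,
                   label: Region | int) -> float:
    """Mean of ``field`` over the voxels of one region (volume weighting is
    uniform on the isotropic grid)."""
    mask = grid.region_mask(label)
    if not np.any(mask):
        raise ValueError(f"region {Region(label).name} is empty")
    return float(field[mask].mean())


def compute_metrics(grid: DomainGrid, flow: FlowField,
                    history: ConcentrationHistory, props: TransportProperties,
                    evaluation: str | float = "window",
                    fluid: FluidProperties | None = None) -> MetricVector:
    """Reduce one run to its five spheroid-averaged metrics.

    ``evaluation="window"`` evaluates the concentration and flux metrics on
    the time-averaged concentration field of the whole perfusion window
    (accumulated at every step): exact window averages for the
    concentration and advective flux, and the flux of the mean field for
    the diffusive entry.  A float evaluates them at the checkpoint nearest
    that time instead.
    """
    speed = volume_average(flow.speed(), grid, Region.SPHEROID)
    shear = volume_average(shear_rate_field(flow, fluid), grid, Region.SPHEROID)

    def instant(c_field: np.ndarray) -> tuple[float, float, float]:
        fx = flux_fields(c_field, flow, props)
        return (volume_average(c_field, grid, Region.SPHEROID),
                volume_average(np.linalg.norm(fx.advective, axis=-1), grid, Region.SPHEROID),
                volume_average(np.linalg.norm(fx.diffusive, axis=-1), grid, Region.SPHEROID))

    if evaluation == "window":
        conc, adv, dif = instant(history.mean_field())
    else:
        if not isinstance(evaluation, (int, float)):
            raise ValueError(f"unknown evaluation policy {evaluation!r}")
        conc, adv, dif = instant(history.field_at(float(evaluation)))

    return MetricVector(concentration=conc, velocity=speed, shear_rate=shear,
                        advective_flux=adv, diffusive_flux=dif)


def classify_transport_mode(metrics: MetricVector,
                            ratio: float = DOMINANCE_RATIO) -> TransportMode:
    """Dominant mode when one volume-averaged flux is >= ``ratio`` times the
    other (boundary inclusive); otherwise MIXED."""
    adv, dif = metrics.advective_flux, metrics.diffusive_flux
    if adv < 0 or dif < 0:
        raise ValueError("flux magnitudes must be non-negative")
    if adv == 0.0 and dif == 0.0:
        raise ValueError("transport mode undefined: both fluxes are zero")
    if dif == 0.0 or (dif > 0 and adv / dif >= ratio):
        return TransportMode.ADVECTION_DOMINANT
    if adv == 0.0 or dif / adv >= ratio:
        return TransportMode.DIFFUSION_DOMINANT
    return TransportMode.MIXED


def minmax_normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-column (x - min)/(max - min); constant columns map to all zeros."""
    if len(raw) < 1:
        raise ValueError("need at least one row")
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    span = hi - lo
    out = (raw - lo).div(span.where(span > 0, 1.0), axis=1)
    out.loc[:, span <= 0] = 0.0
    return out


def build_design_matrix(raw: pd.DataFrame, scenario: str = "equal",
                        evaluation: str | float = "window") -> DesignMatrix:
    return DesignMatrix(raw=raw, normalized=minmax_normalize(raw),
                        scenario=scenario, evaluation=evaluation)


def cluster_designs(matrix: DesignMatrix | pd.DataFrame) -> LinkageTree:
    """Complete-linkage (farthest point) agglomerative clustering of the
    normalized rows under the Euclidean metric."""
    X = matrix.normalized if isinstance(matrix, DesignMatrix) else matrix
    if len(X) < 2:
        raise ValueError("clustering needs at least two designs")
    Z = hierarchy.linkage(np.asarray(X, dtype=float), method="complete",
                          metric="euclidean")
    order = hierarchy.leaves_list(Z).tolist()
    return LinkageTree(merges=Z, leaf_order=order)


def heatmap_export(matrix: DesignMatrix, tree: LinkageTree,
                   out_prefix: str | Path) -> dict[str, Path]:
    """Write the clustered heatmap artifacts.

    ``<prefix>_matrix.csv`` — normalized metrics in clustered row order
    (shortest round-trip float representation); ``<prefix>_merges.csv`` —
    the agglomerative merge list; ``<prefix>_heatmap.png`` — the raster
    design heatmap.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ordered = matrix.normalized.iloc[tree.leaf_order]

    paths = {"matrix": out_prefix.with_name(out_prefix.name + "_matrix.csv"),
             "merges": out_prefix.with_name(out_prefix.name + "_merges.csv"),
             "heatmap": out_prefix.with_name(out_prefix.name + "_heatmap.png")}
    ordered.to_csv(paths["matrix"])  # default shortest-repr floats round-trip
    pd.DataFrame({
        "step": np.arange(len(tree.merges)),
        "left": tree.merges[:, 0].astype(int),
        "right": tree.merges[:, 1].astype(int),
        "height": tree.merges[:, 2],
        "size": tree.merges[:, 3].astype(int),
    }).to_csv(paths["merges"], index=False)

    fig_h = max(2.0, 0.25 * len(ordered) + 1.5)
    fig, ax = plt.subplots(figsize=(6, fig_h))
    sns.heatmap(ordered, ax=ax, cmap="viridis", vmin=0.0, vmax=1.0,
                yticklabels=True, cbar_kws={"label": "normalized metric"})
    ax.set_title(f"design heatmap ({matrix.scenario} flow rates)")
    fig.tight_layout()
    fig.savefig(paths["heatmap"], dpi=120)
    plt.close(fig)
    return paths


def design_query(raw_a: pd.DataFrame, raw_b: pd.DataFrame, metric: str,
                 min_change: float, max_other_change: float = 1.5) -> list[str]:
    """Geometries whose ``metric`` changes by >= ``min_change`` (fold) between
    two flow scenarios while every other metric changes by <= the tolerance
    fold.  Rows are matched on the design-name index."""
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}")
    common = raw_a.index.intersection(raw_b.index)
    hits = []
    tiny = 1e-300
    for name in common:
        a, b = raw_a.loc[name], raw_b.loc[name]
        fold = {m: max(a[m], b[m], tiny) / max(min(a[m], b[m]), tiny)
                for m in METRIC_NAMES}
        if fold[metric] >= min_change and all(
                fold[m] <= max_other_change for m in METRIC_NAMES if m != metric):
            hits.append(str(name))
    return hits
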