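"""Voxelized unit-cell geometry of the spheroid-on-a-chip device.

The simulated domain is one *unit cell* of the microwell row: a segment of
each supply channel (running along x), the rectangular connector duct(s)
(along y), the cylindrical microwell (axis along z) and the porous spheroid
centred inside it.  A row of many wells is the same cell repeated along x,
so (by Stokes linearity) channel pressure drops simply chain.

Coordinates: x along the channels, y across the device, z the chip height.
Config lengths are micrometres; the grid stores SI internally only where a
physical measure is returned.  Cells are labelled by the region containing
their centre; everything not painted is SOLID (PDMS/glass).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .design_space import DesignPoint

UM = 1e-6  # metres per micrometre


class Region(IntEnum):
    SOLID = 0
    CHANNEL_L = 1
    CHANNEL_R = 2
    CONNECTOR_L = 3
    CONNECTOR_R = 4
    WELL = 5
    SPHEROID = 6


#: Regions carrying fluid (open or porous).
FLUID_REGIONS = frozenset({Region.CHANNEL_L, Region.CHANNEL_R, Region.CONNECTOR_L,
                           Region.CONNECTOR_R, Region.WELL, Region.SPHEROID})


class ResolutionError(ValueError):
    """The voxel spacing cannot resolve an open connector."""


@dataclass(frozen=True)
class GeometryConfig:
    """Fixed device dimensions (um) shared by every design.

    The well is a vertical cylinder spanning the chip height; the spheroid
    (diameter 100 um) sits at its centre.  Values are consistent with
    droplet-array spheroid chips of this class and are all overridable.
    """

    channel_width_um: float = 200.0
    channel_height_um: float = 100.0
    connector_length_um: float = 100.0
    well_depth_um: float = 100.0
    spheroid_diameter_um: float = 100.0
    spheroid_center_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit_cell_pitch_um: float = 400.0
    n_wells_row: int = 50

    def __post_init__(self) -> None:
        if self.well_depth_um > self.channel_height_um:
            raise ValueError("well depth cannot exceed the chip (channel) height")


@dataclass
class DomainGrid:
    """Isotropic voxel grid with per-cell region labels."""

    spacing_um: float
    labels: np.ndarray           # uint8, shape (nx, ny, nz)
    origin_um: tuple[float, float, float]
    design: DesignPoint | None = None
    geom: GeometryConfig | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def spacing_m(self) -> float:
        return self.spacing_um * UM

    @property
    def cell_volume_m3(self) -> float:
        return self.spacing_m ** 3

    @property
    def solid(self) -> np.ndarray:
        return self.labels == Region.SOLID

    @property
    def fluid(self) -> np.ndarray:
        return self.labels != Region.SOLID

    @property
    def porous(self) -> np.ndarray:
        return self.labels == Region.SPHEROID

    def region_mask(self, label: Region | int) -> np.ndarray:
        label = Region(label)  # raises on unknown label
        return self.labels == label

    def cell_centers_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h = self.spacing_um
        ox, oy, oz = self.origin_um
        nx, ny, nz = self.shape
        x = ox + (np.arange(nx) + 0.5) * h
        y = oy + (np.arange(ny) + 0.5) * h
        z = oz + (np.arange(nz) + 0.5) * h
        return x, y, z

    @property
    def spheroid_center_um(self) -> tuple[float, float, float]:
        if self.geom is None or self.design is None:
            raise ValueError("synthetic grid has no device geometry attached")
        g, d = self.geom, self.design
        xc = g.unit_cell_pitch_um / 2.0
        yc = g.channel_width_um + g.connector_length_um + d.radius
        zc = g.well_depth_um / 2.0
        off = g.spheroid_center_offset_um
        return (xc + off[0], yc + off[1], zc + off[2])

    def cell_index_at_um(self, point_um: tuple[float, float, float]) -> tuple[int, int, int]:
        h = self.spacing_um
        idx = tuple(int(np.clip((p - o) / h, 0, n - 1))
                    for p, o, n in zip(point_um, self.origin_um, self.shape))
        return idx  # type: ignore[return-value]


def _n_cells(length_um: float, spacing_um: float) -> int:
    n = int(round(length_um / spacing_um))
    if n < 1:
        raise ResolutionError(f"extent {length_um} um below one voxel at {spacing_um} um")
    return n


def build_domain(design: DesignPoint, geom: GeometryConfig | None = None,
                 spacing_um: float = 10.0) -> DomainGrid:
    """Voxelize the unit cell of one design.

    Layout across y: [left channel | left connector | well block (2R) |
    right connector | right channel]; for SSC designs the left channel and
    connector are absent (solid).  Open connectors must span at least two
    voxels in both cross-section directions.
    """
    geom = geom or GeometryConfig()
    d = design
    ssc = d.topology == "SSC"

    open_dims = [d.wr, d.hr] + ([] if ssc else [d.wl, d.hl])
    smallest = min(open_dims)
    if spacing_um > smallest / 2.0:
        raise ResolutionError(
            f"spacing {spacing_um} um cannot resolve a {smallest} um connector; "
            f"need spacing <= {smallest / 2.0} um")

    cw, cl = geom.channel_width_um, geom.connector_length_um
    Lx = geom.unit_cell_pitch_um
    Ly = 2 * cw + 2 * cl + 2 * d.radius
    Lz = geom.channel_height_um
    nx, ny, nz = (_n_cells(L, spacing_um) for L in (Lx, Ly, Lz))

    h = spacing_um
    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    z = (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)

    # supply channels (full x, full chip height)
    if not ssc:
        labels[(Y < cw)] = Region.CHANNEL_L
    labels[(Y > Ly - cw)] = Region.CHANNEL_R

    # connector ducts: W across x, H about channel mid-height, reaching the
    # well centre so the duct meets the curved chamber wall for every W, R
    yc_well = cw + cl + d.radius
    zmid = geom.channel_height_um / 2.0

    def paint_connector(w_um: float, h_um: float, y_lo: float, y_hi: float,
                        label: Region) -> None:
        box = ((np.abs(X - Lx / 2.0) < w_um / 2.0)
               & (Y >= y_lo) & (Y < y_hi)
               & (np.abs(Z - zmid) < h_um / 2.0))
        labels[box] = label

    if not ssc:
        paint_connector(d.wl, d.hl, cw, yc_well, Region.CONNECTOR_L)
    paint_connector(d.wr, d.hr, yc_well, Ly - cw, Region.CONNECTOR_R)

    # cylindrical microwell (axis z, spanning the well depth from the floor)
    r2 = (X - Lx / 2.0) ** 2 + (Y - yc_well) ** 2
    well = (r2 < d.radius ** 2) & (Z < geom.well_depth_um)
    labels[well] = Region.WELL

    # porous spheroid
    sx, sy, sz = (Lx / 2.0 + geom.spheroid_center_offset_um[0],
                  yc_well + geom.spheroid_center_offset_um[1],
                  geom.well_depth_um / 2.0 + geom.spheroid_center_offset_um[2])
    a = geom.spheroid_diameter_um / 2.0
    sphere = ((X - sx) ** 2 + (Y - sy) ** 2 + (Z - sz) ** 2) < a ** 2
    labels[sphere & well] = Region.SPHEROID

    grid = DomainGrid(spacing_um=spacing_um, labels=labels,
                      origin_um=(0.0, 0.0, 0.0), design=design, geom=geom)

    for lab, w_um, h_um in ((Region.CONNECTOR_R, d.wr, d.hr),) + (
            () if ssc else ((Region.CONNECTOR_L, d.wl, d.hl),)):
        if not np.any(labels == lab):
            raise ResolutionError(
                f"{lab.name} ({w_um}x{h_um} um) vanished at {spacing_um} um spacing")
    return grid


def region_measure(grid: DomainGrid, label: Region | int) -> float:
    """Volume (m^3) of all voxels carrying ``label``; 0 for absent regions."""
    return float(np.count_nonzero(grid.region_mask(label))) * grid.cell_volume_m3


def duct_grid(length_um: float = 200.0, width_um: float = 200.0,
              height_um: float = 100.0, spacing_um: float = 5.0) -> DomainGrid:
    """Synthetic straight rectangular duct (validation geometry).

    The whole box is one open channel along x; inlet at x = 0, outlet at
    x = length.  Used by the duct-flow oracle.
    """
    nx, ny, nz = (_n_cells(L, spacing_um) for L in (length_um, width_um, height_um))
    labels = np.full((nx, ny, nz), int(Region.CHANNEL_R), dtype=np.uint8)
    return DomainGrid(spacing_um=spacing_um, labels=labels,
                      origin_um=(0.0, 0.0, 0.0), design=None, geom=None)


def closed_box_grid(shape: tuple[int, int, int], spacing_um: float,
                    labels: np.ndarray | None = None) -> DomainGrid:
    """Synthetic sealed box (no channels): all-wall boundaries.

    With ``labels`` omitted every cell is open WELL fluid.  Used by the
    no-flow equilibrium and diffusion-into-a-sphere oracles.
    """
    if labels is None:
        labels = np.full(shape, int(Region.WELL), dtype=np.uint8)
    return DomainGrid(spacing_um=spacing_um, labels=labels.astype(np.uint8),
                      origin_um=(0.0, 0.0, 0.0), design=None, geom=None)
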