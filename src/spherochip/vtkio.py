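"""Minimal legacy-VTK writer for structured voxel grids.

Writes ASCII ``STRUCTURED_POINTS`` files with cell data (scalars and
vectors), enough for ParaView/VisIt inspection of labels, pressure,
velocity, shear rate and concentration fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import DomainGrid


def write_vtk(path: str | Path, grid: DomainGrid,
              scalars: dict[str, np.ndarray] | None = None,
              vectors: dict[str, np.ndarray] | None = None) -> Path:
    """Write the grid labels plus optional cell fields to ``path`` (.vtk)."""
    scalars = dict(scalars or {})
    vectors = dict(vectors or {})
    scalars.setdefault("region", grid.labels.astype(np.int32))

    nx, ny, nz = grid.shape
    h = grid.spacing_um
    lines = [
        "# vtk DataFile Version 3.0",
        "spherochip unit cell",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        f"ORIGIN {grid.origin_um[0]} {grid.origin_um[1]} {grid.origin_um[2]}",
        f"SPACING {h} {h} {h}",
        f"CELL_DATA {nx * ny * nz}",
    ]

    def flat(a: np.ndarray) -> np.ndarray:
        # VTK expects x fastest: transpose (nx,ny,nz) -> (nz,ny,nx) then ravel
        return np.ascontiguousarray(np.transpose(a, (2, 1, 0))).reshape(a.shape[2], -1)

    for name, a in scalars.items():
        if a.shape != grid.shape:
            raise ValueError(f"scalar field {name!r} shape {a.shape} != grid {grid.shape}")
        dtype = "int" if np.issubdtype(a.dtype, np.integer) else "float"
        lines.append(f"SCALARS {name} {dtype} 1")
        lines.append("LOOKUP_TABLE default")
        for row in flat(a):
            lines.append(" ".join(format(v, ".9g") for v in row))
    for name, a in vectors.items():
        if a.shape != grid.shape + (3,):
            raise ValueError(f"vector field {name!r} shape {a.shape} incompatible")
        lines.append(f"VECTORS {name} float")
        comps = np.stack([np.transpose(a[..., i], (2, 1, 0)).ravel() for i in range(3)], axis=1)
        for v in comps:
            lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")

    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
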