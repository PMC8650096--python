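"""Configuration loading and defaults.

A single YAML file with sections ``factors/geometry/fluid/spheroid/drug/
solver/sweep`` configures a run; every field has a default so an empty file
is a valid configuration.  ``config_dump`` prints the fully resolved
defaults.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml


def default_factor_file() -> Path:
    """Path of the shipped factor-level table."""
    return Path(importlib.resources.files("spherochip") / "data" / "table1.yaml")


@dataclass
class SolverOptions:
    """Numerical knobs shared by the flow and transport solvers."""

    resolution_um: float = 10.0      # isotropic voxel size
    tolerance: float = 1e-4          # required relative residual drop
    dt_s: float = 1.0                # transport time step (backward Euler)
    t_end_s: float = 7200.0          # perfusion horizon (120 min)
    checkpoint_every_s: float = 600.0


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Read a YAML run configuration; missing sections resolve to defaults."""
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    return raw


def resolved_defaults() -> dict[str, Any]:
    """Every tunable default of the pipeline, as one nested dict."""
    from .flow import FluidProperties, SpheroidProperties
    from .geometry import GeometryConfig
    from .transport import TransportProperties

    with open(default_factor_file()) as fh:
        factors = yaml.safe_load(fh)
    return {
        "factors": factors,
        "geometry": asdict(GeometryConfig()),
        "fluid": asdict(FluidProperties()),
        "spheroid": {"cell_grain_diameter_um": SpheroidProperties.GRAIN_D_UM},
        "drug": asdict(TransportProperties()),
        "solver": asdict(SolverOptions()),
        "sweep": {"workers": 1, "subset": None, "seed": None},
    }


def config_dump() -> str:
    return yaml.safe_dump(resolved_defaults(), sort_keys=False)
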