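"""Full-factorial design space for the spheroid-on-a-chip device.

Eight factors span the space: the two supply flow rates (Q1 left, Q2 right),
the left/right connector widths and heights (WL, WR, HL, HR), the microwell
chamber radius R and the spheroid porosity phi.  A left connector at the
"closed" sentinel level (0.1 um, far below continuum resolution) marks the
single-supply-channel (SSC) topology; every other combination is a
double-supply-channel (DSC) device.

Geometry and porosity of a design are encoded in a compact name of the form
``P<p>.Wr<w>.R<r>.Hr<h>.Wl<w>.Hl<h>`` where the porosity contributes its
first decimal digit and each length its value in tens of micrometres (the
closed sentinel encodes as 0).  Flow rates are not part of the name; they
select the flow *scenario* (equal, ``Q1 = 2*Q2``, ...) applied to a geometry.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

#: Sentinel level (um) meaning "left connector closed" -> SSC topology.
CLOSED_SENTINEL_UM = 0.1

_FACTOR_NAMES = ("q1", "q2", "wl", "wr", "hl", "hr", "radius", "phi")

#: Enumeration order (slowest-varying first).
_ENUM_ORDER = ("phi", "radius", "wr", "hr", "wl", "hl", "q1", "q2")

#: Segment order of the design name.
_NAME_FIELDS = (("P", "phi"), ("Wr", "wr"), ("R", "radius"),
                ("Hr", "hr"), ("Wl", "wl"), ("Hl", "hl"))


class InvalidFactorTableError(ValueError):
    """A factor level list is empty, unordered, or out of range."""


class NameCodecError(ValueError):
    """A design name cannot be encoded or decoded."""


@dataclass(frozen=True)
class FactorTable:
    """Levels per factor. Lengths in um, flow rates in ml/h, phi dimensionless."""

    q1: tuple[float, ...]
    q2: tuple[float, ...]
    wl: tuple[float, ...]
    wr: tuple[float, ...]
    hl: tuple[float, ...]
    hr: tuple[float, ...]
    radius: tuple[float, ...]
    phi: tuple[float, ...]

    def __post_init__(self) -> None:
        for f in fields(self):
            levels = tuple(float(v) for v in getattr(self, f.name))
            object.__setattr__(self, f.name, levels)
            if len(levels) == 0:
                raise InvalidFactorTableError(f"factor {f.name!r}: empty level list")
            if any(v <= 0 for v in levels):
                raise InvalidFactorTableError(f"factor {f.name!r}: levels must be positive")
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise InvalidFactorTableError(
                    f"factor {f.name!r}: levels must be strictly increasing")
        if any(not (0.0 < v < 1.0) for v in self.phi):
            raise InvalidFactorTableError("porosity levels must lie strictly in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FactorTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        missing = [k for k in _FACTOR_NAMES if k not in raw]
        if missing:
            raise InvalidFactorTableError(f"factor file missing keys: {missing}")
        return cls(**{k: tuple(raw[k]) for k in _FACTOR_NAMES})

    @classmethod
    def default(cls) -> "FactorTable":
        """The shipped device-study factor table (19,200 combinations)."""
        from .config import default_factor_file
        return cls.from_yaml(default_factor_file())

    def n_designs(self) -> int:
        n = 1
        for f in _FACTOR_NAMES:
            n *= len(getattr(self, f))
        return n


@dataclass(frozen=True)
class DesignPoint:
    """One point of the design space (lengths um, flow rates ml/h)."""

    q1: float
    q2: float
    wl: float
    wr: float
    hl: float
    hr: float
    radius: float
    phi: float

    def __post_init__(self) -> None:
        for name in ("q1", "q2", "wl", "wr", "hl", "hr", "radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.phi < 1.0):
            raise ValueError("porosity must lie strictly in (0, 1)")

    @property
    def topology(self) -> str:
        """``"SSC"`` when the left connector is at the closed sentinel level."""
        closed = (self.wl == CLOSED_SENTINEL_UM or self.hl == CLOSED_SENTINEL_UM)
        return "SSC" if closed else "DSC"

    @property
    def name(self) -> str:
        return encode_name(self)


def enumerate_designs(table: FactorTable) -> list[DesignPoint]:
    """Cartesian product of all factor levels, in deterministic order.

    Ordering is lexicographic over (phi, radius, wr, hr, wl, hl, q1, q2) so
    repeated sweeps schedule designs identically.
    """
    axes = [getattr(table, f) for f in _ENUM_ORDER]
    out = []
    for combo in itertools.product(*axes):
        kw = dict(zip(_ENUM_ORDER, combo))
        out.append(DesignPoint(**kw))
    return out


def _encode_length(um: float, segment: str) -> int:
    if um == CLOSED_SENTINEL_UM:
        return 0
    tens = um / 10.0
    if abs(tens - round(tens)) > 1e-9 or not (1 <= round(tens) <= 99):
        raise NameCodecError(f"{segment}={um} um is not encodable in tens of um")
    return int(round(tens))


def encode_name(design: DesignPoint) -> str:
    """Compact geometry/porosity token, e.g. ``P9.Wr6.R8.Hr6.Wl6.Hl2``."""
    parts = []
    for prefix, field in _NAME_FIELDS:
        if field == "phi":
            digit = design.phi * 10.0
            if abs(digit - round(digit)) > 1e-9 or not (1 <= round(digit) <= 9):
                raise NameCodecError(
                    f"porosity {design.phi} is not a single-decimal-digit level")
            parts.append(f"{prefix}{int(round(digit))}")
        else:
            parts.append(f"{prefix}{_encode_length(getattr(design, field), prefix)}")
    return ".".join(parts)


_NAME_RE = re.compile(
    r"^P(\d)\.Wr(\d+)\.R(\d+)\.Hr(\d+)\.Wl(\d+)\.Hl(\d+)$")


def decode_name(name: str, q1: float = 0.01, q2: float = 0.01) -> DesignPoint:
    """Inverse of :func:`encode_name`; flow rates are supplied separately.

    A 0 digit in the Wl/Hl segments restores the closed sentinel (SSC).
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        # locate the first malformed segment for the error message
        segs = name.strip().split(".")
        expected = [p for p, _ in _NAME_FIELDS]
        for i, prefix in enumerate(expected):
            if i >= len(segs) or not re.fullmatch(prefix + r"\d+", segs[i]):
                bad = segs[i] if i < len(segs) else "<missing>"
                raise NameCodecError(
                    f"malformed design name {name!r}: segment {i} {bad!r} "
                    f"(expected {prefix}<digits>)")
        raise NameCodecError(f"malformed design name {name!r}")
    p, wr, r, hr, wl, hl = (int(g) for g in m.groups())
    if p == 0:
        raise NameCodecError("porosity digit 0 is not a valid level")

    def length(tens: int) -> float:
        return CLOSED_SENTINEL_UM if tens == 0 else 10.0 * tens

    return DesignPoint(q1=q1, q2=q2, wl=length(wl), wr=length(wr),
                       hl=length(hl), hr=length(hr),
                       radius=length(r), phi=p / 10.0)


def designs_to_frame(designs: Iterable[DesignPoint]) -> pd.DataFrame:
    """Manifest table: one row per design."""
    rows = [{
        "name": d.name, "phi": d.phi, "radius_um": d.radius,
        "wl_um": d.wl, "wr_um": d.wr, "hl_um": d.hl, "hr_um": d.hr,
        "q1_ml_h": d.q1, "q2_ml_h": d.q2, "topology": d.topology,
    } for d in designs]
    return pd.DataFrame(rows)


def export_manifest(designs: Sequence[DesignPoint], path: str | Path) -> None:
    designs_to_frame(designs).to_csv(path, index=False)
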