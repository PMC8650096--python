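"""Closed-form reference solutions.

Two classical results are used throughout the package: the Fourier-series
velocity profile of fully developed laminar flow in a rectangular duct
(imposed at channel inlets and used as a solver oracle), and the series
solution for transient diffusion into a sphere whose surface is held at a
constant concentration (a transport oracle).
"""

from __future__ import annotations

import numpy as np


def duct_profile(y: np.ndarray, z: np.ndarray, width: float, height: float,
                 n_terms: int = 51) -> np.ndarray:
    """Fully developed axial velocity shape in a ``width x height`` duct.

    ``y`` in [0, width], ``z`` in [0, height]; broadcastable arrays.  The
    returned profile solves ``mu * lap(u) = -G`` with ``u = 0`` on the walls
    for an arbitrary positive constant ``G/mu`` — scale it to a target flow
    rate with :func:`duct_velocity` or by discrete renormalization.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    a, b = float(width), float(height)
    u = np.zeros(np.broadcast(y, z).shape)
    zc = z - b / 2.0
    for n in range(1, 2 * n_terms, 2):
        k = n * np.pi / a
        u = u + (1.0 / n**3) * (1.0 - np.cosh(k * zc) / np.cosh(k * b / 2.0)) \
            * np.sin(k * y)
    return u


def duct_flow_factor(width: float, height: float, n_terms: int = 51) -> float:
    """Integral of :func:`duct_profile` over the cross-section."""
    a, b = float(width), float(height)
    s = 0.0
    for n in range(1, 2 * n_terms, 2):
        k = n * np.pi / a
        s += (1.0 / n**3) * (2.0 * a / (n * np.pi)) * (b - 2.0 * np.tanh(k * b / 2.0) / k)
    return s


def duct_velocity(y: np.ndarray, z: np.ndarray, width: float, height: float,
                  flow_rate: float, n_terms: int = 51) -> np.ndarray:
    """Fully developed duct velocity (same units as flow_rate/area) carrying
    ``flow_rate`` through the ``width x height`` cross-section."""
    shape = duct_profile(y, z, width, height, n_terms)
    return shape * (flow_rate / duct_flow_factor(width, height, n_terms))


def sphere_dirichlet_concentration(r: np.ndarray | float, t: float, radius: float,
                                   diffusivity: float, surface_value: float = 1.0,
                                   n_terms: int = 200) -> np.ndarray | float:
    """Transient diffusion into a sphere with surface held at ``surface_value``.

    Initial interior concentration is zero.  At the centre the series reduces
    to ``c0 * (1 + 2 * sum((-1)^n exp(-n^2 pi^2 D t / a^2)))``.
    """
    a, D = float(radius), float(diffusivity)
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    out = np.ones_like(r_arr)
    n = np.arange(1, n_terms + 1)
    decay = np.exp(-(n * np.pi / a) ** 2 * D * t)
    center = r_arr < 1e-12 * a
    if np.any(center):
        out[center] = 1.0 + 2.0 * np.sum((-1.0) ** n * decay)
    rr = r_arr[~center]
    if rr.size:
        terms = ((-1.0) ** n / n)[None, :] * np.sin(np.outer(rr, n) * np.pi / a) \
            * decay[None, :]
        out[~center] = 1.0 + (2.0 * a / (np.pi * rr)) * terms.sum(axis=1)
    out = surface_value * out
    return out if np.ndim(r) else float(out[0])
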