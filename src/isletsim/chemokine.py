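"""Steady-state chemokine field of cancer-cell point sources.

Live cancer cells secrete a chemokine at rate gamma; treating each cell
as a point source and solving the steady-state diffusion equation in the
plane gives the superposed logarithmic (2-D Green's function) kernel

    c(r) = - sum_j  gamma_j / (2 pi D_c) * log ||r - r_j||,

whose gradient points toward every source with the 1/distance law.  The
kernel is singular at a source, so distances are clamped from below by a
regularisation radius ``r_min`` (default: the T-cell radius), which
bounds the chemotactic drift at contact.  Only the gradient enters the
T-cell motion; the field itself is exposed for inspection and raster
export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChemokineSources", "concentration", "gradient", "raster"]


@dataclass
class ChemokineSources:
    """Point sources (live cancer cells) of the chemokine field."""

    positions: np.ndarray               # (n, 2), um
    gamma: float = 10.0                 # secretion rate, 1/min
    D_c: float = 0.001                  # chemokine diffusivity, um^2/min
    r_min: float = 2.0                  # regularisation distance, um

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if self.r_min <= 0:
            raise ValueError("r_min must be strictly positive")

    @property
    def strength(self) -> float:
        """Per-source kernel prefactor gamma / (2 pi D_c)."""
        return self.gamma / (2.0 * np.pi * self.D_c)


def _distances(x: np.ndarray, sources: ChemokineSources) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    pts = np.atleast_2d(x)
    delta = pts[:, None, :] - sources.positions[None, :, :]     # (m, n, 2)
    dist = np.linalg.norm(delta, axis=-1)                       # (m, n)
    return delta, dist


def concentration(x: np.ndarray, sources: ChemokineSources) -> float | np.ndarray:
    """Chemokine concentration at point(s) ``x`` (arbitrary units).

    Additive over sources; zero when there are none.  Accepts a single
    2-vector or an (m, 2) array of query points.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if sources.positions.shape[0] == 0:
        return 0.0 if single else np.zeros(np.atleast_2d(x).shape[0])
    _, dist = _distances(x, sources)
    c = -sources.strength * np.log(np.maximum(dist, sources.r_min)).sum(axis=-1)
    return float(c[0]) if single else c


def gradient(x: np.ndarray, sources: ChemokineSources) -> np.ndarray:
    """Analytic gradient of the concentration at point(s) ``x``, 1/um units.

    For a single source the gradient is gamma/(2 pi D_c) * (r_j - x)/d^2:
    it points toward the source and its magnitude follows the 1/d law,
    clamped below ``r_min``.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if sources.positions.shape[0] == 0:
        return np.zeros(2) if single else np.zeros(np.atleast_2d(x).shape)
    delta, dist = _distances(x, sources)
    d_eff = np.maximum(dist, sources.r_min)
    g = -sources.strength * (delta / d_eff[..., None] ** 2).sum(axis=1)
    return g[0] if single else g


def raster(sources: ChemokineSources, extent: float, n: int = 101) -> np.ndarray:
    """Sample the field on an n x n grid over [-extent, extent]^2 (for export)."""
    axis = np.linspace(-extent, extent, n)
    xx, yy = np.meshgrid(axis, axis)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return np.asarray(concentration(pts, sources)).reshape(n, n)
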