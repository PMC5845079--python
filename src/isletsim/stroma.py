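"""Anisotropic stromal collagen layer around the islet.

The desmoplastic stroma is an annulus of thickness ~15 um around the
islet whose collagen fibers run parallel to the islet boundary.  A
T cell entering the annulus keeps its tangential motion but its radial
(inward) motion is attenuated exponentially with penetration depth s:

    v_radial = v0 exp(-k s),

where k >= 0 measures the fiber-induced anisotropy (k = 0: isotropic
tissue).  The effect is encoded in a symmetric 2x2 orientation tensor

    Psi(x) = v0 e^{-ks} lambda1 w1 w1^T + v0 lambda2 w2 w2^T,

whose eigenvectors w1, w2 are the local radial and tangential unit
directions.  Outside the annulus, and inside the islet proper (fibers
exist only in the annulus), Psi reduces to v0 times the identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["StromaGeometry", "penetration_depth", "radial_speed", "orientation_tensor"]


@dataclass(frozen=True)
class StromaGeometry:
    """Annular stroma: centre, inner (islet) radius, thickness, anisotropy."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    islet_radius: float = 35.0   # um, inner boundary of the annulus
    thickness: float = 15.0      # um
    k: float = 0.0               # radial attenuation constant
    v0: float = 1.0              # baseline speed multiplier
    lambda1: float = 1.0         # radial eigen-weight
    lambda2: float = 1.0         # tangential eigen-weight

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(2))
        if self.thickness <= 0 or self.islet_radius <= 0:
            raise ValueError("islet radius and stroma thickness must be positive")
        if self.k < 0:
            raise ValueError("k must be non-negative")

    @property
    def outer_radius(self) -> float:
        return self.islet_radius + self.thickness


def penetration_depth(x: np.ndarray, geom: StromaGeometry) -> float:
    """Depth s advanced inward from the outer stromal boundary, um.

    Clamped to [0, thickness]: zero at and outside the outer boundary,
    saturating at the annulus thickness at and inside the islet boundary.
    """
    r = float(np.linalg.norm(np.asarray(x, dtype=float) - geom.center))
    return float(np.clip(geom.outer_radius - r, 0.0, geom.thickness))


def radial_speed(v0: float, k: float, s: float) -> float:
    """Attenuated radial speed multiplier v = v0 exp(-k s)."""
    if s < 0:
        raise ValueError("penetration depth must be non-negative")
    return v0 * math.exp(-k * s)


def orientation_tensor(x: np.ndarray, geom: StromaGeometry) -> np.ndarray:
    """Symmetric orientation tensor Psi at position ``x`` (2x2 array).

    Inside the annulus the radial eigenvalue is v0 e^{-ks} lambda1 and
    the tangential one v0 lambda2; elsewhere (outside the outer boundary
    or inside the islet, where no oriented fibers exist) Psi = v0 * I
    with the default unit weights.
    """
    x = np.asarray(x, dtype=float).reshape(2)
    delta = x - geom.center
    r = float(np.linalg.norm(delta))
    if r == 0.0:
        raise ValueError("orientation tensor undefined at the islet centre "
                         "(radial direction degenerate)")
    in_annulus = geom.islet_radius < r < geom.outer_radius
    s = penetration_depth(x, geom) if in_annulus else 0.0
    w1 = delta / r                       # radial unit vector
    w2 = np.array([-w1[1], w1[0]])       # tangential unit vector
    radial_eig = radial_speed(geom.v0, geom.k, s) * geom.lambda1
    tangential_eig = geom.v0 * geom.lambda2
    return radial_eig * np.outer(w1, w1) + tangential_eig * np.outer(w2, w2)
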