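"""Euler-Maruyama position updates with adaptive time step.

Positions follow overdamped stochastic differential equations with
additive Wiener noise; nonlinear terms (stimuli, contacts, chemokine
gradients, orientation tensors) are evaluated at the previous step.  A
first-order explicit scheme is used deliberately: the contact energy is
only C^0 at the onset of contact, so higher-order schemes gain nothing.

Stability is enforced twofold: the time step obeys
dt = min(dt_max, R / (2 max ||v||)) over the deterministic
epithelial/cancer speeds, and every per-step displacement is hard-capped
at half the cell radius (R/2, or R_t/2 for the smaller T cells), so no
step can carry a cell past a neighbour.  T-cell chemotactic speeds grow
with the number of cancer sources and are governed by the displacement
cap alone rather than by the global clock.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import cdist

from .chemokine import ChemokineSources, gradient
from .params import ModelParams
from .stroma import StromaGeometry, orientation_tensor

__all__ = [
    "choose_dt",
    "cap_displacement",
    "reflect_into_disk",
    "enforce_min_separation",
    "epithelial_cancer_velocities",
    "step_epithelial_cancer",
    "step_tcells",
]

_CONTACT_PREFACTOR = 4.0 / (15.0 * math.sqrt(2.0))


def choose_dt(max_speed: float, R: float, dt_max: float = 0.1) -> float:
    """Adaptive step dt = min(dt_max, R / (2 max_speed)); dt_max when at rest."""
    if max_speed < 0:
        raise ValueError("max_speed must be non-negative")
    if max_speed == 0.0:
        return dt_max
    return min(dt_max, R / (2.0 * max_speed))


def cap_displacement(disp: np.ndarray, cap: float) -> np.ndarray:
    """Clamp each row of ``disp`` to norm at most ``cap`` (direction kept)."""
    disp = np.asarray(disp, dtype=float)
    norms = np.linalg.norm(disp, axis=-1, keepdims=True)
    scale = np.where(norms > cap, cap / np.maximum(norms, 1e-300), 1.0)
    return disp * scale


def reflect_into_disk(positions: np.ndarray, radius: float,
                      center: np.ndarray | None = None) -> np.ndarray:
    """Reflect positions that left the circular computational domain."""
    positions = np.array(positions, dtype=float)
    c = np.zeros(2) if center is None else np.asarray(center, dtype=float)
    delta = positions - c
    r = np.linalg.norm(delta, axis=-1)
    outside = r > radius
    if np.any(outside):
        factor = (2.0 * radius - r[outside]) / r[outside]
        # a deep overshoot reflects back inside; clamp pathological cases to the rim
        factor = np.clip(factor, 0.0, 1.0)
        positions[outside] = c + delta[outside] * factor[:, None]
    return positions


def enforce_min_separation(positions: np.ndarray, radii: np.ndarray,
                           min_sep: float = 0.1) -> np.ndarray:
    """Push apart pairs closer than ``min_sep`` (cells must never coincide).

    Single symmetric projection pass per step; the displacement caps keep
    per-step approach speeds small enough that one pass suffices.
    """
    positions = np.array(positions, dtype=float)
    n = len(positions)
    if n < 2:
        return positions
    d = cdist(positions, positions)
    iu, ju = np.triu_indices(n, k=1)
    mask = d[iu, ju] < min_sep
    if not np.any(mask):
        return positions
    i_idx, j_idx = iu[mask], ju[mask]
    delta = positions[j_idx] - positions[i_idx]
    dist = np.linalg.norm(delta, axis=1)
    unit = np.where(dist[:, None] > 0, delta / np.maximum(dist, 1e-300)[:, None],
                    np.array([1.0, 0.0]))
    push = 0.5 * (min_sep - dist)[:, None] * unit
    np.add.at(positions, i_idx, -push)
    np.add.at(positions, j_idx, push)
    return positions


def epithelial_cancer_forces(positions: np.ndarray, params: ModelParams,
                             cutoff: float | None = None,
                             epsilon: float = 0.0,
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic velocities and energy bookkeeping of the monolayer.

    Returns ``(velocities, M_remote, contact_sum)`` where ``velocities``
    (um/min) combine attraction alpha * M_remote_i * z_hat_i along the
    normalised stimulus-weighted direction toward neighbours with
    per-pair contact repulsion alpha * M^{ij} away from each partner; on
    the two-cell axis this reduces to the signed net energy
    alpha * (M_remote - M^{ij}) toward the partner, vanishing exactly at
    the equilibrium overlap.  ``M_remote`` and ``contact_sum`` feed the
    event gates |M0 + M_remote - contact_sum|.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n == 0:
        z = np.zeros((0,))
        return np.zeros((0, 2)), z, z
    d = cdist(positions, positions)
    with np.errstate(over="ignore"):
        M = params.M0 * np.exp(-params.lambda_att * d / params.R)
    np.fill_diagonal(M, 0.0)
    if cutoff is not None:
        M[d > cutoff] = 0.0
    if epsilon > 0.0:
        M[M < epsilon] = 0.0

    # component-wise weighted sums (avoids (n, n, 2) temporaries)
    inv_d = np.divide(1.0, d, out=np.zeros_like(d), where=d > 0)
    ux = (positions[None, :, 0] - positions[:, None, 0]) * inv_d  # toward j
    uy = (positions[None, :, 1] - positions[:, None, 1]) * inv_d

    # attraction along the normalised weighted direction
    z = np.column_stack([(M * ux).sum(axis=1), (M * uy).sum(axis=1)])
    z_norm = np.linalg.norm(z, axis=-1, keepdims=True)
    z_hat = np.divide(z, z_norm, out=np.zeros_like(z), where=z_norm > 0)
    M_remote = M.sum(axis=1)
    v = params.alpha * M_remote[:, None] * z_hat

    # per-pair contact repulsion, away from the partner
    h = np.maximum(2.0 * params.R - d, 0.0)
    np.fill_diagonal(h, 0.0)
    Mc = np.zeros_like(h)
    in_contact = h > 0
    if np.any(in_contact):
        Mc[in_contact] = (_CONTACT_PREFACTOR * (params.E_c / math.pi)
                          * (h[in_contact] / params.R) ** 2.5)
        v[:, 0] -= params.alpha * (Mc * ux).sum(axis=1)
        v[:, 1] -= params.alpha * (Mc * uy).sum(axis=1)
    return v, M_remote, Mc.sum(axis=1)


def epithelial_cancer_velocities(positions: np.ndarray, params: ModelParams,
                                 cutoff: float | None = None,
                                 epsilon: float = 0.0) -> np.ndarray:
    """Deterministic velocities of the epithelial/cancer population, um/min."""
    return epithelial_cancer_forces(positions, params, cutoff, epsilon)[0]


def step_epithelial_cancer(positions: np.ndarray, params: ModelParams,
                           rng: np.random.Generator, dt: float,
                           cutoff: float | None = None,
                           velocities: np.ndarray | None = None) -> np.ndarray:
    """One Euler-Maruyama step of the epithelial/cancer positions.

    ``velocities`` may pass in the previously evaluated deterministic
    part (the nonlinear terms are lagged one step); otherwise it is
    computed from the current positions.  Per-cell displacement is
    capped at R/2.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n == 0:
        return positions.copy()
    if velocities is None:
        velocities = epithelial_cancer_velocities(positions, params, cutoff)
    noise = math.sqrt(2.0 * params.D) * rng.normal(0.0, math.sqrt(dt), size=(n, 2))
    disp = cap_displacement(velocities * dt + noise, params.R / 2.0)
    new = positions + disp
    if not np.all(np.isfinite(new)):
        bad = np.nonzero(~np.isfinite(new).all(axis=1))[0]
        raise FloatingPointError(f"non-finite position after update for cell index {bad[0]}")
    return new


def step_tcells(positions: np.ndarray, sources: ChemokineSources,
                geom: StromaGeometry, params: ModelParams,
                rng: np.random.Generator, dt: float,
                repulsion: np.ndarray | None = None) -> np.ndarray:
    """One Euler-Maruyama step of the T-cell positions.

    displacement = Psi (beta grad(c) dt + sqrt(2D) dW) - repulsion dt,
    with Psi the local orientation tensor and ``repulsion`` the summed
    per-contact rates alpha * M^{jl} * u_toward-partner (any phenotype);
    subtracting them moves the T cell away from what it touches.  The
    displacement is capped at R_t/2 per step.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n == 0:
        return positions.copy()
    grad = gradient(positions, sources)
    if grad.ndim == 1:
        grad = grad[None, :]
    noise = math.sqrt(2.0 * params.D) * rng.normal(0.0, math.sqrt(dt), size=(n, 2))
    disp = np.zeros((n, 2))
    for i in range(n):
        r = float(np.linalg.norm(positions[i] - geom.center))
        psi = (geom.v0 * np.eye(2) if r < 1e-12
               else orientation_tensor(positions[i], geom))
        disp[i] = psi @ (params.beta * grad[i] * dt + noise[i])
    if repulsion is not None:
        disp -= np.asarray(repulsion, dtype=float) * dt
    disp = cap_displacement(disp, params.R_t / 2.0)
    new = positions + disp
    if not np.all(np.isfinite(new)):
        raise FloatingPointError("non-finite T-cell position after update")
    return new
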