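"""Strain-energy-density mechanotaxis.

Each epithelial or cancer cell pulls on the elastic substrate with a
traction force F, storing a strain-energy density

    M_j(r) = M_j^0 exp(-lambda_j ||r - r_j|| / R),     M_j^0 = F^2/(2 pi^2 E_s R^4)

at distance ||r - r_j|| from its centre, with attenuation ratio
lambda_j = E_s / E_c.  Energy densities are scalars, so the stimulus a
cell senses is the plain sum over the population.  The migration
direction is the normalised, stimulus-weighted sum of the unit vectors
toward the neighbouring cells: net mechanotactic motion is attractive,
balanced at short range by the contact repulsion of the `contact`
module.  A detection threshold epsilon cuts off signals from beyond the
experimental sensing range d_hat (~30 um); its value at the default
parameters is ~1.99e-54, i.e. numerically zero, and the runtime cutoff
defaults to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .cells import CellRecord, positions_array
from .params import ModelParams

__all__ = [
    "StimulusResult",
    "pairwise_energy",
    "detection_threshold",
    "sensed_stimulus",
    "stimulus_matrix",
    "migration_drift",
]


@dataclass(frozen=True)
class StimulusResult:
    """Sensed mechanical stimulus of one cell.

    ``M_total`` includes the cell's own amplitude M0 (the quantity quoted
    as "equilibrium strain energy density"); ``M_remote`` sums neighbour
    terms only and drives motion.  ``z_hat`` is the unit migration
    direction (None when no remote signal); ``alpha`` the mobility
    beta R^3 / (mu F).
    """

    M_total: float
    M_remote: float
    z_hat: np.ndarray | None
    alpha: float


def pairwise_energy(M0_j: float, lambda_j: float, dist: float, R: float,
                    epsilon: float = 0.0) -> float:
    """Strain-energy density M0_j * exp(-lambda_j * dist / R) at distance ``dist``.

    Values below the detection cutoff ``epsilon`` are clamped to zero.
    """
    if R <= 0:
        raise ValueError("cell radius R must be strictly positive")
    if dist < 0:
        raise ValueError("distance must be non-negative")
    value = M0_j * math.exp(-lambda_j * dist / R)
    return 0.0 if value < epsilon else value


def detection_threshold(M0: float, lambda_att: float, d_hat: float, R: float) -> float:
    """Signal strength at the sensing range d_hat: epsilon = M0 exp(-lambda d_hat / R)."""
    if d_hat < 0:
        raise ValueError("sensing range d_hat must be non-negative")
    if R <= 0:
        raise ValueError("cell radius R must be strictly positive")
    return M0 * math.exp(-lambda_att * d_hat / R)


def stimulus_matrix(positions: np.ndarray, params: ModelParams,
                    cutoff: float | None = None, epsilon: float = 0.0) -> np.ndarray:
    """Matrix of pairwise strain-energy signals for identical cells.

    Entry (i, j) is the energy density cell j deposits at the centre of
    cell i; the diagonal is zero (the own term M0 is added separately).
    Contributions from beyond ``cutoff`` (default: no cutoff) or below
    ``epsilon`` are zero.  Exact for any pair within the cutoff.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n == 0:
        return np.zeros((0, 0))
    d = cdist(positions, positions)
    with np.errstate(over="ignore"):
        m = params.M0 * np.exp(-params.lambda_att * d / params.R)
    np.fill_diagonal(m, 0.0)
    if cutoff is not None:
        m[d > cutoff] = 0.0
    if epsilon > 0.0:
        m[m < epsilon] = 0.0
    return m


def sensed_stimulus(cell: CellRecord, population: list[CellRecord],
                    params: ModelParams, cutoff: float | None = None,
                    epsilon: float = 0.0) -> StimulusResult:
    """Sensed stimulus and migration direction of ``cell`` within ``population``.

    ``population`` holds the live epithelial/cancer cells and may or may
    not contain ``cell`` itself (it is excluded from the remote sum by
    id); listing it twice is a consistency error.
    """
    ids = [c.id for c in population if c.id == cell.id]
    if len(ids) > 1:
        raise ValueError(f"cell {cell.id} appears more than once in the population")
    others = [c for c in population if c.id != cell.id and c.alive]

    M0, lam, R = params.M0, params.lambda_att, params.R
    z = np.zeros(2)
    M_remote = 0.0
    for other in others:
        delta = other.position - cell.position
        dist = float(np.linalg.norm(delta))
        if cutoff is not None and dist > cutoff:
            continue
        m_j = pairwise_energy(M0, lam, dist, R, epsilon)
        M_remote += m_j
        if dist > 0 and m_j > 0:
            z += m_j * delta / dist  # toward the neighbour
    norm = float(np.linalg.norm(z))
    # a weighted sum that cancels to rounding noise (symmetric neighbourhoods)
    # carries no direction information
    z_hat = z / norm if norm > 1e-12 * max(M_remote, 1e-300) else None
    return StimulusResult(M_total=M0 + M_remote, M_remote=M_remote,
                          z_hat=z_hat, alpha=params.alpha)


def migration_drift(stim: StimulusResult, net_energy: float) -> np.ndarray:
    """Mechanotactic displacement rate alpha * max(net_energy, 0) * z_hat, um/min.

    ``net_energy`` is the contact-corrected stimulus (remote sum minus
    the summed contact energies).  The attraction term uses its positive
    part; repulsion is applied per contacting pair by the engine.
    """
    if stim.z_hat is None or net_energy <= 0:
        return np.zeros(2)
    return stim.alpha * net_energy * stim.z_hat
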