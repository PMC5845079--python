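"""Contact (invagination) mechanics of elastically impinging cells.

Overlapping circles generate a repulsive contact strain-energy density

    M^{ij} = (4 / (15 sqrt 2)) (E_c / pi) (h / R)^{5/2},

with indentation h = max(R_a + R_b - ||r_ij||, 0).  The net energy
M-hat subtracts the summed contact energies from the sensed stimulus;
two variants are exposed: the *drift* variant (remote sum minus
contacts) that drives motion and vanishes at the two-cell equilibrium,
and the *gating* variant (total stimulus, own term included, minus
contacts) whose absolute value gates the stochastic events.

``contact_energy`` is continuous and strictly increasing in h but only
C^0 at h = 0 (the 5/2 power has unbounded higher derivatives there),
which is why the integrator uses a first-order Euler-Maruyama scheme.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .cells import CellRecord
from .mechanics import StimulusResult, pairwise_energy
from .params import ModelParams

__all__ = [
    "ContactPair",
    "overlap",
    "contact_energy",
    "find_contacts",
    "net_energy_drift",
    "net_energy_gating",
    "equilibrium_overlap",
]

_CONTACT_PREFACTOR = 4.0 / (15.0 * math.sqrt(2.0))


@dataclass(frozen=True)
class ContactPair:
    """A contacting pair: ids, indentation h, energy, unit vector a -> b."""

    id_a: int
    id_b: int
    h: float
    M_contact: float
    unit_ab: np.ndarray

    def swapped(self) -> "ContactPair":
        return ContactPair(self.id_b, self.id_a, self.h, self.M_contact, -self.unit_ab)


def overlap(dist: float, R_a: float, R_b: float) -> float:
    """Indentation distance h = max(R_a + R_b - dist, 0), um."""
    if dist < 0:
        raise ValueError("distance must be non-negative")
    return max(R_a + R_b - dist, 0.0)


def contact_energy(h: float, R: float, E_c: float) -> float:
    """Contact strain-energy density (4/(15 sqrt 2)) (E_c/pi) (h/R)^(5/2)."""
    if R <= 0:
        raise ValueError("radius must be strictly positive")
    if h < 0:
        raise ValueError("indentation must be non-negative")
    if h > 2.0 * R:
        warnings.warn(f"indentation h={h} exceeds the cell diameter; "
                      "cells are (nearly) coincident", stacklevel=2)
    return _CONTACT_PREFACTOR * (E_c / math.pi) * (h / R) ** 2.5


def find_contacts(cell: CellRecord, population: list[CellRecord],
                  E_c: float) -> list[ContactPair]:
    """All contacts of ``cell`` with the live cells of ``population``.

    Mixed radii use h = R_a + R_b - dist and the smaller radius in the
    energy law (the indentation is limited by the smaller cell).
    """
    pairs: list[ContactPair] = []
    for other in population:
        if other.id == cell.id or not other.alive:
            continue
        delta = other.position - cell.position
        dist = float(np.linalg.norm(delta))
        h = overlap(dist, cell.radius, other.radius)
        if h <= 0:
            continue
        R_eff = min(cell.radius, other.radius)
        unit = delta / dist if dist > 0 else np.array([1.0, 0.0])
        pairs.append(ContactPair(cell.id, other.id, h,
                                 contact_energy(h, R_eff, E_c), unit))
    return pairs


def _contact_sum(cell_id: int, contacts: list[ContactPair]) -> float:
    total = 0.0
    for pair in contacts:
        if cell_id not in (pair.id_a, pair.id_b):
            raise ValueError(f"contact pair {pair.id_a}-{pair.id_b} does not involve cell {cell_id}")
        total += pair.M_contact
    return total


def net_energy_drift(cell: CellRecord, stim: StimulusResult,
                     contacts: list[ContactPair]) -> float:
    """Drift variant: remote stimulus minus summed contact energies (signed)."""
    return stim.M_remote - _contact_sum(cell.id, contacts)


def net_energy_gating(cell: CellRecord, stim: StimulusResult,
                      contacts: list[ContactPair]) -> float:
    """Gating variant ||M-hat||: |total stimulus (own term incl.) - contacts|."""
    return abs(stim.M_total - _contact_sum(cell.id, contacts))


def equilibrium_overlap(params: ModelParams, tol: float = 1e-6) -> float:
    """Two-cell equilibrium indentation h*, um.

    Solves the balance between the remote attraction a cell senses from
    its partner and the contact repulsion,

        M0 exp(-lambda (2R - h) / R) = (4/(15 sqrt 2)) (E_c/pi) (h/R)^{5/2},

    for h on (0, 2R) by bracketed root finding.  The residual has two
    sign changes; the larger root is returned — the "maximum equilibrium
    overlap" of the two-cell analysis, near h ~ 2 um with the calibrated
    defaults.
    """
    R = params.R

    def residual(h: float) -> float:
        attraction = pairwise_energy(params.M0, params.lambda_att, 2.0 * R - h, R)
        return attraction - contact_energy(h, R, params.E_c)

    # Scan for the sign change adjacent to the upper end of the interval:
    # the attraction (exponential in h) overtakes the contact power law
    # near full overlap, so the physically quoted balance point is the
    # largest root below that crossover.
    hs = np.linspace(1e-9, 2.0 * R - 1e-9, 2048)
    vals = np.array([residual(h) for h in hs])
    sign_changes = np.nonzero(np.diff(np.signbit(vals)))[0]
    if sign_changes.size == 0:
        raise ValueError("no equilibrium: attraction and contact energy do not balance on (0, 2R)")
    idx = sign_changes[-1]
    return float(brentq(residual, hs[idx], hs[idx + 1], xtol=tol))
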