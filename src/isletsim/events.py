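"""Stochastic cell events: division, anoikis, mutation and engulfment.

Events are memoryless: an event with probability rate lambda (1/min)
fires within a step of length dt with probability 1 - exp(-lambda dt);
a uniform draw xi fires the event iff xi <= that probability.  Whether a
cell is *eligible* for an event is gated by the absolute net strain
energy ||M-hat|| (gating variant, own term included) and by its growth
clock:

* epithelial division:  ||M-hat|| < 0.03 and clock >= 5 min, limited by
  a somatic division budget (default 50);
* cancer division:      ||M-hat|| < 0.04 and clock >= 5 min, unlimited
  ("immortal" lineage);
* epithelial anoikis:   ||M-hat|| >= 0.1 and clock >= 10 min (cancer
  cells die only by engulfment);
* epithelial mutation:  ||M-hat|| >= 0.05 and clock >= 10 min.

T-lymphocytes engulf cancer cells after sustained proximity: the
per-pair contact clock accrues while the distance is within the kill
distance of the immunity level (2.5 um for weak, 3.5 um for strong) and
resets otherwise; once it reaches the kill time (10 min weak, 5 min
strong) the engulfment event is drawn at the same rate, removing the
cancer cell and, with a configurable probability, the T cell as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cells import CellRecord, Phenotype

__all__ = [
    "EventThresholds",
    "event_probability",
    "draw_event",
    "eligible_events",
    "apply_division",
    "update_immune_interactions",
]


@dataclass(frozen=True)
class EventThresholds:
    """Gates (kg.um/min^2), growth times (min) and immune-interaction rules."""

    rate: float = 10.0                  # 1/min, common to all events
    gate_div_epithelial: float = 0.03
    gate_div_cancer: float = 0.04
    gate_apoptosis: float = 0.1
    gate_mutation: float = 0.05
    tau_div: float = 5.0
    tau_mut: float = 10.0
    tau_apop: float = 10.0
    kill_distance_weak: float = 2.5     # um
    kill_time_weak: float = 10.0        # min
    kill_distance_strong: float = 3.5   # um
    kill_time_strong: float = 5.0       # min
    tcell_death_prob: float = 0.2       # per engulfment event

    def __post_init__(self) -> None:
        for name in ("rate", "gate_div_epithelial", "gate_div_cancer", "gate_apoptosis",
                     "gate_mutation", "tau_div", "tau_mut", "tau_apop",
                     "kill_distance_weak", "kill_time_weak", "kill_distance_strong",
                     "kill_time_strong"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.tcell_death_prob <= 1.0:
            raise ValueError("tcell_death_prob must be a probability")

    def kill_distance(self, immunity: str) -> float:
        return self.kill_distance_strong if immunity == "strong" else self.kill_distance_weak

    def kill_time(self, immunity: str) -> float:
        return self.kill_time_strong if immunity == "strong" else self.kill_time_weak


def event_probability(rate: float, dt: float) -> float:
    """P(event in dt) = 1 - exp(-rate dt) for the exponential waiting time."""
    if rate < 0 or dt < 0:
        raise ValueError("rate and dt must be non-negative")
    return 1.0 - math.exp(-rate * dt)


def draw_event(xi: float, rate: float, dt: float) -> bool:
    """True iff the uniform draw xi falls below 1 - exp(-rate dt)."""
    if not 0.0 <= xi <= 1.0:
        raise ValueError("uniform draw xi must lie in [0, 1]")
    return xi <= event_probability(rate, dt)


def eligible_events(cell: CellRecord, net_gate_energy: float,
                    thresholds: EventThresholds,
                    division_cap_epithelial: int = 50) -> set[str]:
    """Set of events ``{'divide', 'die', 'mutate'}`` the cell is gated into.

    ``net_gate_energy`` is ||M-hat|| (gating variant).  T cells are
    eligible for none of these (they neither divide nor mutate here).
    """
    if not cell.alive or cell.phenotype is Phenotype.TCELL:
        return set()
    events: set[str] = set()
    m = net_gate_energy
    clock = cell.growth_clock
    if cell.phenotype is Phenotype.EPITHELIAL:
        if (m < thresholds.gate_div_epithelial and clock >= thresholds.tau_div
                and cell.divisions_done < division_cap_epithelial):
            events.add("divide")
        if m >= thresholds.gate_apoptosis and clock >= thresholds.tau_apop:
            events.add("die")
        if m >= thresholds.gate_mutation and clock >= thresholds.tau_mut:
            events.add("mutate")
    elif cell.phenotype is Phenotype.CANCER:
        if m < thresholds.gate_div_cancer and clock >= thresholds.tau_div:
            events.add("divide")
    return events


def apply_division(mother: CellRecord, new_id: int, rng: np.random.Generator,
                   birth_distance: float | None = None) -> CellRecord:
    """Create a daughter cell at ``birth_distance`` (default: one radius).

    The daughter is placed in a uniformly random direction at the cell
    radius R from the mother (initial indentation h = R); the contact
    repulsion then separates the pair gradually.  Both growth clocks
    reset; the mother's division count is incremented; the daughter
    inherits the phenotype with a fresh division budget.
    """
    if birth_distance is None:
        birth_distance = mother.radius
    theta = rng.uniform(0.0, 2.0 * math.pi)
    offset = birth_distance * np.array([math.cos(theta), math.sin(theta)])
    mother.growth_clock = 0.0
    mother.divisions_done += 1
    return CellRecord(id=new_id, position=mother.position + offset,
                      phenotype=mother.phenotype, radius=mother.radius)


def update_immune_interactions(tcells: list[CellRecord], cancers: list[CellRecord],
                               immunity: str, dt: float,
                               rng: np.random.Generator,
                               thresholds: EventThresholds,
                               ) -> tuple[list[int], list[int]]:
    """Advance T-cell/cancer contact clocks and draw engulfment events.

    Returns ``(engulfed cancer ids, dead T-cell ids)``.  Clocks accrue by
    dt while the pair distance is within the kill distance and reset when
    the pair separates; once a clock reaches the kill time the engulfment
    is drawn each step at the common event rate.  An engulfing T cell
    dies with probability ``thresholds.tcell_death_prob``.

    Draws consume the generator in deterministic (T-cell id, cancer id)
    order so replicates are reproducible.
    """
    if immunity == "none" or not tcells or not cancers:
        return [], []
    kill_d = thresholds.kill_distance(immunity)
    kill_t = thresholds.kill_time(immunity)
    engulfed: list[int] = []
    tcell_deaths: list[int] = []

    live_cancers = sorted((c for c in cancers if c.alive), key=lambda c: c.id)
    live_tcells = sorted((t for t in tcells if t.alive), key=lambda c: c.id)
    if not live_cancers or not live_tcells:
        return [], []
    cpos = np.array([c.position for c in live_cancers])
    tpos = np.array([t.position for t in live_tcells])
    # (tcell, cancer) proximity matrix; python work only on close pairs
    dists = np.linalg.norm(tpos[:, None, :] - cpos[None, :, :], axis=-1)

    for ti, tcell in enumerate(live_tcells):
        close_ids = {live_cancers[ci].id for ci in np.nonzero(dists[ti] <= kill_d)[0]}
        # clocks of separated or removed partners reset (drop)
        tcell.contact_clocks = {cid: t for cid, t in tcell.contact_clocks.items()
                                if cid in close_ids}
        for ci in np.nonzero(dists[ti] <= kill_d)[0]:
            cancer = live_cancers[ci]
            if not cancer.alive or not tcell.alive:
                continue
            clock = tcell.contact_clocks.get(cancer.id, 0.0) + dt
            tcell.contact_clocks[cancer.id] = clock
            if clock >= kill_t and draw_event(rng.uniform(), thresholds.rate, dt):
                cancer.alive = False
                engulfed.append(cancer.id)
                if rng.uniform() < thresholds.tcell_death_prob:
                    tcell.alive = False
                    tcell_deaths.append(tcell.id)
                    break
    return engulfed, tcell_deaths
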