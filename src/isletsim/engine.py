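"""Simulation engine: initial configurations, the coupled time loop and sweeps.

A simulation starts from a hexagonally packed epithelial monolayer
filling the islet disk (no cancer cells, no T cells).  Each step, in
order: (1) stimuli, contacts and gating energies are evaluated at the
current positions; (2) the adaptive time step is chosen from the
deterministic monolayer speeds; (3) epithelial/cancer cells and T cells
move by one Euler-Maruyama step (nonlinear terms lagged); (4) growth
clocks advance; (5) mutation, anoikis and division events are drawn
(death-dominant order: a dying cell cannot divide in the same step);
(6) T-cell engulfment interactions fire; (7) counts are recorded.  The
first cancer cell triggers recruitment of T cells on a circle outside
the stroma.

Randomness comes from one seeded generator per replicate, consumed in a
fixed order (monolayer Wiener draws, T-cell Wiener draws, event draws in
cell-id order, placement draws, immune draws), so a replicate is fully
reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cells import CellRecord, Phenotype, hex_lattice_disk, positions_array
from .chemokine import ChemokineSources
from .events import (EventThresholds, apply_division, draw_event, eligible_events,
                     update_immune_interactions)
from .integrator import (choose_dt, enforce_min_separation, epithelial_cancer_forces,
                         reflect_into_disk, step_epithelial_cancer, step_tcells)
from .params import ModelParams, ScenarioConfig
from .reporting import RunSummary, summarize_run
from .stroma import StromaGeometry

__all__ = ["SimulationState", "initialize", "spawn_tcells", "run", "k_sweep"]

#: margin of the reflecting computational boundary beyond the stroma, um
BOUNDARY_MARGIN = 10.0
#: minimum admissible centre-to-centre separation, um
MIN_SEPARATION = 0.1


@dataclass
class SimulationState:
    """Full mutable state of one replicate."""

    time: float
    cells: list[CellRecord]
    geometry: StromaGeometry
    params: ModelParams
    scenario: ScenarioConfig
    thresholds: EventThresholds
    rng: np.random.Generator
    event_log: list[tuple[float, str, tuple[int, ...]]] = field(default_factory=list)
    series: list[dict] = field(default_factory=list)
    next_id: int = 0
    tcells_spawned: bool = False
    cancer_seeded: bool = False

    def live(self, *phenotypes: Phenotype) -> list[CellRecord]:
        wanted = set(phenotypes) or set(Phenotype)
        return [c for c in self.cells if c.alive and c.phenotype in wanted]

    def counts(self) -> dict[str, int]:
        out = {"n_epithelial": 0, "n_cancer": 0, "n_tcell": 0}
        for c in self.cells:
            if c.alive:
                out["n_" + c.phenotype.value] += 1
        return out

    @property
    def domain_radius(self) -> float:
        return self.geometry.outer_radius + BOUNDARY_MARGIN


def initialize(scenario: ScenarioConfig, params: ModelParams,
               rng: np.random.Generator | None = None,
               thresholds: EventThresholds | None = None) -> SimulationState:
    """Build the initial state: a packed epithelial monolayer in the islet.

    Placement is deterministic (a hexagonal lattice with spacing
    ``packing_factor * 2R``), so the initial cell count is invariant
    under the seed.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    if thresholds is None:
        thresholds = EventThresholds(tcell_death_prob=scenario.tcell_death_prob)
    spacing = scenario.packing_factor * 2.0 * params.R
    cells = hex_lattice_disk(scenario.islet_radius, spacing, radius=params.R)
    if not cells:
        raise ValueError("packing produced zero cells")
    geometry = StromaGeometry(islet_radius=scenario.islet_radius,
                              thickness=scenario.stroma_thickness, k=scenario.k)
    state = SimulationState(time=0.0, cells=cells, geometry=geometry,
                            params=params, scenario=scenario,
                            thresholds=thresholds, rng=rng,
                            next_id=len(cells))
    _record(state)
    return state


def spawn_tcells(state: SimulationState) -> SimulationState:
    """Recruit T cells on the circle 5 um outside the stroma.

    The number is set by the immunity level (N_s = 2 N_w); angles are
    drawn uniformly from the replicate generator.
    """
    n = state.scenario.n_tcells
    radius = state.geometry.outer_radius + 5.0
    ids = []
    for _ in range(n):
        theta = state.rng.uniform(0.0, 2.0 * math.pi)
        pos = radius * np.array([math.cos(theta), math.sin(theta)])
        cell = CellRecord(id=state.next_id, position=pos,
                          phenotype=Phenotype.TCELL, radius=state.params.R_t)
        state.cells.append(cell)
        ids.append(cell.id)
        state.next_id += 1
    state.tcells_spawned = True
    if ids:
        state.event_log.append((state.time, "spawn_tcell", tuple(ids)))
    return state


def _record(state: SimulationState) -> None:
    counts = state.counts()
    total = counts["n_epithelial"] + counts["n_cancer"]
    if state.scenario.totals_include_tcells:
        total += counts["n_tcell"]
    fraction = counts["n_cancer"] / total if total > 0 else 0.0
    state.series.append({"time_min": state.time, **counts, "cancer_fraction": fraction})


def _seed_cancer(state: SimulationState) -> None:
    """Deterministically convert the epithelial cell nearest the centre."""
    epithelial = state.live(Phenotype.EPITHELIAL)
    if not epithelial:
        return
    nearest = min(epithelial, key=lambda c: float(np.linalg.norm(c.position)))
    nearest.phenotype = Phenotype.CANCER
    nearest.growth_clock = 0.0
    state.cancer_seeded = True
    state.event_log.append((state.time, "mutate", (nearest.id,)))


def _tcell_repulsion(tcells: list[CellRecord], others: list[CellRecord],
                     params: ModelParams) -> np.ndarray:
    """Summed contact displacement rates of each T cell, toward partners."""
    rep = np.zeros((len(tcells), 2))
    if not tcells:
        return rep
    prefactor = 4.0 / (15.0 * math.sqrt(2.0)) * params.E_c / math.pi
    partners = [c for c in others if c.alive]
    if not partners:
        return rep
    tpos = np.array([t.position for t in tcells])
    tids = np.array([t.id for t in tcells])
    opos = np.array([o.position for o in partners])
    oids = np.array([o.id for o in partners])
    orad = np.array([o.radius for o in partners])
    trad = np.array([t.radius for t in tcells])

    delta = opos[None, :, :] - tpos[:, None, :]            # (t, o, 2)
    dist = np.linalg.norm(delta, axis=-1)
    h = trad[:, None] + orad[None, :] - dist
    h[tids[:, None] == oids[None, :]] = 0.0                # self-pairs
    in_contact = h > 0
    if not np.any(in_contact):
        return rep
    R_eff = np.minimum(trad[:, None], orad[None, :])
    m_c = np.zeros_like(h)
    m_c[in_contact] = prefactor * (h[in_contact] / R_eff[in_contact]) ** 2.5
    safe = np.where(dist > 0, dist, np.inf)
    unit = delta / safe[..., None]
    rep += params.alpha * (m_c[..., None] * unit).sum(axis=1)
    return rep


def _step(state: SimulationState) -> float:
    """Advance one step; returns the dt taken."""
    sc, params, thresholds = state.scenario, state.params, state.thresholds
    wcells = state.live(Phenotype.EPITHELIAL, Phenotype.CANCER)
    tcells = state.live(Phenotype.TCELL)
    cancers = [c for c in wcells if c.phenotype is Phenotype.CANCER]

    # (1) stimuli, contacts, gating energies at the current positions
    wpos = positions_array(wcells)
    velocities, M_remote, contact_sum = epithelial_cancer_forces(
        wpos, params, cutoff=sc.d_hat, epsilon=sc.epsilon)
    gate_energy = np.abs(params.M0 + M_remote - contact_sum) if len(wcells) else M_remote

    # (2) time step from the deterministic monolayer speeds
    max_speed = float(np.max(np.linalg.norm(velocities, axis=1))) if len(wcells) else 0.0
    dt = choose_dt(max_speed, params.R, sc.dt_max)
    dt = max(dt, sc.dt_min)
    dt = min(dt, max(sc.t_end - state.time, 1e-12))

    # (3) Euler-Maruyama moves, nonlinear parts lagged one step
    if len(wcells):
        new_wpos = step_epithelial_cancer(wpos, params, state.rng, dt,
                                          cutoff=sc.d_hat, velocities=velocities)
    else:
        new_wpos = wpos
    if tcells:
        sources = ChemokineSources(positions_array(cancers), gamma=params.gamma,
                                   D_c=params.D_c, r_min=params.R_t)
        rep = _tcell_repulsion(tcells, state.live(), params)
        new_tpos = step_tcells(positions_array(tcells), sources, state.geometry,
                               params, state.rng, dt, repulsion=rep)
    else:
        new_tpos = np.empty((0, 2))

    all_cells = wcells + tcells
    all_pos = np.vstack([new_wpos, new_tpos]) if all_cells else np.empty((0, 2))
    all_pos = reflect_into_disk(all_pos, state.domain_radius)
    radii = np.array([c.radius for c in all_cells])
    all_pos = enforce_min_separation(all_pos, radii, MIN_SEPARATION)
    for cell, pos in zip(all_cells, all_pos):
        cell.position = pos

    # (4) clocks
    for cell in all_cells:
        cell.growth_clock += dt
    state.time += dt

    # (5) stochastic events, death-dominant order, cell-id order draws
    gate_by_id = {c.id: float(g) for c, g in zip(wcells, gate_energy)}
    daughters: list[CellRecord] = []
    for cell in sorted(wcells, key=lambda c: c.id):
        if not cell.alive:
            continue
        events = eligible_events(cell, gate_by_id[cell.id], thresholds,
                                 sc.division_cap_epithelial)
        if "mutate" in events and draw_event(state.rng.uniform(), thresholds.rate, dt):
            cell.phenotype = Phenotype.CANCER
            cell.growth_clock = 0.0
            state.event_log.append((state.time, "mutate", (cell.id,)))
            continue
        if "die" in events and draw_event(state.rng.uniform(), thresholds.rate, dt):
            cell.alive = False
            state.event_log.append((state.time, "die", (cell.id,)))
            continue
        if "divide" in events and draw_event(state.rng.uniform(), thresholds.rate, dt):
            daughter = apply_division(cell, state.next_id, state.rng)
            state.next_id += 1
            daughters.append(daughter)
            state.event_log.append((state.time, "divide", (cell.id, daughter.id)))
    state.cells.extend(daughters)

    if (sc.seed_cancer_time is not None and not state.cancer_seeded
            and state.time >= sc.seed_cancer_time):
        _seed_cancer(state)

    # (6) immune interactions
    live_tcells = state.live(Phenotype.TCELL)
    live_cancers = state.live(Phenotype.CANCER)
    if live_tcells and live_cancers:
        engulfed, tdead = update_immune_interactions(
            live_tcells, live_cancers, sc.immunity, dt, state.rng, thresholds)
        for cid in engulfed:
            state.event_log.append((state.time, "engulf", (cid,)))
        for tid in tdead:
            state.event_log.append((state.time, "tcell_death", (tid,)))

    # recruit T cells once the first cancer cell exists
    if not state.tcells_spawned and sc.immunity != "none" and state.live(Phenotype.CANCER):
        spawn_tcells(state)

    # dead cells leave the population immediately (no inert corpses)
    state.cells = [c for c in state.cells if c.alive]

    # (7) record
    _record(state)
    return dt


def _absorbed(state: SimulationState) -> bool:
    counts = state.counts()
    cleared = state.tcells_spawned and counts["n_cancer"] == 0
    all_cancer = counts["n_epithelial"] == 0 and counts["n_cancer"] > 0 and \
        state.scenario.immunity == "none"
    return cleared or all_cancer


def run(state: SimulationState, outdir: str | Path | None = None) -> RunSummary:
    """Advance the state to ``t_end`` and summarise the replicate.

    Snapshots (one CSV per configured time) and the time-series CSV are
    written when ``outdir`` is given.
    """
    sc = state.scenario
    outdir = Path(outdir) if outdir is not None else None
    snapshot_times = sorted(t for t in sc.snapshot_times if t <= sc.t_end)
    next_snapshot = 0
    if outdir is not None and snapshot_times and snapshot_times[0] <= 0.0:
        _write_snapshot(state, outdir)
        next_snapshot = 1

    while state.time < sc.t_end:
        _step(state)
        while (outdir is not None and next_snapshot < len(snapshot_times)
               and state.time >= snapshot_times[next_snapshot]):
            _write_snapshot(state, outdir)
            next_snapshot += 1
        if sc.early_exit and _absorbed(state):
            break

    summary = summarize_run(pd.DataFrame(state.series), seed=sc.seed, scenario=sc)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        summary.series.to_csv(outdir / "timeseries.csv", index=False)
        (outdir / "summary.json").write_text(summary.to_json())
    return summary


def _write_snapshot(state: SimulationState, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [{"id": c.id, "x_um": c.position[0], "y_um": c.position[1],
             "phenotype": c.phenotype.value, "radius_um": c.radius}
            for c in state.cells if c.alive]
    pd.DataFrame(rows, columns=["id", "x_um", "y_um", "phenotype", "radius_um"]).to_csv(
        outdir / f"snapshot_t{state.time:07.1f}.csv", index=False)


def k_sweep(base_scenario: ScenarioConfig, params: ModelParams,
            k_values: Sequence[float] | None = None, replicates: int = 10,
            thresholds: EventThresholds | None = None) -> pd.DataFrame:
    """Run ``replicates`` seeded simulations per anisotropy value.

    Default grid: the ten values k = 0.0, 0.1, ..., 0.9.  Each run gets
    an independent generator derived from (base seed, k index,
    replicate), so the table is reproducible.  Returns one row per run
    with the derived metrics (immune response time, censoring flag, max
    cancer fraction, final counts).
    """
    if k_values is None:
        k_values = [round(0.1 * j, 1) for j in range(10)]
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    rows = []
    for ki, k in enumerate(k_values):
        for rep in range(replicates):
            scenario = ScenarioConfig(**{**_scenario_dict(base_scenario),
                                         "k": float(k)})
            rng = np.random.default_rng([base_scenario.seed, ki, rep])
            state = initialize(scenario, params, rng=rng, thresholds=thresholds)
            summary = run(state)
            final = state.counts()
            rows.append({"k": float(k), "replicate": rep,
                         "immune_response_time": summary.immune_response_time,
                         "censored": summary.censored,
                         "max_cancer_fraction": summary.max_cancer_fraction,
                         **final})
    return pd.DataFrame(rows)


def _scenario_dict(scenario: ScenarioConfig) -> dict:
    import dataclasses
    return dataclasses.asdict(scenario)
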