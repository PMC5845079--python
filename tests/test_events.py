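"""Memoryless event model, gates and immune interactions."""

import math

import numpy as np
import pytest

from isletsim import (EventThresholds, apply_division, draw_event, eligible_events,
                      event_probability, update_immune_interactions)
from isletsim.cells import CellRecord, Phenotype

TH = EventThresholds()


class TestEventProbability:
    def test_printed_default_step_value(self):
        # rate 10/min over 0.1 min
        assert event_probability(10.0, 0.1) == pytest.approx(0.6321, abs=5e-5)

    def test_zero_dt(self):
        assert event_probability(10.0, 0.0) == 0.0

    def test_zero_rate(self):
        assert event_probability(0.0, 5.0) == 0.0

    def test_small_rate_linearisation(self):
        rate, dt = 0.01, 0.01
        assert event_probability(rate, dt) == pytest.approx(rate * dt, rel=1e-3)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            event_probability(-1.0, 0.1)
        with pytest.raises(ValueError):
            event_probability(1.0, -0.1)

    def test_memorylessness_split_step(self):
        """Survival over dt equals the product of two half-step survivals."""
        rate, dt = 10.0, 0.1
        full = 1.0 - event_probability(rate, dt)
        half = 1.0 - event_probability(rate, dt / 2.0)
        assert full == pytest.approx(half * half, rel=1e-12)


class TestDrawEvent:
    def test_zero_draw_always_fires(self):
        assert draw_event(0.0, 10.0, 0.1)

    def test_unit_draw_never_fires(self):
        assert not draw_event(1.0, 10.0, 0.1)

    def test_median_draw(self):
        assert draw_event(0.5, 10.0, 0.1)  # 0.5 < 0.6321

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            draw_event(1.5, 10.0, 0.1)

    def test_monte_carlo_frequency(self, rng):
        """Empirical frequency matches 1 - exp(-rate dt) within 3 sigma."""
        rate, dt, n = 10.0, 0.1, 100_000
        p = event_probability(rate, dt)
        hits = sum(draw_event(x, rate, dt) for x in rng.uniform(size=n))
        tol = 3.0 * math.sqrt(p * (1 - p) / n)
        assert hits / n == pytest.approx(p, abs=tol)


def _cell(phenotype, clock, divisions=0):
    return CellRecord(id=0, position=[0, 0], phenotype=phenotype,
                      growth_clock=clock, divisions_done=divisions)


class TestEligibility:
    @pytest.mark.parametrize("m,clock,expected", [
        (0.02, 6.0, {"divide"}),            # below division gate, grown
        (0.02, 4.0, set()),                 # not grown yet
        (0.07, 12.0, {"mutate"}),           # between mutation and death gates
        (0.12, 12.0, {"die", "mutate"}),    # above both gates
        (0.04, 12.0, set()),                # between gates: neither divide nor mutate
        (0.12, 9.0, set()),                 # gates met but clocks not
    ])
    def test_epithelial_gates(self, m, clock, expected):
        assert eligible_events(_cell(Phenotype.EPITHELIAL, clock), m, TH) == expected

    def test_cancer_gate_is_looser_and_immortal(self):
        # 0.035 blocks epithelial division (>= 0.03) but not cancer (< 0.04)
        assert eligible_events(_cell(Phenotype.EPITHELIAL, 6.0), 0.035, TH) == set()
        assert eligible_events(_cell(Phenotype.CANCER, 6.0), 0.035, TH) == {"divide"}
        # mechanics never kill cancer cells
        assert eligible_events(_cell(Phenotype.CANCER, 20.0), 5.0, TH) == set()

    def test_cancer_has_no_division_cap(self):
        cell = _cell(Phenotype.CANCER, 6.0, divisions=10_000)
        assert eligible_events(cell, 0.01, TH) == {"divide"}

    def test_epithelial_cap_blocks_division(self):
        capped = _cell(Phenotype.EPITHELIAL, 6.0, divisions=50)
        assert eligible_events(capped, 0.01, TH, division_cap_epithelial=50) == set()
        assert eligible_events(capped, 0.01, TH, division_cap_epithelial=100) == {"divide"}

    def test_tcells_have_no_events(self):
        assert eligible_events(_cell(Phenotype.TCELL, 100.0), 0.0, TH) == set()

    def test_dead_cells_have_no_events(self):
        cell = _cell(Phenotype.EPITHELIAL, 10.0)
        cell.alive = False
        assert eligible_events(cell, 0.01, TH) == set()


class TestDivision:
    def test_daughter_geometry_and_inheritance(self, rng):
        mother = _cell(Phenotype.CANCER, 8.0)
        mother.divisions_done = 3
        daughter = apply_division(mother, new_id=99, rng=rng)
        assert daughter.phenotype is Phenotype.CANCER
        assert daughter.id == 99
        assert np.linalg.norm(daughter.position - mother.position) == pytest.approx(
            mother.radius)
        assert mother.growth_clock == 0.0
        assert daughter.growth_clock == 0.0
        assert mother.divisions_done == 4
        assert daughter.divisions_done == 0

    def test_direction_uniform_over_angles(self, rng):
        mother = _cell(Phenotype.EPITHELIAL, 8.0)
        angles = []
        for i in range(500):
            d = apply_division(_cell(Phenotype.EPITHELIAL, 8.0), i, rng)
            angles.append(math.atan2(d.position[1], d.position[0]))
        # crude isotropy check: all four quadrants populated
        quadrants = np.histogram(angles, bins=4, range=(-math.pi, math.pi))[0]
        assert quadrants.min() > 50


class TestImmuneInteractions:
    def _pair(self, dist):
        t = CellRecord(id=1, position=[0.0, 0.0], phenotype=Phenotype.TCELL, radius=2.0)
        c = CellRecord(id=2, position=[dist, 0.0], phenotype=Phenotype.CANCER, radius=2.5)
        return t, c

    def test_strong_reach_exceeds_weak(self, rng):
        """A 3.0-um pair accrues clock under strong rules but resets under weak."""
        t, c = self._pair(3.0)
        update_immune_interactions([t], [c], "strong", 0.1, rng, TH)
        assert t.contact_clocks.get(2) == pytest.approx(0.1)
        t2, c2 = self._pair(3.0)
        t2.contact_clocks[2] = 3.0
        update_immune_interactions([t2], [c2], "weak", 0.1, rng, TH)
        assert 2 not in t2.contact_clocks

    def test_no_kill_before_contact_time(self, rng):
        t, c = self._pair(2.0)
        t.contact_clocks[2] = TH.kill_time_strong - 0.2
        engulfed, dead = update_immune_interactions([t], [c], "strong", 0.1, rng, TH)
        assert engulfed == [] and dead == []
        assert c.alive

    def test_kill_after_sustained_contact(self):
        rng = np.random.default_rng(0)
        t, c = self._pair(2.0)
        t.contact_clocks[2] = TH.kill_time_strong
        # rate 10 over dt 1 -> p = 1 - e^-10; the draw fires essentially surely
        engulfed, _ = update_immune_interactions([t], [c], "strong", 1.0, rng, TH)
        assert engulfed == [2]
        assert not c.alive

    def test_none_immunity_is_inert(self, rng):
        t, c = self._pair(1.0)
        t.contact_clocks[2] = 100.0
        assert update_immune_interactions([t], [c], "none", 1.0, rng, TH) == ([], [])

    def test_tcell_death_risk_accompanies_kills(self):
        """Over many engulfments the T-cell death fraction matches the configured probability."""
        rng = np.random.default_rng(1)
        deaths = 0
        n = 2000
        for _ in range(n):
            t, c = self._pair(2.0)
            t.contact_clocks[2] = TH.kill_time_strong
            _, dead = update_immune_interactions([t], [c], "strong", 5.0, rng, TH)
            deaths += len(dead)
        p = TH.tcell_death_prob
        assert deaths / n == pytest.approx(p, abs=3 * math.sqrt(p * (1 - p) / n))
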