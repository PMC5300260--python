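"""Schedule heuristic: worked examples, oracle certification, occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graftsim import (
    ShipmentScenario,
    enumerate_optimal,
    make_scenario,
    optimize_schedule,
    storage_occupancy,
)
from graftsim.schedule import ScheduleError, enumeration_size


class TestWorkedExamples:
    def test_late_block_of_60_spreads_to_three_weeks(self):
        sc = ShipmentScenario("tomato", (0, 0, 60))
        s = optimize_schedule(sc, max_storage_weeks=2, block_size=10, seed=0)
        assert s.weekly_graft == (20, 20, 20)
        assert s.peak == 20

    def test_zero_storage_returns_identity(self):
        sc = make_scenario("single_peak", 5, 50, 3, 1, 6)
        s = optimize_schedule(sc, max_storage_weeks=0, seed=0)
        assert s.weekly_graft == sc.demand

    def test_two_thirty_weeks_level_to_twenty(self):
        sc = ShipmentScenario("tomato", (0, 30, 30))
        s = optimize_schedule(sc, max_storage_weeks=1, block_size=10, seed=1)
        assert s.weekly_graft == (20, 20, 20)

    def test_exact_mode_matches_oracle(self):
        sc = ShipmentScenario("tomato", (0, 0, 60))
        s = optimize_schedule(sc, 2, block_size=10, seed=3, method="exact")
        assert s.weekly_graft == (20, 20, 20)


class TestOracle:
    def test_oracle_contains_level_schedule(self):
        optima = enumerate_optimal(ShipmentScenario("tomato", (0, 0, 60)), 2, 10)
        assert any(s.weekly_graft == (20, 20, 20) for s in optima)

    def test_flat_demand_unique_identity_optimum(self):
        optima = enumerate_optimal(ShipmentScenario("tomato", (10, 10, 10)), 2, 10)
        assert len(optima) == 1
        assert optima[0].weekly_graft == (10, 10, 10)

    def test_two_placements_level_forty(self):
        optima = enumerate_optimal(ShipmentScenario("tomato", (0, 40)), 1, 20)
        assert optima[0].weekly_graft == (20, 20)

    def test_oracle_refuses_oversized_instances(self):
        sc = make_scenario("single_peak", 50, 500, 12, 1, 24)
        assert enumeration_size(sc, 4, 10) > 500_000
        with pytest.raises(ScheduleError, match="oracle bound"):
            enumerate_optimal(sc, 4, 10)


def _random_small_instance(draw):
    horizon = draw(st.integers(2, 6))
    storage = draw(st.integers(1, 4))
    block = draw(st.sampled_from([5, 10, 20]))
    demand = draw(
        st.lists(st.sampled_from([0, 5, 10, 15, 20, 25, 30]), min_size=horizon, max_size=horizon)
    )
    return horizon, storage, block, demand


class TestHeuristicCertification:
    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_default_solver_matches_exhaustive_oracle(self, data):
        """Default-mode output achieves the oracle's peak and variance on
        every random instance small enough to enumerate (<= 12 blocks)."""
        horizon, storage, block, demand = _random_small_instance(data.draw)
        while sum(-(-d // block) for d in demand) > 12:
            i = max(range(horizon), key=lambda j: demand[j])
            demand[i] = max(0, demand[i] - block)
        if not any(demand):
            demand[0] = block
        sc = ShipmentScenario("tomato", tuple(demand))
        if enumeration_size(sc, storage, block) > 300_000:
            return
        optimum = enumerate_optimal(sc, storage, block)[0]
        heur = optimize_schedule(sc, storage, block, seed=42)
        assert heur.peak == optimum.peak
        assert heur.variance == pytest.approx(optimum.variance)

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_greedy_descent_optimal_for_uniform_blocks(self, data):
        """The exchange descent itself (no exact fallback) reaches the
        lexicographic optimum whenever all blocks share one size."""
        horizon = data.draw(st.integers(2, 6))
        storage = data.draw(st.integers(1, 4))
        block = 10
        demand = data.draw(
            st.lists(st.sampled_from([0, 10, 20, 30]), min_size=horizon, max_size=horizon)
        )
        while sum(d // block for d in demand) > 12:
            i = max(range(horizon), key=lambda j: demand[j])
            demand[i] = max(0, demand[i] - block)
        if not any(demand):
            demand[0] = block
        sc = ShipmentScenario("tomato", tuple(demand))
        if enumeration_size(sc, storage, block) > 300_000:
            return
        optimum = enumerate_optimal(sc, storage, block)[0]
        heur = optimize_schedule(sc, storage, block, seed=42, method="greedy")
        assert heur.peak == optimum.peak
        assert heur.variance == pytest.approx(optimum.variance)

    @given(data=st.data())
    @settings(max_examples=40, deadline=None)
    def test_conservation_and_monotone_improvement(self, data):
        horizon, storage, block, demand = _random_small_instance(data.draw)
        if not any(demand):
            demand[-1] = block
        sc = ShipmentScenario("tomato", tuple(demand))
        s = optimize_schedule(sc, storage, block, seed=7)
        assert s.total_trays == sc.total_trays  # trays conserve
        assert s.peak <= max(sc.demand)  # never worse than no storage
        # more storage never hurts the optimal peak
        s_more = optimize_schedule(sc, storage + 1, block, seed=7)
        assert s_more.peak <= s.peak

    def test_same_seed_reproduces_schedule(self):
        sc = make_scenario("multi_week_consistent", 10, 60, 3, 3, 8)
        a = optimize_schedule(sc, 3, seed=11)
        b = optimize_schedule(sc, 3, seed=11)
        assert a.assignments == b.assignments


class TestStorageOccupancy:
    def test_identity_schedule_never_stores(self):
        sc = make_scenario("single_peak", 5, 50, 3, 1, 6)
        s = optimize_schedule(sc, 0)
        assert storage_occupancy(s, healing_weeks=1).sum() == 0

    def test_levelled_sixty_occupancy_event_table(self):
        # blocks shifted 2 and 1 weeks overlap in week 3: 20 + 20 trays
        sc = ShipmentScenario("tomato", (0, 0, 60))
        s = optimize_schedule(sc, 2, block_size=10, seed=0)
        occ = storage_occupancy(s, healing_weeks=1)
        assert occ.tolist() == [0, 20, 40, 0]

    def test_single_shifted_block_occupies_shift_weeks(self):
        sc = ShipmentScenario("tomato", (0, 0, 0, 10))
        s = optimize_schedule(sc, 2, block_size=10, seed=0)
        shift = s.assignments[0][0] - s.assignments[0][1]
        occ = storage_occupancy(s, healing_weeks=1)
        assert (occ > 0).sum() == shift
        run = np.flatnonzero(occ)
        assert len(run) == 0 or np.all(np.diff(run) == 1)  # consecutive weeks
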