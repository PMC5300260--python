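"""Weekly production simulator: conservation, reproducibility, noise model."""

import numpy as np
import pytest

from graftsim import (
    make_scenario,
    margin_of_error,
    optimize_schedule,
    replicate_and_summarize,
    run_simulation,
    storage_occupancy,
    summarize_ledger,
    welch_ttest,
)
from graftsim.simulate import SimulationError


class TestDeterministicMode:
    def test_every_demanded_tray_ships_in_its_week(self, tomato, peaked_scenario):
        s = optimize_schedule(peaked_scenario, tomato.max_storage_weeks, seed=0)
        led = run_simulation(peaked_scenario, s, tomato, seed=0, deterministic=True)
        shipped = {l.week: l.trays_shipped for l in led}
        for week, demand in zip(peaked_scenario.weeks, peaked_scenario.demand):
            assert shipped.get(week, 0) == demand

    def test_identity_schedule_never_stores(self, tomato, peaked_scenario):
        s = optimize_schedule(peaked_scenario, 0)
        led = run_simulation(peaked_scenario, s, tomato, seed=0, deterministic=True)
        assert all(l.trays_in_storage == 0 for l in led)

    def test_simulator_occupancy_matches_schedule_module(self, tomato, peaked_scenario):
        s = optimize_schedule(peaked_scenario, tomato.max_storage_weeks, seed=3)
        led = run_simulation(peaked_scenario, s, tomato, seed=0, deterministic=True)
        occ = storage_occupancy(s, tomato.healing_weeks)
        for l in led[: len(occ)]:
            assert l.trays_in_storage == occ[l.week - 1]

    def test_optimized_peak_below_identity_peak(self, tomato, peaked_scenario):
        s_opt = optimize_schedule(peaked_scenario, tomato.max_storage_weeks, seed=0)
        s_id = optimize_schedule(peaked_scenario, 0)
        led_opt = run_simulation(peaked_scenario, s_opt, tomato, seed=0, deterministic=True)
        led_id = run_simulation(peaked_scenario, s_id, tomato, seed=0, deterministic=True)
        assert max(l.trays_grafted for l in led_opt) <= max(l.trays_grafted for l in led_id)

    def test_infeasible_schedule_rejected(self, watermelon, peaked_scenario):
        s = optimize_schedule(peaked_scenario, 4, seed=0)  # needs 4 storage weeks
        with pytest.raises(SimulationError, match="tolerates"):
            run_simulation(peaked_scenario, s, watermelon)


class TestReproducibility:
    def test_same_seed_bit_identical_ledgers(self, tomato, peaked_scenario):
        s = optimize_schedule(peaked_scenario, tomato.max_storage_weeks, seed=1)
        a = run_simulation(peaked_scenario, s, tomato, seed=99)
        b = run_simulation(peaked_scenario, s, tomato, seed=99)
        assert [vars(x) for x in a] == [vars(y) for y in b]

    def test_different_seed_differs_somewhere(self, tomato, peaked_scenario):
        s = optimize_schedule(peaked_scenario, tomato.max_storage_weeks, seed=1)
        a = run_simulation(peaked_scenario, s, tomato, seed=1)
        b = run_simulation(peaked_scenario, s, tomato, seed=2)
        assert [vars(x) for x in a] != [vars(y) for y in b]


class TestNoiseModel:
    def test_monte_carlo_unbiased_shipping(self, tomato):
        """Mean total shipped over 200 stochastic replicates stays within
        2 standard errors of total demand (unbiased survival noise)."""
        sc = make_scenario("single_peak", 10, 60, 4, 1, 6)
        s = optimize_schedule(sc, tomato.max_storage_weeks, seed=0)
        totals = []
        for rep_seed in np.random.SeedSequence(2024).spawn(200):
            led = run_simulation(sc, s, tomato, seed=rep_seed)
            totals.append(sum(l.trays_shipped for l in led))
        mean = np.mean(totals)
        sem = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(mean - sc.total_trays) <= max(2 * sem, 1.0)

    def test_mean_loss_scales_expected_shipping(self, tomato):
        sc = make_scenario("single_peak", 10, 60, 4, 1, 6)
        s = optimize_schedule(sc, 0)
        led = run_simulation(sc, s, tomato, seed=0, deterministic=True, mean_loss_frac=0.10)
        shipped = sum(l.trays_shipped for l in led)
        assert shipped == pytest.approx(0.9 * sc.total_trays, rel=0.05)


class TestReplication:
    def test_margin_of_error_closed_form(self):
        # t(0.975, 4) = 2.776, sd = 1.5811 -> ME = 1.963
        assert margin_of_error([1, 2, 3, 4, 5]) == pytest.approx(1.963, abs=0.001)
        assert margin_of_error([4.0, 4.0, 4.0]) == 0.0

    def test_replicates_required(self, tomato, peaked_scenario):
        s = optimize_schedule(peaked_scenario, 0)
        with pytest.raises(SimulationError):
            replicate_and_summarize(peaked_scenario, s, tomato, n_reps=1)

    def test_summary_shapes_and_determinism(self, tomato, peaked_scenario):
        s = optimize_schedule(peaked_scenario, tomato.max_storage_weeks, seed=5)
        a = replicate_and_summarize(peaked_scenario, s, tomato, n_reps=5, seed=8)
        b = replicate_and_summarize(peaked_scenario, s, tomato, n_reps=5, seed=8)
        assert a.per_week.equals(b.per_week)
        assert a.metrics["mean"].equals(b.metrics["mean"])
        assert len(a.ledgers) == 5

    def test_storage_lowers_peak_workers_significantly(self, tomato, peaked_scenario):
        """Welch test detects the with/without-storage difference in peak
        grafting quantity for a strongly peaked scenario."""
        s_with = optimize_schedule(peaked_scenario, tomato.max_storage_weeks, seed=0)
        s_without = optimize_schedule(peaked_scenario, 0)
        a = replicate_and_summarize(peaked_scenario, s_with, tomato, n_reps=20, seed=3)
        b = replicate_and_summarize(peaked_scenario, s_without, tomato, n_reps=20, seed=3)
        t, p = welch_ttest(
            a.raw_metrics["peak_graft_trays"], b.raw_metrics["peak_graft_trays"]
        )
        assert p <= 0.05
        assert np.mean(a.raw_metrics["peak_graft_trays"]) < np.mean(
            b.raw_metrics["peak_graft_trays"]
        )

    def test_welch_not_testable_for_twin_constants(self):
        assert welch_ttest([2, 2, 2], [2, 2, 2]) is None
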