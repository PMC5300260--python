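"""Learning curve, workforce sizing and labor-cost accounting."""

import math

import pytest
from hypothesis import given, strategies as st

from graftsim import (
    LaborPolicy,
    LearningCurve,
    graft_time,
    plants_per_hour,
    reduction_report,
    size_workforce,
    weekly_labor_cost,
)
from graftsim.labor import LaborError


TOMATO_CURVE = LearningCurve.from_endpoints(36, 12)
WATERMELON_CURVE = LearningCurve.from_endpoints(64, 24)


class TestLearningCurve:
    @pytest.mark.parametrize(
        "curve,day1,expert,pph_day1,pph_expert",
        [
            (TOMATO_CURVE, 36.0, 12.0, 100, 300),
            (WATERMELON_CURVE, 64.0, 24.0, 56, 150),
        ],
    )
    def test_endpoints_and_throughput(self, curve, day1, expert, pph_day1, pph_expert):
        assert graft_time(curve, 1) == pytest.approx(day1)
        assert plants_per_hour(graft_time(curve, 1)) == pph_day1
        assert plants_per_hour(expert) == pph_expert
        assert curve.X == expert

    def test_learning_period_leaves_5pct_of_amplitude(self):
        # after 21 practice days only 5 % of the learnable gap remains
        for curve in (TOMATO_CURVE, WATERMELON_CURVE):
            assert graft_time(curve, 21) - curve.X == pytest.approx(0.05 * curve.N)

    @given(p=st.integers(1, 120))
    def test_monotone_and_bounded_below_by_asymptote(self, p):
        t1 = graft_time(TOMATO_CURVE, p)
        t2 = graft_time(TOMATO_CURVE, p + 1)
        assert TOMATO_CURVE.X <= t2 <= t1 <= TOMATO_CURVE.X + TOMATO_CURVE.N

    def test_practice_below_one_day_rejected(self):
        with pytest.raises(LaborError):
            graft_time(TOMATO_CURVE, 0)


class TestWorkforceSizing:
    def test_zero_min_week_means_no_skilled_crew(self):
        plan = size_workforce([0, 5000, 0], TOMATO_CURVE, 12.0)
        assert all(w.skilled == 0 for w in plan)
        assert plan[1].seasonal > 0

    def test_skilled_sized_from_min_week_arithmetic(self):
        # 100,000 plants/week at 12 s/plant and 40 h weeks -> ceil(8.33) = 9
        plan = size_workforce([100_000, 120_000], TOMATO_CURVE, 12.0)
        assert plan[0].skilled == math.ceil(100_000 * 12 / (40 * 3600)) == 9

    def test_migrants_hired_beyond_seasonal_cap(self):
        from graftsim.labor import _Worker, _weekly_capacity

        policy = LaborPolicy()
        novice_cap = _weekly_capacity(_Worker(), TOMATO_CURVE, policy)
        # one enormous week needing ~60 novice workers: 50 seasonal + migrants
        plants = int(novice_cap * 59.5)
        plan = size_workforce([0, plants], TOMATO_CURVE, 12.0, policy)
        week = plan[1]
        assert week.seasonal == 50
        assert week.migrant >= 1
        assert week.seasonal + week.migrant > 50

    def test_weekly_capacity_covers_planned_quantity(self):
        plan = size_workforce([3000, 9000, 27000, 5000], TOMATO_CURVE, 12.0)
        for week in plan:
            assert week.capacity_plants >= week.plants

    def test_retained_workers_speed_up_released_reset(self):
        # constant demand: retained crew shrinks as each worker speeds up
        plan = size_workforce([8000] * 6, TOMATO_CURVE, 12.0)
        counts = [w.seasonal + w.migrant for w in plan]
        assert counts[0] >= counts[-1]
        # an idle week releases everyone; rehires start slow again
        plan2 = size_workforce([8000, 0, 8000], TOMATO_CURVE, 12.0)
        assert plan2[2].seasonal + plan2[2].migrant == plan2[0].seasonal + plan2[0].migrant


class TestCosts:
    def test_zero_workers_zero_cost(self):
        assert weekly_labor_cost(0, 0, 0, 0, LaborPolicy()) == 0.0

    def test_seasonal_week_cost_closed_form(self):
        # 7.80 $/h * 40 h * 1.25 fringe = 390 $
        assert weekly_labor_cost(0, 1, 0, 0, LaborPolicy()) == pytest.approx(390.00)

    def test_migrant_first_week_cost_closed_form(self):
        # wage 312 + 7 housed days * 17.50 + 500 transport = 934.50 $
        assert weekly_labor_cost(0, 0, 1, 1, LaborPolicy()) == pytest.approx(934.50)

    def test_migrant_transport_charged_once(self):
        from graftsim.labor import _Worker, _weekly_capacity

        novice_cap = _weekly_capacity(_Worker(), TOMATO_CURVE, LaborPolicy())
        plants = int(novice_cap * 59.5)
        plan = size_workforce([0, plants, plants], TOMATO_CURVE, 12.0)
        assert plan[1].new_migrants >= 1
        assert plan[2].new_migrants == 0  # same migrants retained

    def test_cost_audit_sums_over_worker_classes(self):
        plan = size_workforce([4000, 16000, 4000], TOMATO_CURVE, 12.0)
        policy = LaborPolicy()
        for week in plan:
            assert week.labor_cost_usd == pytest.approx(
                weekly_labor_cost(
                    week.skilled, week.seasonal, week.migrant, week.new_migrants, policy
                )
            )


class TestReductionReport:
    def test_printed_table_rows_reproduce_abstract_extremes(self):
        # peak labor 46 -> 23 is a 50 % reduction; peak cost 0.157 -> 0.110 is 30 %
        r = reduction_report({"labor": 23, "cost": 0.110}, {"labor": 46, "cost": 0.157})
        assert r == {"labor": 50, "cost": 30}

    def test_identical_ledgers_zero_reduction(self):
        assert reduction_report({"x": 5.0}, {"x": 5.0}) == {"x": 0}

    def test_zero_denominator_rejected(self):
        with pytest.raises(LaborError):
            reduction_report({"x": 1.0}, {"x": 0.0})
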