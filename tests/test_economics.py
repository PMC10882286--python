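"""Costing, QALY accounting, net monetary benefit and the frontier."""

import numpy as np
import pytest

from tpxcea import (
    CeResult,
    build_frontier,
    evaluate_strategy,
    net_monetary_benefit,
    padua_point,
    strategy_all,
    strategy_none,
    strategy_ram,
)

from conftest import flat_life_table


class TestCosts:
    def test_no_treatment_no_events_costs_nothing(self, zero_risk_params):
        res = evaluate_strategy(strategy_none(), zero_risk_params)
        assert float(res.cost) == pytest.approx(0.0, abs=1e-9)

    def test_treat_all_no_events_costs_one_course(self, zero_risk_params):
        res = evaluate_strategy(strategy_all(), zero_risk_params)
        assert float(res.cost) == pytest.approx(23.91, abs=1e-9)

    @pytest.mark.parametrize("threshold", [1, 4, 7])
    def test_ram_assessment_cost_applies_to_everyone(self, zero_risk_params, threshold):
        op = padua_point(threshold)
        res = evaluate_strategy(strategy_ram(op), zero_risk_params)
        # with zero prevalence the treated fraction is the false-positive rate
        expected = 9.08 + (1 - op.specificity) * 23.91
        assert float(res.cost) == pytest.approx(expected, abs=1e-9)

    def test_seven_day_course_costs_extra_days(self, zero_risk_params):
        zero_risk_params.cohort.tpx_days = 7.0
        res = evaluate_strategy(strategy_all(), zero_risk_params)
        assert float(res.cost) == pytest.approx(23.91 + 2 * 23.91 / 5, abs=1e-9)


class TestQalys:
    def test_event_free_year_at_point_eight(self, zero_risk_params):
        """No events, utility 0.8, zero discounting, one-year horizon: the
        cohort accrues exactly 0.8 QALYs."""
        ps = zero_risk_params
        ps.cohort.discount_rate = 0.0
        ps.life_table = flat_life_table(0.0)
        res = evaluate_strategy(strategy_none(), ps, horizon=1.0)
        assert float(res.qalys) == pytest.approx(0.8, abs=1e-12)

    def test_prophylaxis_decrement_closed_form(self, zero_risk_params):
        ps = zero_risk_params
        ps.cohort.discount_rate = 0.0
        ps.life_table = flat_life_table(0.0)
        none = evaluate_strategy(strategy_none(), ps, horizon=1.0)
        all_ = evaluate_strategy(strategy_all(), ps, horizon=1.0)
        # 0.007 for five of 365.25 days
        assert float(none.qalys - all_.qalys) == pytest.approx(0.007 * 5 / 365.25, abs=1e-12)

    def test_null_effect_makes_none_the_unique_frontier_point(self, params, strategies):
        params.effects.rr_vte = 1.0
        params.effects.rr_bleed = 1.0
        results = [evaluate_strategy(s, params) for s in strategies]
        frontier = build_frontier(results)
        assert frontier.frontier_labels() == ["None"]


class TestNmb:
    def test_lambda_zero_is_negative_cost(self):
        r = CeResult("x", cost=100.0, qalys=2.0)
        assert net_monetary_benefit(r, 0.0) == -100.0

    def test_linear_in_lambda(self):
        r = CeResult("x", cost=100.0, qalys=2.0)
        lams = [0.0, 10.0, 20.0, 30.0]
        nmbs = [net_monetary_benefit(r, lam) for lam in lams]
        diffs = np.diff(nmbs)
        assert np.allclose(diffs, diffs[0])

    def test_reported_increment_arithmetic(self):
        # published increments: +0.0552 QALYs and -£28.44 for treat-all
        a = CeResult("all", cost=216.49, qalys=9.0585)
        b = CeResult("none", cost=216.49 + 28.44, qalys=9.0585 - 0.0552)
        dnmb = net_monetary_benefit(a, 20_000.0) - net_monetary_benefit(b, 20_000.0)
        assert dnmb == pytest.approx(20_000 * 0.0552 + 28.44, abs=1e-9)


BASE_CASE_TABLE = [
    # (strategy, cost, qalys) — published base-case columns
    ("None", 244.93, 9.0033),
    ("Padua >=7", 251.40, 9.0061),
    ("Padua >=6", 249.09, 9.0087),
    ("Padua >=5", 244.81, 9.0141),
    ("Padua >=4", 235.91, 9.0243),
    ("Padua >=3", 231.70, 9.0311),
    ("Padua >=2", 227.79, 9.0417),
    ("Padua >=1", 224.43, 9.0544),
    ("All inpatients", 216.49, 9.0585),
]

ELIAS_TABLE = [
    ("None", 242.95, 9.0031),
    ("Padua >=7", 220.57, 9.0351),
    ("Padua >=6", 212.07, 9.0471),
    ("Padua >=5", 212.90, 9.0510),
    ("Padua >=4", 211.68, 9.0567),
    ("Padua >=3", 215.49, 9.0586),
    ("Padua >=2", 217.03, 9.0586),
    ("Padua >=1", 220.41, 9.0583),
    ("All inpatients", 215.31, 9.0580),
]


class TestFrontier:
    def test_two_strategy_dominance(self):
        frontier = build_frontier(
            [CeResult("A", 10.0, 2.0), CeResult("B", 20.0, 1.5)]
        )
        assert frontier.status_of("B") == "dominated_by A"
        assert frontier.frontier_labels() == ["A"]

    def test_published_base_case_all_dominates(self):
        frontier = build_frontier([CeResult(*row) for row in BASE_CASE_TABLE])
        assert frontier.frontier_labels() == ["All inpatients"]
        for label, _, _ in BASE_CASE_TABLE[:-1]:
            assert frontier.status_of(label) == "dominated_by All inpatients"

    def test_published_elias_scenario_labels(self):
        frontier = build_frontier([CeResult(*row) for row in ELIAS_TABLE])
        assert frontier.frontier_labels() == ["Padua >=4", "Padua >=3"]
        assert frontier.status_of("All inpatients") == "extendedly_dominated"
        for label in ("None", "Padua >=7", "Padua >=6", "Padua >=5"):
            assert frontier.status_of(label) == "dominated_by Padua >=4"
        for label in ("Padua >=2", "Padua >=1"):
            assert frontier.status_of(label) == "dominated_by Padua >=3"

    def test_frontier_icers_strictly_increase(self):
        frontier = build_frontier([CeResult(*row) for row in ELIAS_TABLE])
        icers = [
            e.icer_vs_previous
            for e in frontier.entries
            if e.status == "frontier" and e.icer_vs_previous is not None
        ]
        assert all(a < b for a, b in zip(icers, icers[1:]))

    def test_exact_ties_keep_first_listed(self):
        frontier = build_frontier(
            [CeResult("A", 10.0, 2.0), CeResult("B", 10.0, 2.0), CeResult("C", 30.0, 1.0)]
        )
        assert frontier.status_of("A") == "frontier"
        assert frontier.status_of("B") == "dominated_by A"


class TestFullPipeline:
    def test_treat_all_dominates_none_deterministically(self, base_params):
        none = evaluate_strategy(strategy_none(), base_params)
        all_ = evaluate_strategy(strategy_all(), base_params)
        assert float(all_.qalys) > float(none.qalys)
        assert float(all_.cost) < float(none.cost)

    def test_removing_ram_cost_never_hurts_ram_strategy(self, params):
        s = strategy_ram(padua_point(3))
        with_cost = evaluate_strategy(s, params)
        params.costs.c_ram = 0.0
        without = evaluate_strategy(s, params)
        assert float(with_cost.cost - without.cost) == pytest.approx(9.08, abs=1e-9)
        assert float(with_cost.qalys) == pytest.approx(float(without.qalys), rel=1e-12)
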