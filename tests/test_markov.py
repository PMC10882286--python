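"""Chronic-complication assignment, mortality layering and the Markov
trace."""

import numpy as np
import pytest

from tpxcea import (
    ValidationError,
    assign_chronic_complications,
    discount_factor,
    mortality_schedule,
    run_decision_tree,
    run_markov,
    strategy_none,
)
from tpxcea.markov import ALIVE_STATES, STATES

from conftest import flat_life_table


def initial_all(state):
    occ = {s: 0.0 for s in STATES}
    occ[state] = 1.0
    return occ


class TestChronicAssignment:
    def test_pts_entrants_closed_form(self, base_params):
        """Hand calculation: symptomatic DVT 202.0 x (0.6*0.324 + 0.4*0.156)
        + asymptomatic 3046.0 x (0.2*0.565 + 0.8*0.156) = 776.2 per 10,000
        under no prophylaxis."""
        o = run_decision_tree(strategy_none(), base_params)
        occ = assign_chronic_complications(o, base_params)
        assert 1e4 * occ["pts"] == pytest.approx(776.21, abs=0.05)

    def test_pts_count_within_5pct_of_reported(self, base_params):
        # cumulative PTS incidence for no prophylaxis: reported 787/10,000
        o = run_decision_tree(strategy_none(), base_params)
        occ = assign_chronic_complications(o, base_params)
        assert abs(1e4 * occ["pts"] - 787) / 787 < 0.05

    def test_zero_pts_risk_zero_entrants(self, params):
        for k in ("pts_sympt_prox", "pts_asympt_prox", "pts_distal"):
            setattr(params.risks, k, 0.0)
        o = run_decision_tree(strategy_none(), params)
        assert assign_chronic_complications(o, params)["pts"] == 0.0

    def test_asymptomatic_distal_term_droppable(self, params):
        o = run_decision_tree(strategy_none(), params)
        base_pts = assign_chronic_complications(o, params)["pts"]
        params.risks.pts_distal_asympt = 0.0
        reduced = assign_chronic_complications(o, params)["pts"]
        advt = float(o.asympt_dvt) / 1e4
        dropped = advt * (1 - params.risks.frac_prox_asympt) * params.risks.pts_distal
        assert base_pts - reduced == pytest.approx(dropped, rel=1e-9)

    def test_occupancy_sums_to_one(self, base_params):
        o = run_decision_tree(strategy_none(), base_params)
        occ = assign_chronic_complications(o, base_params)
        assert sum(occ.values()) == pytest.approx(1.0, abs=1e-12)


class TestMortalitySchedule:
    def test_smr_one_equals_life_table(self, params):
        params.mortality.smr_year1 = 1.0
        params.mortality.smr_ich_y1 = 1.0
        params.mortality.smr_ich_y2to6 = 1.0
        params.mortality.cteph_mortality_multiplier = 1.0
        for t in (0.5, 1.0, 5.0, 20.0):
            q = mortality_schedule(
                65.8, 0.445, params.life_table, params.mortality, "well_no_event", t
            )
            assert q == pytest.approx(params.life_table.annual_q(65.8 + t, 0.445))

    def test_first_year_multiplier(self, base_params):
        q = mortality_schedule(
            65.8, 0.445, base_params.life_table, base_params.mortality, "well_no_event", 0.5
        )
        base = base_params.life_table.annual_q(66.3, 0.445)
        assert q == pytest.approx(min(1.0, 9.4 * base))

    def test_post_ich_years_2_to_6(self, base_params):
        q = mortality_schedule(
            65.8, 0.445, base_params.life_table, base_params.mortality, "post_ich", 3.0
        )
        assert q == pytest.approx(2.2 * base_params.life_table.annual_q(68.8, 0.445))

    def test_age_cap_terminal(self, base_params):
        q = mortality_schedule(
            65.8, 0.445, base_params.life_table, base_params.mortality, "well_no_event", 40.0
        )
        assert q == 1.0


class TestMarkovTrace:
    def test_all_dead_is_absorbing(self, base_params):
        trace = run_markov(initial_all("dead"), base_params)
        for c in trace.cycles:
            assert c.occupancy["dead"] == 1.0
            assert all(c.occupancy[s] == 0.0 for s in ALIVE_STATES)

    def test_conservation_and_monotone_death(self, base_params):
        o = run_decision_tree(strategy_none(), base_params)
        trace = run_markov(assign_chronic_complications(o, base_params), base_params)
        trace.check_conservation()
        dead = [float(c.occupancy["dead"]) for c in trace.cycles]
        assert all(b >= a for a, b in zip(dead, dead[1:]))

    def test_zero_mortality_constant_occupancy(self, params):
        params.life_table = flat_life_table(0.0)
        params.cohort.age_cap = 80.0  # keep the run finite
        trace = run_markov(initial_all("well_no_event"), params, horizon=10)
        for c in trace.cycles:
            assert c.occupancy["well_no_event"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_hazard_geometric_decay(self, params):
        """Flat life table with SMR 1 everywhere: occupancy at annual cycle
        ends must follow (1-q1)(1-q)^k exactly."""
        q = 0.1
        params.life_table = flat_life_table(q)
        for k in ("smr_year1", "smr_ich_y1", "smr_ich_y2to6", "cteph_mortality_multiplier"):
            setattr(params.mortality, k, 1.0)
        trace = run_markov(initial_all("well_no_event"), params, horizon=10)
        # cycle 1 applies the full first-year q at its start
        expected = 1.0 - q
        assert trace.cycles[0].occupancy["well_no_event"] == pytest.approx(expected, rel=1e-12)
        for c in trace.cycles[1:]:
            expected *= 1.0 - q
            assert c.occupancy["well_no_event"] == pytest.approx(expected, rel=1e-12)
            # half-cycle correction: accrual occupancy at the mid-cycle level
            assert c.mean_occupancy["well_no_event"] == pytest.approx(
                c.occupancy["well_no_event"] / (1 - q) * (1 - q / 2), rel=1e-12
            )

    def test_unnormalised_initial_rejected(self, base_params):
        bad = initial_all("well_no_event")
        bad["dead"] = 0.5
        with pytest.raises(ValidationError):
            run_markov(bad, base_params)


class TestDiscounting:
    def test_closed_forms(self):
        assert discount_factor(0.0, 0.035) == 1.0
        assert discount_factor(1.0, 0.035) == pytest.approx(0.96618, abs=1e-5)
        assert discount_factor(10.0, 0.035) == pytest.approx(0.70892, abs=1e-5)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            discount_factor(-1.0, 0.035)


def test_smr_one_reproduces_life_table_life_expectancy(params):
    """With all SMRs at 1 the model's undiscounted person-years equal the
    life expectancy computed directly from the life table (deaths at six
    months in year one, mid-year thereafter)."""
    for k in ("smr_year1", "smr_ich_y1", "smr_ich_y2to6", "cteph_mortality_multiplier"):
        setattr(params.mortality, k, 1.0)
    trace = run_markov(initial_all("well_no_event"), params)
    model_le = 0.5 + sum(trace.person_years(s) for s in ALIVE_STATES)

    # direct life-table computation
    lt, age0, fm = params.life_table, params.cohort.age0, params.cohort.frac_male
    q0 = lt.annual_q(age0, fm)
    le = 0.5 + 0.5 * (1 - q0)
    surv = 1 - q0
    k = 1
    while surv > 1e-15 and k < 200:
        age = age0 + k
        q = 1.0 if age >= params.cohort.age_cap else lt.annual_q(age, fm)
        le += surv * (1 - q / 2)
        surv *= 1 - q
        k += 1
    assert model_le == pytest.approx(le, abs=0.1)
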