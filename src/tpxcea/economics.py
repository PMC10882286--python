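"""Economic layer: attach costs and utilities to the six-month tree and the
lifetime Markov trace, and build the incremental cost-effectiveness
frontier.

All costs are 2020 GBP from the NHS and Personal Social Services
perspective; QALYs and costs are discounted at the cohort's annual rate
using cycle-midpoint times.  Prophylaxis and risk-assessment costs fall at
admission (t = 0); acute event costs and tree-phase utility effects are
discounted to the middle of the six-month tree phase (t = 0.25); chronic
entry lumps fall at Markov entry (t = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from .markov import (
    MarkovTrace,
    assign_chronic_complications,
    discount_factor,
    run_markov,
)
from .parameters import ParameterSet
from .tree import SixMonthOutcomes, StrategySpec, run_decision_tree

__all__ = [
    "CeResult",
    "Frontier",
    "FrontierEntry",
    "strategy_cost",
    "strategy_qalys",
    "evaluate_strategy",
    "build_frontier",
    "net_monetary_benefit",
    "ce_table",
]

_PER = 1.0 / 10_000.0


@dataclass
class CeResult:
    strategy: str
    cost: Any  # discounted lifetime cost per patient
    qalys: Any  # discounted lifetime QALYs per patient


def _tree_phase_cost(outcomes: SixMonthOutcomes, params: ParameterSet, strategy: StrategySpec):
    c = params.costs
    coh = params.cohort
    r = params.risks
    d_event = discount_factor(0.25, coh.discount_rate)

    cost = 0.0
    if strategy.kind == "ram":
        cost = cost + c.c_ram
    extra_days = np.maximum(0.0, np.asarray(coh.tpx_days) - 5.0)
    course = c.c_tpx_course + extra_days * (c.c_tpx_per_extra_day + c.c_tpx_extra_day_admin)
    cost = cost + outcomes.treated_fraction * course

    adj = c.anticoag_cost_adjustment(coh.doac_fraction)
    sdvt_cost = r.frac_prox_sympt * (c.c_sdvt_prox + adj) + (1.0 - r.frac_prox_sympt) * (
        c.c_sdvt_distal + adj
    )
    events = (
        outcomes.sympt_dvt * sdvt_cost
        + outcomes.nonfatal_pe * (c.c_pe_nonfatal + adj)
        + outcomes.fatal_pe * c.c_pe_fatal
        + (outcomes.hosp_fatal_bleed + outcomes.tx_fatal_bleed) * c.c_bleed_fatal
        + (outcomes.hosp_other_bleed + outcomes.tx_other_bleed) * c.c_bleed_other
        + (outcomes.hosp_ich + outcomes.tx_ich) * c.c_ich_first90d
    ) * _PER
    return cost + events * d_event


def _tree_phase_qalys(outcomes: SixMonthOutcomes, params: ParameterSet):
    """Expected QALYs over months 0-6.

    Everyone starts the phase at the year-1 background utility; event
    groups swap to their acute utility for the phase (one month for
    non-intracranial bleeds), decedents receive half-phase credit, and the
    prophylaxis and anticoagulation decrements apply for their actual
    durations.  Asymptomatic DVT is undiagnosed and untreated, so carries
    no acute decrement.
    """
    u = params.utilities
    coh = params.cohort
    base = np.asarray(u.u_well_y1)

    q = 0.5 * base  # half a year for the whole cohort
    q = q - outcomes.deaths * _PER * base * 0.25  # decedents get half credit
    q = q - outcomes.sympt_dvt * _PER * (base - u.u_dvt_6m) * 0.5
    q = q - outcomes.nonfatal_pe * _PER * (base - u.u_pe_6m) * 0.5
    q = q - (outcomes.hosp_ich + outcomes.tx_ich) * _PER * (base - u.u_ich_6m) * 0.5
    q = q - (outcomes.hosp_other_bleed + outcomes.tx_other_bleed) * _PER * (
        base - u.u_bleed_other_1m
    ) * (1.0 / 12.0)
    q = q - outcomes.treated_fraction * u.tpx_decrement * (np.asarray(coh.tpx_days) / 365.25)
    q = q - outcomes.n_on_treatment * _PER * u.anticoag_decrement * 0.25
    return q * discount_factor(0.25, coh.discount_rate)


_STATE_COST_KEYS = {
    "pts": "c_pts_annual",
    "cteph_medical": "c_cteph_med_annual",
    "post_ich": "c_ich_annual",
}

_STATE_MULT_KEYS = {
    "pts": "mult_pts",
    "cteph_medical": "mult_cteph",
    "cteph_surgical": "mult_cteph",
    "post_ich": "mult_ich",
}


def _fill_markov_increments(trace: MarkovTrace, initial: dict, params: ParameterSet) -> None:
    """Compute per-cycle discounted cost and QALY increments in place."""
    c = params.costs
    u = params.utilities
    coh = params.cohort
    for cyc in trace.cycles:
        length = cyc.t_end - cyc.t_start
        df = discount_factor(cyc.t_discount, coh.discount_rate)
        cost = 0.0
        for state, key in _STATE_COST_KEYS.items():
            cost = cost + cyc.mean_occupancy[state] * getattr(c, key)
        qaly = 0.0
        if cyc.t_start < 1.0:
            u_base = np.asarray(u.u_well_y1)
        else:
            u_base = u.utility_well(coh.age0 + cyc.t_discount, coh.age0)
        for state in (
            "well_no_event",
            "well_post_dvt",
            "well_post_pe",
            "pts",
            "cteph_medical",
            "cteph_surgical",
            "post_ich",
        ):
            mult = getattr(u, _STATE_MULT_KEYS[state]) if state in _STATE_MULT_KEYS else 1.0
            qaly = qaly + cyc.mean_occupancy[state] * u_base * mult
        cyc.cost_increment = cost * length * df
        cyc.qaly_increment = qaly * length * df


def strategy_cost(
    outcomes: SixMonthOutcomes,
    trace: MarkovTrace,
    params: ParameterSet,
    strategy: StrategySpec,
    initial: dict | None = None,
):
    """Discounted lifetime cost per patient for one strategy."""
    if initial is None:
        initial = assign_chronic_complications(outcomes, params)
    if trace.cycles and trace.cycles[0].cost_increment is None:
        _fill_markov_increments(trace, initial, params)
    c = params.costs
    d_entry = discount_factor(0.5, params.cohort.discount_rate)
    lumps = (
        initial["pts"] * (c.c_pts_y1 - c.c_pts_annual)
        + initial["cteph_surgical"] * c.c_cteph_surg_y1
    ) * d_entry
    markov = sum(cyc.cost_increment for cyc in trace.cycles) if trace.cycles else 0.0
    return _tree_phase_cost(outcomes, params, strategy) + lumps + markov


def strategy_qalys(
    outcomes: SixMonthOutcomes,
    trace: MarkovTrace,
    params: ParameterSet,
    strategy: StrategySpec,
    initial: dict | None = None,
):
    """Discounted lifetime QALYs per patient for one strategy."""
    if initial is None:
        initial = assign_chronic_complications(outcomes, params)
    if trace.cycles and trace.cycles[0].qaly_increment is None:
        _fill_markov_increments(trace, initial, params)
    markov = sum(cyc.qaly_increment for cyc in trace.cycles) if trace.cycles else 0.0
    return _tree_phase_qalys(outcomes, params) + markov


def evaluate_strategy(
    strategy: StrategySpec,
    params: ParameterSet,
    horizon: float | None = None,
    detail: bool = False,
):
    """Full pipeline for one strategy: tree, chronic assignment, Markov,
    costs and QALYs.  Returns a :class:`CeResult` (plus the intermediate
    objects when ``detail`` is true)."""
    outcomes = run_decision_tree(strategy, params)
    initial = assign_chronic_complications(outcomes, params)
    trace = run_markov(initial, params, horizon=horizon)
    _fill_markov_increments(trace, initial, params)
    result = CeResult(
        strategy=strategy.label,
        cost=strategy_cost(outcomes, trace, params, strategy, initial),
        qalys=strategy_qalys(outcomes, trace, params, strategy, initial),
    )
    if detail:
        return result, outcomes, initial, trace
    return result


def net_monetary_benefit(result: CeResult, lam: float):
    """lambda * QALYs - cost at willingness-to-pay ``lam`` (GBP/QALY)."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return lam * result.qalys - result.cost


# ---------------------------------------------------------------------------
# Frontier
# ---------------------------------------------------------------------------


@dataclass
class FrontierEntry:
    strategy: str
    cost: float
    qalys: float
    status: str  # "frontier", "dominated_by <X>" or "extendedly_dominated"
    icer_vs_previous: float | None = None


@dataclass
class Frontier:
    entries: list[FrontierEntry]

    def frontier_labels(self) -> list[str]:
        return [e.strategy for e in self.entries if e.status == "frontier"]

    def status_of(self, label: str) -> str:
        for e in self.entries:
            if e.strategy == label:
                return e.status
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


def build_frontier(results: list[CeResult]) -> Frontier:
    """Incremental cost-effectiveness frontier with dominance labelling.

    Strictly dominated strategies (another strategy has no fewer QALYs for
    lower cost, or more QALYs for no more cost) are labelled with their
    cheapest dominator; extendedly dominated strategies (ICER exceeding the
    next frontier ICER) are removed iteratively; frontier members carry the
    ICER against the previous frontier member.  Exact ties on both axes
    keep the first-listed strategy.
    """
    if len(results) < 2:
        raise ValueError("need at least two strategies to build a frontier")
    entries = [FrontierEntry(r.strategy, float(r.cost), float(r.qalys), "frontier") for r in results]

    # strict (including weak) dominance, cheapest dominator named
    for e in entries:
        dominators = []
        for o in entries:
            if o is e:
                continue
            better = (o.qalys >= e.qalys and o.cost < e.cost) or (
                o.qalys > e.qalys and o.cost <= e.cost
            )
            if better:
                dominators.append(o)
            elif (
                o.qalys == e.qalys
                and o.cost == e.cost
                and entries.index(o) < entries.index(e)
            ):
                dominators.append(o)  # exact tie: first-listed wins
        if dominators:
            cheapest = min(dominators, key=lambda o: (o.cost, -o.qalys))
            e.status = f"dominated_by {cheapest.strategy}"

    def _candidates():
        return sorted(
            (e for e in entries if e.status == "frontier"),
            key=lambda e: (e.qalys, e.cost),
        )

    # extended dominance: ICERs along the frontier must strictly increase
    changed = True
    while changed:
        changed = False
        cand = _candidates()
        icers = [
            (cand[i + 1].cost - cand[i].cost) / (cand[i + 1].qalys - cand[i].qalys)
            for i in range(len(cand) - 1)
        ]
        for i in range(len(icers) - 1):
            if icers[i] >= icers[i + 1]:
                cand[i + 1].status = "extendedly_dominated"
                changed = True
                break

    cand = _candidates()
    for i, e in enumerate(cand):
        if i == 0:
            e.icer_vs_previous = None
        else:
            e.icer_vs_previous = (e.cost - cand[i - 1].cost) / (e.qalys - cand[i - 1].qalys)
    ordered = sorted(entries, key=lambda e: (e.qalys, e.cost))
    return Frontier(ordered)


def ce_table(
    strategies: list[StrategySpec],
    params: ParameterSet,
    horizon: float | None = None,
) -> pd.DataFrame:
    """Cost-effectiveness table: one row per strategy with treated percent,
    operating point, discounted cost/QALYs and frontier status."""
    results = []
    rows = []
    for s in strategies:
        res, outcomes, _, _ = evaluate_strategy(s, params, horizon=horizon, detail=True)
        results.append(res)
        op = s.operating_point
        sens = {"none": 0.0, "all": 1.0}.get(s.kind, op.sensitivity if op else None)
        spec = {"none": 1.0, "all": 0.0}.get(s.kind, op.specificity if op else None)
        rows.append(
            {
                "strategy": s.label,
                "tpx_pct": 100.0 * float(np.asarray(outcomes.treated_fraction)),
                "sensitivity_pct": 100.0 * sens,
                "specificity_pct": 100.0 * spec,
                "cost": float(np.asarray(res.cost)),
                "qalys": float(np.asarray(res.qalys)),
            }
        )
    frontier = build_frontier(results)
    df = pd.DataFrame(rows)
    df["status"] = [frontier.status_of(label) for label in df["strategy"]]
    df["icer_vs_previous"] = [
        next(e.icer_vs_previous for e in frontier.entries if e.strategy == label)
        for label in df["strategy"]
    ]
    return df
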