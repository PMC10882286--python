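"""Lifetime Markov extrapolation of the six-month cohort.

Eight states: well with no event history, well after DVT, well after PE,
post-thrombotic syndrome (PTS), medically and surgically managed chronic
thromboembolic pulmonary hypertension (CTEPH), post intracranial
haemorrhage (ICH), and dead.  Chronic complications are assigned once, at
entry to the Markov phase (diagnosis deferred to the end of the decision
tree), and the only subsequent transition is death, at a state-specific
multiple of general-population mortality.

Cycle structure follows the decision-tree handover: a six-month cycle
spanning months 6-12 with the full first-year all-cause mortality applied
at its start (at six months), then annual cycles with half-cycle-corrected
occupancy (transitions at mid-cycle) up to the age cap.  Discounting uses
cycle midpoint times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .parameters import ParameterSet, ValidationError
from .tree import SixMonthOutcomes

__all__ = [
    "STATES",
    "ALIVE_STATES",
    "MarkovCycle",
    "MarkovTrace",
    "assign_chronic_complications",
    "mortality_schedule",
    "run_markov",
    "discount_factor",
]

STATES = (
    "well_no_event",
    "well_post_dvt",
    "well_post_pe",
    "pts",
    "cteph_medical",
    "cteph_surgical",
    "post_ich",
    "dead",
)
ALIVE_STATES = STATES[:-1]


def discount_factor(t, rate):
    """Present-value factor (1 + rate)^(-t) for a time ``t`` in years."""
    if np.any(np.asarray(t) < 0):
        raise ValidationError("discount time must be non-negative")
    return (1.0 + rate) ** (-np.asarray(t, dtype=float))


def assign_chronic_complications(outcomes: SixMonthOutcomes, params: ParameterSet) -> dict:
    """Initial Markov occupancy (per patient) from six-month event counts.

    PTS entrants come from DVT survivors weighted by location and symptom
    status; CTEPH entrants are PE survivors times the cumulative two-year
    incidence, split into medical and surgical management; ICH survivors
    (hospital and treatment phase) enter the post-ICH state.  The full
    cumulative PTS/CTEPH risks are applied at entry.
    """
    r = params.risks
    per = 1.0 / 10_000.0

    sdvt = outcomes.sympt_dvt * per
    advt = outcomes.asympt_dvt * per
    nonfatal_pe = outcomes.nonfatal_pe * per

    pts = sdvt * (
        r.frac_prox_sympt * r.pts_sympt_prox + (1.0 - r.frac_prox_sympt) * r.pts_distal
    ) + advt * (
        r.frac_prox_asympt * r.pts_asympt_prox
        + (1.0 - r.frac_prox_asympt) * r.pts_distal_asympt_effective
    )
    cteph = nonfatal_pe * r.p_cteph
    cteph_surg = cteph * r.frac_cteph_surgical
    cteph_med = cteph - cteph_surg
    post_ich = (outcomes.hosp_ich + outcomes.tx_ich) * per
    dead = outcomes.deaths * per

    if np.any(np.asarray(pts) > np.asarray(sdvt + advt)) or np.any(
        np.asarray(cteph) > np.asarray(nonfatal_pe)
    ):
        raise ValidationError("chronic-state entrants exceed their source counts")

    well_post_pe = nonfatal_pe - cteph
    well_post_dvt = sdvt + advt - pts
    occ = {
        "well_post_dvt": well_post_dvt,
        "well_post_pe": well_post_pe,
        "pts": pts,
        "cteph_medical": cteph_med,
        "cteph_surgical": cteph_surg,
        "post_ich": post_ich,
        "dead": dead,
    }
    occ["well_no_event"] = 1.0 - sum(occ.values())
    if np.any(np.asarray(occ["well_no_event"]) < 0):
        raise ValidationError("event fractions exceed the cohort")
    return {s: occ[s] for s in STATES}


def mortality_schedule(
    age0: float,
    frac_male: float,
    life_table,
    mort,
    state: str,
    years_since_event: float,
    age_cap: float = 100.0,
):
    """Annual death probability for a state at ``years_since_event`` after
    admission (events occur at the start of follow-up).

    The cohort-wide first-year SMR applies to every state in the first
    year; post-ICH carries its own multiplier in years 2-6; the CTEPH
    multiplier applies throughout time in state.  Probabilities are capped
    at 1, and q = 1 at or beyond the age cap.
    """
    t = years_since_event
    age = age0 + t
    if age >= age_cap:
        return 1.0
    q = life_table.annual_q(age, frac_male)
    if state == "dead":
        return 0.0
    mult = 1.0
    if t < 1.0:
        mult = mort.smr_ich_y1 if state == "post_ich" else mort.smr_year1
    elif state == "post_ich" and t < 6.0:
        mult = mort.smr_ich_y2to6
    if state in ("cteph_medical", "cteph_surgical"):
        mult = mult * np.asarray(mort.cteph_mortality_multiplier)
    return np.minimum(1.0, q * mult)


@dataclass
class MarkovCycle:
    t_start: float
    t_end: float
    occupancy: dict  # at cycle end
    mean_occupancy: dict  # used for accrual (half-cycle corrected)
    t_discount: float  # midpoint
    cost_increment: Any = None  # discounted; filled by the economics layer
    qaly_increment: Any = None


@dataclass
class MarkovTrace:
    cycles: list[MarkovCycle] = field(default_factory=list)

    def check_conservation(self, atol: float = 1e-10) -> None:
        for c in self.cycles:
            total = sum(c.occupancy.values())
            if np.any(np.abs(np.asarray(total) - 1.0) > atol):
                raise ValidationError("occupancy does not sum to 1")

    def person_years(self, state: str):
        """Undiscounted person-years accrued in ``state`` over the trace."""
        return sum(c.mean_occupancy[state] * (c.t_end - c.t_start) for c in self.cycles)

    def occupancy_at(self, t: float) -> dict:
        """Occupancy at the end of the last cycle closing at or before ``t``."""
        chosen = None
        for c in self.cycles:
            if c.t_end <= t + 1e-9:
                chosen = c
        if chosen is None:
            raise ValueError("time precedes the first Markov cycle")
        return chosen.occupancy

    def to_frame(self):
        import pandas as pd

        rows = []
        for c in self.cycles:
            for s in STATES:
                rows.append(
                    {
                        "t_start": c.t_start,
                        "t_end": c.t_end,
                        "state": s,
                        "occupancy": np.asarray(c.occupancy[s]).mean(),
                    }
                )
        return pd.DataFrame(rows)


def run_markov(
    initial: dict,
    params: ParameterSet,
    horizon: float | None = None,
) -> MarkovTrace:
    """Run the Markov extrapolation from six months to the horizon.

    ``initial`` is the occupancy at six months (from
    :func:`assign_chronic_complications`).  Cycle 1 spans months 6-12 with
    mortality applied at its start; annual cycles follow, half-cycle
    corrected, until ``horizon`` years after admission or the age cap.
    """
    total = sum(initial[s] for s in STATES)
    if np.any(np.abs(np.asarray(total) - 1.0) > 1e-9):
        raise ValidationError("initial occupancy must sum to 1")

    cohort = params.cohort
    mort = params.mortality
    lt = params.life_table
    occ = {s: initial[s] for s in STATES}
    trace = MarkovTrace()

    def q_for(state: str, t: float):
        return mortality_schedule(
            cohort.age0, cohort.frac_male, lt, mort, state, t, age_cap=cohort.age_cap
        )

    # --- cycle 1: months 6-12, mortality applied at the cycle start -------
    if horizon is None or horizon > 0.5:
        new = {}
        deaths = 0.0
        for s in ALIVE_STATES:
            q = q_for(s, 0.5)
            new[s] = occ[s] * (1.0 - q)
            deaths = deaths + occ[s] * q
        new["dead"] = occ["dead"] + deaths
        occ = new
        trace.cycles.append(
            MarkovCycle(
                t_start=0.5,
                t_end=1.0,
                occupancy=dict(occ),
                mean_occupancy=dict(occ),  # constant after start-of-cycle deaths
                t_discount=0.75,
            )
        )

    # --- annual cycles ----------------------------------------------------
    n_annual = int(np.ceil(cohort.age_cap - cohort.age0))
    for k in range(1, n_annual + 1):
        t0 = float(k)
        if horizon is not None and t0 >= horizon - 1e-9:
            break
        new = {}
        mean = {}
        deaths = 0.0
        for s in ALIVE_STATES:
            q = q_for(s, t0)
            new[s] = occ[s] * (1.0 - q)
            mean[s] = occ[s] * (1.0 - 0.5 * q)  # transitions at mid-cycle
            deaths = deaths + occ[s] * q
        new["dead"] = occ["dead"] + deaths
        mean["dead"] = 0.5 * (occ["dead"] + new["dead"])
        occ = new
        trace.cycles.append(
            MarkovCycle(
                t_start=t0,
                t_end=t0 + 1.0,
                occupancy=dict(occ),
                mean_occupancy=mean,
                t_discount=t0 + 0.5,
            )
        )
        alive = sum(np.max(np.asarray(occ[s])) for s in ALIVE_STATES)
        if alive <= 0.0:
            break
    return trace
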