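"""Six-month decision tree: expected event counts per 10,000 patients for a
prophylaxis strategy.

Strategy arithmetic is expectation-level: VTE-destined patients are flagged
(and hence treated) with probability equal to the RAM's sensitivity, so the
cohort VTE multiplier is ``sens * RR + (1 - sens)``; bleeding applies by
treatment receipt, so the bleed multiplier uses the overall treated
fraction.  VTE and major bleeding are treated as independent.  Treated
risks are always the unrounded product of baseline risk and relative risk.

Reported table columns: "fatal bleed" is the hospital phase only, while the
ICH and other-major-bleed columns include treatment-phase bleeds among
anticoagulated VTE survivors (treatment-phase fatal bleeds still remove
patients and count toward mortality, but are not shown in the fatal-bleed
column).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from .parameters import EffectSizes, ParameterSet, ValidationError
from .ram import RamOperatingPoint, treated_fraction

__all__ = [
    "StrategySpec",
    "SixMonthOutcomes",
    "strategy_none",
    "strategy_all",
    "strategy_ram",
    "vte_multiplier",
    "bleed_multiplier",
    "treated_fraction_for_strategy",
    "treated_probability_given_vte",
    "run_decision_tree",
    "outcomes_table",
]


@dataclass(frozen=True)
class StrategySpec:
    """A prophylaxis strategy: treat none, treat all, or treat by RAM."""

    kind: str  # {"none", "all", "ram"}
    operating_point: RamOperatingPoint | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("none", "all", "ram"):
            raise ValidationError(f"unknown strategy kind {self.kind!r}")
        if (self.kind == "ram") != (self.operating_point is not None):
            raise ValidationError("operating_point must be present iff kind='ram'")
        if not self.label:
            object.__setattr__(
                self,
                "label",
                {"none": "None", "all": "All inpatients"}.get(self.kind)
                or self.operating_point.threshold_label,
            )


def strategy_none() -> StrategySpec:
    return StrategySpec("none")


def strategy_all() -> StrategySpec:
    return StrategySpec("all")


def strategy_ram(op: RamOperatingPoint, label: str = "") -> StrategySpec:
    return StrategySpec("ram", op, label)


def treated_probability_given_vte(strategy: StrategySpec) -> float:
    """P(receives prophylaxis | VTE-destined): the RAM's sensitivity."""
    if strategy.kind == "none":
        return 0.0
    if strategy.kind == "all":
        return 1.0
    return strategy.operating_point.sensitivity


def treated_fraction_for_strategy(strategy: StrategySpec, prevalence):
    if strategy.kind == "none":
        return 0.0
    if strategy.kind == "all":
        return 1.0
    return treated_fraction(strategy.operating_point, prevalence)


def vte_multiplier(strategy: StrategySpec, effects: EffectSizes):
    """Cohort-level multiplier on baseline VTE risks."""
    s = treated_probability_given_vte(strategy)
    return s * np.asarray(effects.rr_vte) + (1.0 - s)


def bleed_multiplier(strategy: StrategySpec, effects: EffectSizes, prevalence):
    """Cohort-level multiplier on hospital-phase major-bleed risks."""
    f = treated_fraction_for_strategy(strategy, prevalence)
    return f * np.asarray(effects.rr_bleed) + (1.0 - f)


@dataclass
class SixMonthOutcomes:
    """Expected counts per 10,000 patients over the six-month tree horizon.

    Exact fractional values are retained; integer rendering (round half up)
    happens only at the reporting layer.
    """

    fatal_pe: Any
    nonfatal_pe: Any
    sympt_dvt: Any
    asympt_dvt: Any
    hosp_fatal_bleed: Any
    hosp_ich: Any
    hosp_other_bleed: Any
    tx_fatal_bleed: Any
    tx_ich: Any
    tx_other_bleed: Any
    treated_fraction: Any
    n_on_treatment: Any  # symptomatic VTE survivors on 3-month anticoagulation

    # reported (table) columns --------------------------------------------
    @property
    def fatal_bleed_column(self):
        return self.hosp_fatal_bleed

    @property
    def ich_column(self):
        return self.hosp_ich + self.tx_ich

    @property
    def other_bleed_column(self):
        return self.hosp_other_bleed + self.tx_other_bleed

    @property
    def deaths(self):
        """All tree-phase deaths (fatal PE plus fatal bleeds of both phases)."""
        return self.fatal_pe + self.hosp_fatal_bleed + self.tx_fatal_bleed


def run_decision_tree(strategy: StrategySpec, params: ParameterSet) -> SixMonthOutcomes:
    """Evaluate the six-month decision tree for one strategy.

    All quantities are expectations per 10,000 admitted patients; patients
    with major bleeds stop anticoagulation (this affects downstream cost and
    utility durations, not the event counts themselves).
    """
    r = params.risks
    prevalence = r.total_vte_risk
    m_v = vte_multiplier(strategy, params.effects)
    m_b = bleed_multiplier(strategy, params.effects, prevalence)

    if np.any(np.asarray(prevalence * m_v) > 1.0):
        raise ValidationError("VTE multiplier pushes total VTE probability above 1")
    hosp_any = (np.asarray(r.q_hosp_fatal) + r.q_hosp_ich + r.q_hosp_other) * m_b
    if np.any(np.asarray(hosp_any) > 1.0):
        raise ValidationError("bleed multiplier pushes hospital bleed probability above 1")

    per10k = 10_000.0
    pe = per10k * r.p_pe * m_v
    fatal_pe = pe * r.cfr_pe
    nonfatal_pe = pe - fatal_pe
    sympt_dvt = per10k * r.p_sdvt * m_v
    asympt_dvt = per10k * r.p_advt * m_v
    n_on_tx = nonfatal_pe + sympt_dvt

    return SixMonthOutcomes(
        fatal_pe=fatal_pe,
        nonfatal_pe=nonfatal_pe,
        sympt_dvt=sympt_dvt,
        asympt_dvt=asympt_dvt,
        hosp_fatal_bleed=per10k * r.q_hosp_fatal * m_b,
        hosp_ich=per10k * r.q_hosp_ich * m_b,
        hosp_other_bleed=per10k * r.q_hosp_other * m_b,
        tx_fatal_bleed=n_on_tx * r.q_tx_fatal,
        tx_ich=n_on_tx * r.q_tx_ich,
        tx_other_bleed=n_on_tx * r.q_tx_other,
        treated_fraction=treated_fraction_for_strategy(strategy, prevalence),
        n_on_treatment=n_on_tx,
    )


def round_half_up(x) -> int:
    return int(np.floor(np.asarray(x, dtype=float) + 0.5))


def outcomes_table(strategies: list[StrategySpec], params: ParameterSet) -> pd.DataFrame:
    """Six-month outcome columns for a list of strategies, integer-rendered
    per 10,000 (round half up)."""
    rows = []
    for s in strategies:
        o = run_decision_tree(s, params)
        rows.append(
            {
                "strategy": s.label,
                "fatal_pe": round_half_up(o.fatal_pe),
                "fatal_bleed": round_half_up(o.fatal_bleed_column),
                "nonfatal_ich": round_half_up(o.ich_column),
                "other_major_bleed": round_half_up(o.other_bleed_column),
                "nonfatal_pe": round_half_up(o.nonfatal_pe),
                "sympt_dvt": round_half_up(o.sympt_dvt),
                "asympt_dvt": round_half_up(o.asympt_dvt),
                "treated_pct": round_half_up(100.0 * o.treated_fraction),
            }
        )
    return pd.DataFrame(rows)
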