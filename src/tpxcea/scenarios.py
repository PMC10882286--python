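"""Scenario engine: named parameter overrides, one-way threshold searches
for the point at which the optimal strategy switches, and two-way grids.

Scenario application is pure: the base parameter set is never mutated.
Override paths are dotted ``section.key`` names validated against the
parameter schema; values are either absolute replacements or
``{"multiply": x}`` multipliers.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .economics import evaluate_strategy, net_monetary_benefit
from .parameters import ParameterSet, ValidationError
from .tree import StrategySpec

__all__ = [
    "ScenarioSpec",
    "BUILTIN_SCENARIOS",
    "get_scenario",
    "apply_scenario",
    "optimal_strategy",
    "threshold_search",
    "two_way_grid",
    "vte_risk_multiplier_scenario",
    "bleed_risk_multiplier_scenario",
]

#: parameter paths scaled by the VTE-risk and bleed-risk multiplier axes
VTE_RISK_PATHS = ("risks.p_pe", "risks.p_sdvt", "risks.p_advt")
BLEED_RISK_PATHS = ("risks.q_hosp_fatal", "risks.q_hosp_ich", "risks.q_hosp_other")


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    overrides: dict = field(default_factory=dict)
    notes: str = ""
    #: cohort whose bundled operating points the strategies should use
    #: (None keeps the caller's choice)
    ram_cohort: str | None = None


def vte_risk_multiplier_scenario(x: float) -> ScenarioSpec:
    return ScenarioSpec(
        f"vte_risk_x{x:g}",
        {p: {"multiply": x} for p in VTE_RISK_PATHS},
        notes="scale all baseline 90-day VTE risks",
    )


def bleed_risk_multiplier_scenario(x: float) -> ScenarioSpec:
    return ScenarioSpec(
        f"bleed_risk_x{x:g}",
        {p: {"multiply": x} for p in BLEED_RISK_PATHS},
        notes="scale baseline hospital-phase major-bleed risks",
    )


BUILTIN_SCENARIOS: dict[str, ScenarioSpec] = {
    "base_case": ScenarioSpec("base_case", {}),
    "seven_day_lmwh": ScenarioSpec(
        "seven_day_lmwh",
        {"cohort.tpx_days": 7.0},
        notes="seven days of LMWH, two of them after discharge (extra days costed)",
    ),
    "all_doac": ScenarioSpec(
        "all_doac",
        {"cohort.doac_fraction": 1.0},
        notes="all VTE treated with direct oral anticoagulants",
    ),
    "pts_decrement_2pct": ScenarioSpec(
        "pts_decrement_2pct",
        {"utilities.mult_pts": 0.98},
        notes="post-thrombotic syndrome utility decrement 2% instead of 10%",
    ),
    "no_pts_asympt_distal": ScenarioSpec(
        "no_pts_asympt_distal",
        {"risks.pts_distal_asympt": 0.0},
        notes="zero PTS incidence after asymptomatic distal DVT",
    ),
    "pe_cfr_low": ScenarioSpec("pe_cfr_low", {"risks.cfr_pe": 0.13}),
    "pe_cfr_high": ScenarioSpec("pe_cfr_high", {"risks.cfr_pe": 0.67}),
    "elias_operating_points": ScenarioSpec(
        "elias_operating_points",
        {},
        notes="high-performance Padua operating points from a mixed cohort",
        ram_cohort="Elias2017",
    ),
}


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return BUILTIN_SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(BUILTIN_SCENARIOS))}"
        ) from None


def apply_scenario(base: ParameterSet, scenario: ScenarioSpec) -> ParameterSet:
    """Return a modified deep copy of ``base``; ``base`` is untouched."""
    ps = copy.deepcopy(base)
    for path, value in scenario.overrides.items():
        section, _, key = path.partition(".")
        block = getattr(ps, section, None)
        if block is None or not hasattr(block, key):
            raise ValidationError(f"unknown override path {path!r}")
        if isinstance(value, dict) and set(value) == {"multiply"}:
            current = getattr(block, key)
            if current is None:
                raise ValidationError(f"cannot multiply unset parameter {path!r}")
            setattr(block, key, np.asarray(current) * value["multiply"] * 1.0)
        else:
            setattr(block, key, value)
    return ps.validate()


def optimal_strategy(
    strategies: list[StrategySpec], params: ParameterSet, lam: float
) -> str:
    """Label of the strategy with the highest net monetary benefit."""
    best = None
    for s in strategies:
        nmb = float(np.asarray(net_monetary_benefit(evaluate_strategy(s, params), lam)))
        if best is None or nmb > best[0]:
            best = (nmb, s.label)
    return best[1]


_AXES = {"vte": VTE_RISK_PATHS, "bleed": BLEED_RISK_PATHS}


def _scaled(base: ParameterSet, axis, mult: float) -> ParameterSet:
    paths = _AXES[axis] if isinstance(axis, str) else tuple(axis)
    return apply_scenario(
        base, ScenarioSpec(f"{axis}_x{mult:g}", {p: {"multiply": mult} for p in paths})
    )


def threshold_search(
    base: ParameterSet,
    axis,
    direction: str,
    lam: float,
    strategies: list[StrategySpec],
    tol: float = 1e-3,
    bounds: tuple[float, float] = (0.01, 100.0),
    optimum=None,
) -> dict:
    """Smallest multiplicative change along ``axis`` that alters the
    optimal (argmax-NMB) strategy.

    ``axis`` is ``"vte"``, ``"bleed"`` or an explicit tuple of parameter
    paths; ``direction`` is ``"down"`` (multiplier below 1) or ``"up"``.
    Bisection to a multiplier tolerance of ``tol``; if the optimum never
    changes within the bounds the result reports ``"no switch"``.
    ``optimum`` overrides the default argmax-NMB rule with a callable
    ``params -> label`` (useful for analytically solvable toys).
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    if optimum is None:
        optimum = lambda ps: optimal_strategy(strategies, ps, lam)  # noqa: E731
    base_label = optimum(base)
    extreme = bounds[0] if direction == "down" else bounds[1]
    # shrink the bracket endpoint toward 1 if it leaves the model's valid
    # parameter space (e.g. a bleed probability pushed above 1)
    for _ in range(60):
        try:
            extreme_label = optimum(_scaled(base, axis, extreme))
            break
        except ValidationError:
            extreme = 1.0 + 0.9 * (extreme - 1.0)
    else:
        return {"status": "no switch", "multiplier": None, "from": base_label, "to": None}
    if extreme_label == base_label:
        return {"status": "no switch", "multiplier": None, "from": base_label, "to": None}

    near, far = 1.0, extreme  # optimum unchanged at `near`, changed at `far`
    while abs(far - near) > tol:
        mid = 0.5 * (near + far)
        if optimum(_scaled(base, axis, mid)) == base_label:
            near = mid
        else:
            far = mid
    switch = 0.5 * (near + far)
    return {
        "status": "switch",
        "multiplier": switch,
        "from": base_label,
        "to": optimum(_scaled(base, axis, far)),
    }


def two_way_grid(
    base: ParameterSet,
    axis1,
    axis2,
    grid1,
    grid2,
    lam: float,
    strategies: list[StrategySpec],
):
    """Optimal-strategy label for every cell of a two-axis multiplier grid.

    Returns a pandas DataFrame indexed by ``axis1`` multipliers with
    ``axis2`` multipliers as columns.
    """
    import pandas as pd

    rows = []
    for m1 in grid1:
        row = []
        for m2 in grid2:
            ps = _scaled(_scaled(base, axis1, float(m1)), axis2, float(m2))
            row.append(optimal_strategy(strategies, ps, lam))
        rows.append(row)
    return pd.DataFrame(rows, index=list(grid1), columns=list(grid2))
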