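"""Probabilistic sensitivity analysis: Monte-Carlo propagation of parameter
uncertainty through the full deterministic pipeline.

Parameters are sampled independently from their fitted distributions; the
three hospital-phase bleed subtypes share a single "any major bleed" draw
split by the fixed subtype proportions (and likewise for treatment-phase
bleeds), preserving the tabulated type ratios in every draw.  RAM
sensitivity and specificity are held fixed: the uncertainty in risk
assessment model performance is explored through scenario analysis
instead.

Because every numeric parameter may be a vector of draws and the model
arithmetic is elementwise, one vectorised pipeline evaluation per strategy
covers all draws.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .economics import evaluate_strategy
from .parameters import (
    DistributionSpec,
    ParameterSet,
    ValidationError,
    fit_beta_from_ci,
    fit_beta_from_mean_sd,
    fit_gamma_from_ci,
    fit_lognormal_from_ci,
)
from .tree import StrategySpec

__all__ = [
    "PsaResult",
    "default_distributions",
    "sample_parameter_set",
    "run_psa",
    "ceac",
    "HOSP_BLEED_SPLIT",
    "TX_BLEED_SPLIT",
]

#: fixed subtype shares of "any major bleed" (fatal : ICH : other),
#: hospital phase 0.10/0.06/0.51 of 0.67 and treatment phase
#: 0.21/0.08/0.56 of 0.85
HOSP_BLEED_SPLIT = {"q_hosp_fatal": 0.10 / 0.67, "q_hosp_ich": 0.06 / 0.67, "q_hosp_other": 0.51 / 0.67}
TX_BLEED_SPLIT = {"q_tx_fatal": 0.21 / 0.85, "q_tx_ich": 0.08 / 0.85, "q_tx_other": 0.56 / 0.85}

_UTILITY_SD = 0.02  # assumed sd for utilities/multipliers (no printed CIs)
_COST_CI_REL = 0.2  # assumed +-20% 95% CI for event costs (no printed CIs)


def default_distributions() -> dict[str, DistributionSpec]:
    """Default sampling distributions for every uncertain parameter.

    Probabilities are beta (fit from the printed mean and 95% CI), relative
    risks and standardised mortality ratios lognormal, event costs gamma,
    utilities and multipliers beta.  Unit costs of applying the RAM and of
    the prophylaxis course, the cohort profile, and RAM operating points
    are fixed.
    """
    d: dict[str, DistributionSpec] = {
        "risks.p_pe": fit_beta_from_ci(0.0138, 0.0072, 0.0224),
        "risks.p_sdvt": fit_beta_from_ci(0.0202, 0.0121, 0.0297),
        "risks.p_advt": fit_beta_from_ci(0.3046, 0.1690, 0.5087),
        "risks.any_hosp_bleed": fit_beta_from_ci(0.0067, 0.0030, 0.0140),
        "risks.any_tx_bleed": fit_beta_from_ci(0.0085, 0.0015, 0.0199),
        "risks.cfr_pe": fit_beta_from_ci(0.268, 0.113, 0.331),
        "risks.pts_sympt_prox": fit_beta_from_ci(0.324, 0.221, 0.436),
        "risks.pts_asympt_prox": fit_beta_from_ci(0.565, 0.365, 0.738),
        "risks.pts_distal": fit_beta_from_ci(0.156, 0.079, 0.253),
        "risks.p_cteph": fit_beta_from_ci(0.032, 0.020, 0.044),
        "effects.rr_vte": fit_lognormal_from_ci(0.49, 0.37, 0.67),
        "effects.rr_bleed": fit_lognormal_from_ci(1.53, 0.80, 2.92),
        "mortality.smr_year1": fit_lognormal_from_ci(9.4, 8.9, 10.0),
        "mortality.smr_ich_y2to6": fit_lognormal_from_ci(2.2, 1.8, 2.7),
        "utilities.u_well_y1": fit_beta_from_mean_sd(0.800, _UTILITY_SD),
        "utilities.u_dvt_6m": fit_beta_from_mean_sd(0.769, _UTILITY_SD),
        "utilities.u_pe_6m": fit_beta_from_mean_sd(0.768, _UTILITY_SD),
        "utilities.u_bleed_other_1m": fit_beta_from_mean_sd(0.685, _UTILITY_SD),
        "utilities.u_ich_6m": fit_beta_from_mean_sd(0.580, _UTILITY_SD),
        "utilities.mult_ich": fit_beta_from_mean_sd(0.888, _UTILITY_SD),
        "utilities.mult_pts": fit_beta_from_mean_sd(0.895, _UTILITY_SD),
        "utilities.mult_cteph": fit_beta_from_mean_sd(0.629, _UTILITY_SD),
    }
    for name, mean in (
        ("costs.c_sdvt_prox", 763.12),
        ("costs.c_sdvt_distal", 642.95),
        ("costs.c_pe_nonfatal", 1848.75),
        ("costs.c_pe_fatal", 1517.13),
        ("costs.c_bleed_fatal", 1865.51),
        ("costs.c_bleed_other", 1209.75),
        ("costs.c_ich_first90d", 21987.80),
        ("costs.c_ich_annual", 8292.83),
        ("costs.c_pts_y1", 293.16),
        ("costs.c_pts_annual", 78.00),
        ("costs.c_cteph_med_annual", 18569.53),
        ("costs.c_cteph_surg_y1", 10236.60),
    ):
        d[name] = fit_gamma_from_ci(mean, mean * (1 - _COST_CI_REL), mean * (1 + _COST_CI_REL))
    return d


def _set_path(ps: ParameterSet, path: str, value) -> None:
    section, key = path.split(".", 1)
    block = getattr(ps, section)
    if not hasattr(block, key):
        raise ValidationError(f"unknown parameter path {path!r}")
    setattr(block, key, value)


def sample_parameter_set(
    dists: dict[str, DistributionSpec],
    seed: int | np.random.Generator,
    base: ParameterSet | None = None,
    size: int | None = None,
) -> ParameterSet:
    """Draw a parameter set from the distributions.

    ``size=None`` yields scalar draws (one sampled parameter set); an
    integer yields vectorised fields of that length.  Identical seeds give
    identical draws.  The special names ``risks.any_hosp_bleed`` and
    ``risks.any_tx_bleed`` are sampled once and split into their subtype
    risks by the fixed proportions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ps = copy.deepcopy(base) if base is not None else ParameterSet()
    n = size if size is not None else 1
    for name in sorted(dists):  # sorted: draw order independent of dict order
        spec = dists[name]
        try:
            draw = spec.sample(rng, n)
        except Exception as exc:  # noqa: BLE001
            raise ValidationError(f"invalid distribution for {name!r}: {exc}") from exc
        if size is None:
            draw = float(draw[0])
        if name == "risks.any_hosp_bleed":
            for key, share in HOSP_BLEED_SPLIT.items():
                _set_path(ps, f"risks.{key}", draw * share)
        elif name == "risks.any_tx_bleed":
            for key, share in TX_BLEED_SPLIT.items():
                _set_path(ps, f"risks.{key}", draw * share)
        else:
            _set_path(ps, name, draw)
    return ps


@dataclass
class PsaResult:
    n_samples: int
    seed: int
    strategies: list[str]
    mean_cost: dict[str, float]
    mean_qalys: dict[str, float]
    #: per-strategy incremental summaries versus the comparator:
    #: {label: {d_cost: {mean, ci}, d_qalys: {mean, ci}, prob_dominant}}
    incremental: dict[str, dict]
    comparator: str
    prob_ce_at: dict[float, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "seed": self.seed,
            "strategies": self.strategies,
            "mean_cost": self.mean_cost,
            "mean_qalys": self.mean_qalys,
            "comparator": self.comparator,
            "incremental": self.incremental,
            "prob_ce_at": {str(k): v for k, v in self.prob_ce_at.items()},
        }


def ceac(costs: np.ndarray, qalys: np.ndarray, labels: list[str], lambdas) -> dict[float, dict[str, float]]:
    """Cost-effectiveness acceptability: for each willingness-to-pay, the
    fraction of draws in which each strategy has the highest net monetary
    benefit.  Exact ties are split equally, so probabilities sum to one.

    ``costs`` and ``qalys`` have shape (n_draws, n_strategies).
    """
    out: dict[float, dict[str, float]] = {}
    for lam in lambdas:
        nmb = lam * qalys - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        share = winners / winners.sum(axis=1, keepdims=True)
        out[float(lam)] = {lab: float(share[:, j].mean()) for j, lab in enumerate(labels)}
    return out


def run_psa(
    strategies: list[StrategySpec],
    dists: dict[str, DistributionSpec] | None = None,
    n: int = 10_000,
    lambdas=(20_000.0, 30_000.0),
    seed: int = 0,
    base: ParameterSet | None = None,
    comparator: str | None = None,
    return_draws: bool = False,
):
    """Monte-Carlo PSA over ``n`` parameter draws.

    Every draw runs the full deterministic pipeline (tree, Markov,
    economics) for each strategy.  Draws violating model validity (for
    example a bleed multiplier pushing a probability above one) are
    rejected and logged; more than 1% rejections aborts.
    """
    if n < 1:
        raise ValidationError("n must be at least 1")
    if dists is None:
        dists = default_distributions()
    ps = sample_parameter_set(dists, seed, base=base, size=n)

    # validity screen before the vectorised evaluation
    r = ps.risks
    valid = (np.asarray(r.total_vte_risk) <= 1.0) & (
        (np.asarray(r.q_hosp_fatal) + r.q_hosp_ich + r.q_hosp_other)
        * np.maximum(1.0, np.asarray(ps.effects.rr_bleed))
        <= 1.0
    )
    valid = np.broadcast_to(valid, (n,))
    n_rejected = int(n - valid.sum())
    if n_rejected > 0.01 * n:
        raise ValidationError(f"{n_rejected}/{n} parameter draws rejected; aborting")
    if n_rejected:
        ps = _mask_draws(ps, valid)
    n_eff = int(valid.sum())

    labels = [s.label for s in strategies]
    costs = np.empty((n_eff, len(strategies)))
    qalys = np.empty((n_eff, len(strategies)))
    for j, s in enumerate(strategies):
        res = evaluate_strategy(s, ps)
        costs[:, j] = np.broadcast_to(np.asarray(res.cost), (n_eff,))
        qalys[:, j] = np.broadcast_to(np.asarray(res.qalys), (n_eff,))

    comparator = comparator or labels[0]
    jc = labels.index(comparator)
    incremental: dict[str, dict] = {}
    for j, lab in enumerate(labels):
        if j == jc:
            continue
        dc = costs[:, j] - costs[:, jc]
        dq = qalys[:, j] - qalys[:, jc]
        incremental[lab] = {
            "d_cost": {"mean": float(dc.mean()), "ci": [float(np.percentile(dc, 2.5)), float(np.percentile(dc, 97.5))]},
            "d_qalys": {"mean": float(dq.mean()), "ci": [float(np.percentile(dq, 2.5)), float(np.percentile(dq, 97.5))]},
            "prob_dominant": float(np.mean((dc < 0) & (dq > 0))),
        }

    result = PsaResult(
        n_samples=n_eff,
        seed=seed,
        strategies=labels,
        mean_cost={lab: float(costs[:, j].mean()) for j, lab in enumerate(labels)},
        mean_qalys={lab: float(qalys[:, j].mean()) for j, lab in enumerate(labels)},
        incremental=incremental,
        comparator=comparator,
        prob_ce_at=ceac(costs, qalys, labels, lambdas),
    )
    if return_draws:
        return result, costs, qalys
    return result


def _mask_draws(ps: ParameterSet, mask: np.ndarray) -> ParameterSet:
    """Drop rejected draws from every vector-valued field."""
    import dataclasses

    ps = copy.deepcopy(ps)
    n = mask.shape[0]
    for section in ("risks", "effects", "mortality", "costs", "utilities", "cohort"):
        block = getattr(ps, section)
        for f in dataclasses.fields(block):
            v = getattr(block, f.name)
            if isinstance(v, np.ndarray) and v.shape == (n,):
                setattr(block, f.name, v[mask])
    return ps
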