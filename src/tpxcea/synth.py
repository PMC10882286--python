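"""Synthetic inputs: parametric life tables, risk-assessment-model
validation cohorts with a controllable ROC, and an individual-level
microsimulation of the six-month pathway.

Everything the analysis consumes can be generated here, so the full
pipeline runs without any external download.  All generated artifacts are
synthetic stand-ins: life tables follow a Gompertz hazard shaped to
resemble national (England & Wales) mortality rather than copying it, and
cohorts use a binormal latent-risk model chosen for its closed-form ROC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .parameters import LifeTable, ValidationError

__all__ = [
    "SyntheticCohort",
    "generate_life_table",
    "generate_ram_cohort",
    "operating_point_from_cohort",
    "theoretical_operating_point",
    "microsimulate_tree",
]

# Gompertz defaults: q(65) ~ 1.3% (men) / 0.9% (women), doubling roughly
# every 7 years — the familiar shape of a contemporary UK national life table.
GOMPERTZ_A_MALE = 1.955e-5
GOMPERTZ_A_FEMALE = 1.353e-5
GOMPERTZ_B = 0.10


def generate_life_table(
    a_male: float = GOMPERTZ_A_MALE,
    a_female: float = GOMPERTZ_A_FEMALE,
    b: float = GOMPERTZ_B,
    age_max: int = 100,
) -> LifeTable:
    """Parametric life table with Gompertz hazard h(age) = a * exp(b * age).

    Annual death probability q(age) = 1 - exp(-h(age)), capped at 1 in the
    terminal row (``age_max``).  This is a SYNTHETIC stand-in for a national
    life table; supply a real one via configuration for applied work.
    """
    if a_male <= 0 or a_female <= 0 or b < 0:
        raise ValidationError("Gompertz parameters must be positive (b may be 0)")
    age = np.arange(0, age_max + 1, dtype=float)
    qm = 1.0 - np.exp(-a_male * np.exp(b * age))
    qf = 1.0 - np.exp(-a_female * np.exp(b * age))
    qm[-1] = 1.0
    qf[-1] = 1.0
    return LifeTable(age, np.clip(qm, 0, 1), np.clip(qf, 0, 1))


# ---------------------------------------------------------------------------
# RAM validation cohorts (binormal latent score)
# ---------------------------------------------------------------------------

_SCORE_SCALE = 3.0  # latent sd units per integer score step band
_SCORE_OFFSET = 15.0  # keeps rounded scores comfortably above zero


@dataclass
class SyntheticCohort:
    """A simulated RAM validation cohort.

    ``frame`` holds (patient_id, risk_score, vte_90d); the generating
    parameters are retained so theoretical operating points can be computed
    in closed form.  Scores are integers obtained by rounding an affine
    transform of a latent standard-normal risk score whose class means are
    separated by ``delta = sqrt(2) * Phi^{-1}(AUC)``.
    """

    frame: pd.DataFrame
    n: int
    prevalence: float
    auc_target: float
    delta: float
    seed: int
    latent: str = "binormal"
    provenance: str = "SYNTHETIC"

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# {self.provenance} cohort: n={self.n} prevalence={self.prevalence} "
                f"auc={self.auc_target} seed={self.seed}\n"
            )
            self.frame.to_csv(fh, index=False)


def _logistic_delta_for_auc(auc: float) -> float:
    """Class-mean separation giving the requested AUC for unit-scale
    logistic class-conditionals (numeric inversion of E[F0(X1)])."""
    from scipy import integrate, optimize
    from scipy.stats import logistic

    if auc <= 0.5:
        return 0.0

    def auc_of(delta: float) -> float:
        val, _ = integrate.quad(
            lambda x: logistic.cdf(x) * logistic.pdf(x - delta), -30, 30 + delta
        )
        return val

    return float(optimize.brentq(lambda d: auc_of(d) - auc, 1e-9, 40.0))


def generate_ram_cohort(
    n: int,
    prevalence: float = 0.3386,
    auc_target: float = 0.66,
    seed: int = 0,
    latent: str = "binormal",
) -> SyntheticCohort:
    """Simulate a validation cohort with a latent-risk ROC of the requested
    AUC.

    The 90-day VTE outcome is drawn first (Bernoulli ``prevalence``); the
    latent score is then drawn from the class-conditional distribution
    (unit scale, class means separated by ``delta``) and discretised to an
    integer score.  ``latent="binormal"`` gives the classic binormal ROC
    with ``AUC = Phi(delta / sqrt(2))``; ``latent="logistic"`` gives a ROC
    that is exactly linear on the logit scale (slope 1, intercept
    ``delta``), the natural truth for checking the logit-scale ROC
    regression.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if not 0 < prevalence < 1:
        raise ValidationError("prevalence must lie in (0, 1)")
    if not 0.5 <= auc_target < 1:
        raise ValidationError("auc_target must lie in [0.5, 1)")
    rng = np.random.default_rng(seed)
    vte = rng.random(n) < prevalence
    if latent == "binormal":
        delta = float(np.sqrt(2.0) * norm.ppf(auc_target))
        noise = rng.standard_normal(n)
    elif latent == "logistic":
        delta = _logistic_delta_for_auc(auc_target)
        noise = rng.logistic(0.0, 1.0, size=n)
    else:
        raise ValidationError(f"unknown latent model {latent!r}")
    score = np.maximum(0, np.rint(_SCORE_OFFSET + _SCORE_SCALE * (noise + delta * vte))).astype(int)
    frame = pd.DataFrame(
        {"patient_id": np.arange(n), "risk_score": score, "vte_90d": vte.astype(int)}
    )
    return SyntheticCohort(frame, n, prevalence, auc_target, delta, seed, latent=latent)


def operating_point_from_cohort(cohort: SyntheticCohort, threshold: int):
    """Empirical (sensitivity, specificity) of the rule score >= threshold.

    Returns a :class:`~tpxcea.ram.RamOperatingPoint`.
    """
    from .ram import RamOperatingPoint  # deferred: ram imports parameters only

    score = cohort.frame["risk_score"].to_numpy()
    vte = cohort.frame["vte_90d"].to_numpy().astype(bool)
    if not vte.any() or vte.all():
        raise ValidationError("cohort lacks one outcome class")
    flagged = score >= threshold
    sens = float(np.mean(flagged[vte]))
    spec = float(np.mean(~flagged[~vte]))
    return RamOperatingPoint(
        ram_name="synthetic",
        threshold_label=f">={threshold}",
        sensitivity=sens,
        specificity=spec,
        source_cohort=f"synthetic(seed={cohort.seed})",
    )


def theoretical_operating_point(cohort: SyntheticCohort, threshold: int) -> tuple[float, float]:
    """Closed-form (sensitivity, specificity) of score >= threshold under the
    generating latent model, accounting for the integer rounding of scores."""
    from scipy.stats import logistic

    dist = norm if cohort.latent == "binormal" else logistic
    # round(offset + scale*x) >= t  <=>  x >= (t - 0.5 - offset) / scale
    cut = (threshold - 0.5 - _SCORE_OFFSET) / _SCORE_SCALE
    sens = float(dist.sf(cut - cohort.delta))
    spec = float(dist.cdf(cut))
    return sens, spec


# ---------------------------------------------------------------------------
# Individual-level microsimulation of the six-month pathway
# ---------------------------------------------------------------------------


def microsimulate_tree(strategy, params, n: int, seed: int = 0, chunk: int = 2_500_000):
    """Simulate ``n`` individual patients through the six-month pathway and
    return summed event counts (same keys as the cohort-expectation tree,
    absolute counts, not per 10,000).

    Used as an independent stochastic oracle for the expectation model: each
    patient's VTE destiny, risk-assessment flag, prophylaxis effect,
    hospital-phase bleeds, PE case fatality and treatment-phase bleeds are
    drawn explicitly.
    """
    from .tree import treated_probability_given_vte, treated_fraction_for_strategy

    r = params.risks
    rng = np.random.default_rng(seed)
    sens_eff = treated_probability_given_vte(strategy)  # P(treated | VTE-destined)
    f = treated_fraction_for_strategy(strategy, r.total_vte_risk)
    # P(treated | not destined): solve f = prev*sens_eff + (1-prev)*x
    prev = r.total_vte_risk
    p_tx_given_no = (f - prev * sens_eff) / (1.0 - prev)

    keys = (
        "fatal_pe nonfatal_pe sympt_dvt asympt_dvt hosp_fatal_bleed hosp_ich "
        "hosp_other_bleed tx_fatal_bleed tx_ich tx_other_bleed n_treated"
    ).split()
    totals = dict.fromkeys(keys, 0)

    done = 0
    while done < n:
        m = min(chunk, n - done)
        u = rng.random(m)
        destined_pe = u < r.p_pe
        destined_sdvt = (u >= r.p_pe) & (u < r.p_pe + r.p_sdvt)
        destined_advt = (u >= r.p_pe + r.p_sdvt) & (u < prev)
        destined = u < prev
        treated = np.where(destined, rng.random(m) < sens_eff, rng.random(m) < p_tx_given_no)
        # prophylaxis lets a destined patient escape the event with prob 1 - rr
        event = ~treated | (rng.random(m) < params.effects.rr_vte)
        pe = destined_pe & event
        sdvt = destined_sdvt & event
        advt = destined_advt & event
        fatal_pe = pe & (rng.random(m) < r.cfr_pe)
        nonfatal_pe = pe & ~fatal_pe

        u2 = rng.random(m)
        mult_b = np.where(treated, params.effects.rr_bleed, 1.0)
        hosp_fatal = u2 < r.q_hosp_fatal * mult_b
        hosp_ich = (u2 >= r.q_hosp_fatal * mult_b) & (u2 < (r.q_hosp_fatal + r.q_hosp_ich) * mult_b)
        hosp_other = (u2 >= (r.q_hosp_fatal + r.q_hosp_ich) * mult_b) & (
            u2 < (r.q_hosp_fatal + r.q_hosp_ich + r.q_hosp_other) * mult_b
        )
        on_tx = nonfatal_pe | sdvt
        u3 = rng.random(m)
        tx_fatal = on_tx & (u3 < r.q_tx_fatal)
        tx_ich = on_tx & (u3 >= r.q_tx_fatal) & (u3 < r.q_tx_fatal + r.q_tx_ich)
        tx_other = on_tx & (u3 >= r.q_tx_fatal + r.q_tx_ich) & (
            u3 < r.q_tx_fatal + r.q_tx_ich + r.q_tx_other
        )

        for key, mask in (
            ("fatal_pe", fatal_pe),
            ("nonfatal_pe", nonfatal_pe),
            ("sympt_dvt", sdvt),
            ("asympt_dvt", advt),
            ("hosp_fatal_bleed", hosp_fatal),
            ("hosp_ich", hosp_ich),
            ("hosp_other_bleed", hosp_other),
            ("tx_fatal_bleed", tx_fatal),
            ("tx_ich", tx_ich),
            ("tx_other_bleed", tx_other),
            ("n_treated", treated),
        ):
            totals[key] += int(mask.sum())
        done += m
    return totals
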