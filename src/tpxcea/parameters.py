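"""Model parameters: defaults, validation, configuration loading and
distribution fitting for probabilistic sensitivity analysis.

The parameter set is the single source of truth for one model evaluation.
Baseline (no-prophylaxis) risks are stored together with relative risks;
"with prophylaxis" risks are always derived as ``baseline * RR`` using the
unrounded product, never stored.

Every numeric field may hold either a scalar ``float`` or a 1-D
``numpy.ndarray`` of Monte-Carlo draws; all downstream model arithmetic is
elementwise, so a single code path serves both the deterministic analysis
and the probabilistic sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from scipy import optimize, stats

__all__ = [
    "ClinicalRisks",
    "EffectSizes",
    "MortalityParams",
    "CostParams",
    "UtilityParams",
    "CohortProfile",
    "LifeTable",
    "ParameterSet",
    "DistributionSpec",
    "ValidationError",
    "fit_lognormal_from_ci",
    "fit_beta_from_ci",
    "fit_beta_from_mean_sd",
    "fit_gamma_from_ci",
    "load_parameter_set",
]

SCHEMA_VERSION = 1

#: multiplicative health-utility index by age band (lower bound of band ->
#: index), normalised so that the 65-74 band (the cohort's baseline band)
#: equals 1.  Shape follows published general-population EQ-5D norms for
#: England; swappable through the ``utilities.age_adjustment_table`` config key.
DEFAULT_AGE_UTILITY_INDEX: dict[int, float] = {
    0: 1.15,
    25: 1.13,
    35: 1.10,
    45: 1.06,
    55: 1.02,
    65: 1.00,
    75: 0.93,
    85: 0.85,
}


class ValidationError(ValueError):
    """A parameter or configuration value violates its declared range."""


def _check(cond, message: str) -> None:
    if not np.all(cond):
        raise ValidationError(message)


def _is_prob(x) -> bool:
    return bool(np.all((np.asarray(x) >= 0.0) & (np.asarray(x) <= 1.0)))


# ---------------------------------------------------------------------------
# Parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class ClinicalRisks:
    """Baseline clinical probabilities (all without prophylaxis).

    90-day VTE risks and hospital-phase bleed risks apply to the whole
    admitted cohort; treatment-phase bleed risks apply to patients on three
    months of therapeutic anticoagulation after symptomatic VTE.  PTS risks
    are cumulative three-year risks by DVT class; CTEPH is the cumulative
    two-year incidence among PE survivors.
    """

    p_pe: Any = 0.0138
    p_sdvt: Any = 0.0202
    p_advt: Any = 0.3046
    q_hosp_fatal: Any = 0.0010
    q_hosp_ich: Any = 0.0006
    q_hosp_other: Any = 0.0051
    q_tx_fatal: Any = 0.0021
    q_tx_ich: Any = 0.0008
    q_tx_other: Any = 0.0056
    cfr_pe: Any = 0.268
    pts_sympt_prox: Any = 0.324
    pts_asympt_prox: Any = 0.565
    pts_distal: Any = 0.156
    #: PTS risk for asymptomatic distal DVT; ``None`` means "same as
    #: pts_distal" (the base case).  Set to 0 by the scenario that assumes no
    #: PTS after asymptomatic distal DVT.
    pts_distal_asympt: Any = None
    p_cteph: Any = 0.032
    frac_prox_sympt: Any = 0.6
    frac_prox_asympt: Any = 0.2
    frac_cteph_surgical: Any = 0.5

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            _check(_is_prob(v), f"risks.{f.name} must lie in [0, 1]")
        _check(
            np.asarray(self.q_hosp_fatal) + self.q_hosp_ich + self.q_hosp_other <= 1.0,
            "hospital-phase bleed risks must sum to at most 1",
        )
        _check(
            np.asarray(self.p_pe) + self.p_sdvt + self.p_advt <= 1.0,
            "90-day VTE risks must sum to at most 1",
        )

    @property
    def total_vte_risk(self):
        """Total 90-day VTE risk without prophylaxis (PE + symptomatic DVT +
        asymptomatic DVT); the prevalence used for treated fractions."""
        return self.p_pe + self.p_sdvt + self.p_advt

    @property
    def pts_distal_asympt_effective(self):
        return self.pts_distal if self.pts_distal_asympt is None else self.pts_distal_asympt


@dataclass
class EffectSizes:
    """Relative risks of low-molecular-weight heparin prophylaxis."""

    rr_vte: Any = 0.49
    rr_bleed: Any = 1.53

    def validate(self) -> None:
        _check(np.asarray(self.rr_vte) > 0, "effects.rr_vte must be > 0")
        _check(np.asarray(self.rr_bleed) > 0, "effects.rr_bleed must be > 0")


@dataclass
class MortalityParams:
    """Standardised mortality ratios layered on the general-population life
    table.

    ``smr_year1`` applies to every patient in the year after admission;
    ``smr_ich_y1`` is the first-year multiplier for intracranial-haemorrhage
    survivors (the cohort-wide first-year SMR exceeds the ICH-specific 4.5
    and is therefore used); ``smr_ich_y2to6`` applies in years 2-6 after
    ICH.  ``cteph_mortality_multiplier`` applies while in a CTEPH state and
    is an unprinted placeholder default.
    """

    smr_year1: Any = 9.4
    smr_ich_y1: Any = 9.4
    smr_ich_y2to6: Any = 2.2
    cteph_mortality_multiplier: Any = 3.0

    def validate(self) -> None:
        for f in fields(self):
            _check(np.asarray(getattr(self, f.name)) >= 1.0, f"mortality.{f.name} must be >= 1")


@dataclass
class CostParams:
    """Unit costs in 2020 GBP (NHS and Personal Social Services perspective).

    Symptomatic-VTE event costs include a 60:40 phased-anticoagulation/DOAC
    treatment component (``c_vte_tx_phased``/``c_vte_tx_doac``); changing the
    DOAC share shifts the event cost by the component difference only, so the
    bundled totals reproduce the tabulated event costs at the default split.
    """

    c_ram: Any = 9.08
    c_tpx_course: Any = 23.91
    c_tpx_per_extra_day: Any = 23.91 / 5.0
    c_tpx_extra_day_admin: Any = 0.0
    c_sdvt_prox: Any = 763.12
    c_sdvt_distal: Any = 642.95
    c_pe_nonfatal: Any = 1848.75
    c_pe_fatal: Any = 1517.13
    c_bleed_fatal: Any = 1865.51
    c_bleed_other: Any = 1209.75
    c_ich_first90d: Any = 21987.80
    c_ich_annual: Any = 8292.83
    c_pts_y1: Any = 293.16
    c_pts_annual: Any = 78.00
    c_cteph_med_annual: Any = 18569.53
    c_cteph_surg_y1: Any = 10236.60
    # 3-month anticoagulation cost components inside the symptomatic-VTE
    # event costs (composition not tabulated; package defaults)
    c_vte_tx_phased: Any = 182.00
    c_vte_tx_doac: Any = 130.00
    #: DOAC fraction at which the bundled event-cost totals are quoted
    doac_fraction_reference: Any = 0.4

    def validate(self) -> None:
        for f in fields(self):
            _check(np.asarray(getattr(self, f.name)) >= 0.0, f"costs.{f.name} must be >= 0")

    def anticoag_cost_adjustment(self, doac_fraction):
        """Shift applied to each symptomatic-VTE event cost when the
        phased/DOAC split differs from the reference split."""
        return (doac_fraction - self.doac_fraction_reference) * (
            np.asarray(self.c_vte_tx_doac) - self.c_vte_tx_phased
        )


@dataclass
class UtilityParams:
    """Health-state utilities, decrements and chronic multipliers."""

    u_well_y1: Any = 0.800
    tpx_decrement: Any = 0.007
    anticoag_decrement: Any = 0.011
    u_dvt_6m: Any = 0.769
    u_pe_6m: Any = 0.768
    u_bleed_other_1m: Any = 0.685
    u_ich_6m: Any = 0.580
    mult_ich: Any = 0.888
    mult_pts: Any = 0.895
    mult_cteph: Any = 0.629
    age_adjustment_table: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_UTILITY_INDEX)
    )

    def validate(self) -> None:
        for name in ("u_well_y1", "u_dvt_6m", "u_pe_6m", "u_bleed_other_1m", "u_ich_6m"):
            _check(_is_prob(getattr(self, name)), f"utilities.{name} must lie in [0, 1]")
        for name in ("mult_ich", "mult_pts", "mult_cteph"):
            v = np.asarray(getattr(self, name))
            _check((v > 0) & (v <= 1), f"utilities.{name} must lie in (0, 1]")
        for name in ("tpx_decrement", "anticoag_decrement"):
            _check(np.asarray(getattr(self, name)) >= 0, f"utilities.{name} must be >= 0")

    def age_index(self, age: float) -> float:
        """Multiplicative utility index for an age, from the band table."""
        key = max(k for k in self.age_adjustment_table if k <= age)
        return self.age_adjustment_table[key]

    def utility_well(self, age: float, age0: float):
        """Background utility at ``age`` for a cohort admitted at ``age0``:
        the year-1 utility rescaled by the age-band index relative to the
        admission band."""
        return np.asarray(self.u_well_y1) * self.age_index(age) / self.age_index(age0)


@dataclass
class CohortProfile:
    """Cohort characteristics and analysis settings."""

    age0: float = 65.8
    frac_male: float = 0.445
    tpx_days: Any = 5.0
    nurse_minutes_per_dose: float = 2.5
    ram_minutes: float = 5.0
    doac_fraction: Any = 0.4
    discount_rate: float = 0.035
    age_cap: float = 100.0

    def validate(self) -> None:
        _check(self.age0 > 0, "cohort.age0 must be > 0")
        _check(_is_prob(self.frac_male), "cohort.frac_male must lie in [0, 1]")
        _check(_is_prob(self.doac_fraction), "cohort.doac_fraction must lie in [0, 1]")
        _check(self.discount_rate >= 0, "cohort.discount_rate must be >= 0")
        _check(np.asarray(self.tpx_days) >= 0, "cohort.tpx_days must be >= 0")
        _check(self.age_cap > self.age0, "cohort.age_cap must exceed cohort.age0")


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------


@dataclass
class LifeTable:
    """Annual death probabilities by integer age and sex.

    Ages must be contiguous; probabilities are linearly interpolated at
    non-integer ages and clamped to the terminal row beyond the table.
    """

    age: np.ndarray
    q_male: np.ndarray
    q_female: np.ndarray

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.q_male = np.asarray(self.q_male, dtype=float)
        self.q_female = np.asarray(self.q_female, dtype=float)
        _check(_is_prob(self.q_male) and _is_prob(self.q_female), "life-table q outside [0, 1]")
        if not np.all(np.diff(self.age) == 1):
            raise ValidationError("life-table ages must be contiguous integers")

    def annual_q(self, age: float, frac_male: float) -> float:
        """Sex-weighted annual death probability at (possibly fractional)
        ``age``."""
        qm = np.interp(age, self.age, self.q_male)
        qf = np.interp(age, self.age, self.q_female)
        return frac_male * qm + (1.0 - frac_male) * qf

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        return cls(df["age"].to_numpy(), df["q_male"].to_numpy(), df["q_female"].to_numpy())

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        import pandas as pd

        df = pd.DataFrame({"age": self.age.astype(int), "q_male": self.q_male, "q_female": self.q_female})
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Parameter set
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    risks: ClinicalRisks = field(default_factory=ClinicalRisks)
    effects: EffectSizes = field(default_factory=EffectSizes)
    mortality: MortalityParams = field(default_factory=MortalityParams)
    costs: CostParams = field(default_factory=CostParams)
    utilities: UtilityParams = field(default_factory=UtilityParams)
    cohort: CohortProfile = field(default_factory=CohortProfile)
    life_table: LifeTable | None = None

    def __post_init__(self) -> None:
        if self.life_table is None:
            from .synth import generate_life_table  # deferred: avoids cycle

            self.life_table = generate_life_table()

    def validate(self) -> "ParameterSet":
        for block in (self.risks, self.effects, self.mortality, self.costs, self.utilities, self.cohort):
            block.validate()
        return self

    def replace(self, **sections) -> "ParameterSet":
        """Return a copy with whole sections replaced (shallow)."""
        return dataclasses.replace(self, **sections)

    def copy(self) -> "ParameterSet":
        import copy as _copy

        return _copy.deepcopy(self)


_SECTIONS = {
    "risks": ClinicalRisks,
    "effects": EffectSizes,
    "mortality": MortalityParams,
    "costs": CostParams,
    "utilities": UtilityParams,
    "cohort": CohortProfile,
}


def _apply_overrides(ps: ParameterSet, overrides: dict, logger=None) -> ParameterSet:
    bad: list[str] = []
    for section, values in overrides.items():
        if section in ("schema_version", "strategies", "psa", "scenarios", "life_table"):
            continue
        if section not in _SECTIONS:
            bad.append(section)
            continue
        block = getattr(ps, section)
        valid = {f.name for f in fields(block)}
        if not isinstance(values, dict):
            bad.append(section)
            continue
        for key, value in values.items():
            if key not in valid:
                bad.append(f"{section}.{key}")
                continue
            if key == "age_adjustment_table":
                value = {int(k): float(v) for k, v in value.items()}
            setattr(block, key, value)
            if logger is not None:
                logger.info("override %s.%s = %r", section, key, value)
    if bad:
        raise ValidationError(f"unknown configuration keys: {', '.join(sorted(bad))}")
    return ps


def load_parameter_set(config_path: str | Path | None = None, logger=None) -> ParameterSet:
    """Load a fully populated parameter set.

    ``config_path`` points to a YAML or JSON file holding nested overrides
    (sections ``cohort``, ``risks``, ``effects``, ``costs``, ``utilities``,
    ``mortality``; optionally ``life_table`` with a CSV path).  Missing keys
    keep their bundled defaults.  Unknown keys or out-of-range values raise
    :class:`ValidationError` naming the offending keys.
    """
    ps = ParameterSet()
    if config_path is not None:
        path = Path(config_path)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text()
        cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        cfg = cfg or {}
        if not isinstance(cfg, dict):
            raise ValidationError("configuration root must be a mapping")
        if cfg.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
            raise ValidationError(f"unsupported schema_version (expected {SCHEMA_VERSION})")
        if "life_table" in cfg:
            lt_path = Path(cfg["life_table"])
            if not lt_path.is_absolute():
                lt_path = path.parent / lt_path
            ps = ps.replace(life_table=LifeTable.from_csv(lt_path))
        ps = _apply_overrides(ps, cfg, logger=logger)
    return ps.validate()


# ---------------------------------------------------------------------------
# Distribution fitting for the probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution for one parameter.

    ``family`` is one of ``beta``, ``lognormal``, ``gamma`` or ``fixed``;
    ``params`` holds family-specific parameters; ``source`` records the
    printed summary (mean, ci_low, ci_high) the fit was derived from.
    """

    family: str
    params: tuple[float, ...]
    source: tuple[float, float, float] | None = None

    def mean(self) -> float:
        if self.family == "fixed":
            return self.params[0]
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        if self.family == "lognormal":
            mu, sigma = self.params
            return float(np.exp(mu + 0.5 * sigma**2))
        if self.family == "gamma":
            k, scale = self.params
            return k * scale
        raise ValueError(self.family)

    def median(self) -> float:
        if self.family == "lognormal":
            return float(np.exp(self.params[0]))
        return float(self._frozen().ppf(0.5)) if self.family != "fixed" else self.params[0]

    def _frozen(self):
        if self.family == "beta":
            return stats.beta(*self.params)
        if self.family == "lognormal":
            mu, sigma = self.params
            return stats.lognorm(s=sigma, scale=np.exp(mu))
        if self.family == "gamma":
            k, scale = self.params
            return stats.gamma(k, scale=scale)
        raise ValueError(f"no frozen form for family {self.family!r}")

    def interval95(self) -> tuple[float, float]:
        if self.family == "fixed":
            return (self.params[0], self.params[0])
        frozen = self._frozen()
        return (float(frozen.ppf(0.025)), float(frozen.ppf(0.975)))

    def sample(self, rng: np.random.Generator, size: int):
        if self.family == "fixed":
            return np.full(size, self.params[0])
        if self.family == "beta":
            return rng.beta(*self.params, size=size)
        if self.family == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mu, sigma, size=size)
        if self.family == "gamma":
            k, scale = self.params
            return rng.gamma(k, scale, size=size)
        raise ValueError(self.family)


def fit_lognormal_from_ci(point: float, lo: float, hi: float) -> DistributionSpec:
    """Lognormal with log-scale mean ``ln(point)`` and log-scale sd
    ``(ln hi - ln lo) / (2 * 1.96)`` — the standard back-calculation from a
    ratio estimate with a 95% confidence interval."""
    if not (0 < lo < point < hi):
        raise ValidationError("require 0 < lo < point < hi for a lognormal fit")
    mu = float(np.log(point))
    sigma = float((np.log(hi) - np.log(lo)) / (2.0 * 1.959963984540054))
    return DistributionSpec("lognormal", (mu, sigma), source=(point, lo, hi))


def fit_beta_from_ci(mean: float, lo: float, hi: float) -> DistributionSpec:
    """Beta with the given mean whose central 95% interval best matches
    ``(lo, hi)`` in least squares, found by a 1-D search over the effective
    sample size ``alpha + beta``."""
    if not (0 <= lo <= mean <= hi <= 1):
        raise ValidationError("require 0 <= lo <= mean <= hi <= 1 for a beta fit")
    if mean in (0.0, 1.0):
        return DistributionSpec("fixed", (mean,), source=(mean, lo, hi))

    def loss(log_n: float) -> float:
        n = np.exp(log_n)
        a, b = mean * n, (1.0 - mean) * n
        q = stats.beta.ppf([0.025, 0.975], a, b)
        return float((q[0] - lo) ** 2 + (q[1] - hi) ** 2)

    res = optimize.minimize_scalar(loss, bounds=(np.log(1e-2), np.log(1e8)), method="bounded")
    n = float(np.exp(res.x))
    return DistributionSpec("beta", (mean * n, (1.0 - mean) * n), source=(mean, lo, hi))


def fit_beta_from_mean_sd(mean: float, sd: float) -> DistributionSpec:
    """Beta by moment matching (used where only a plausible sd is assumed)."""
    if not (0 < mean < 1):
        return DistributionSpec("fixed", (mean,))
    n = mean * (1.0 - mean) / sd**2 - 1.0
    if n <= 0:
        raise ValidationError("sd too large for a beta distribution with this mean")
    return DistributionSpec("beta", (mean * n, (1.0 - mean) * n))


def fit_gamma_from_ci(mean: float, lo: float, hi: float) -> DistributionSpec:
    """Gamma with the given mean whose central 95% interval best matches
    ``(lo, hi)``; 1-D search over the shape parameter."""
    if not (0 < lo <= mean <= hi):
        raise ValidationError("require 0 < lo <= mean <= hi for a gamma fit")

    def loss(log_k: float) -> float:
        k = np.exp(log_k)
        q = stats.gamma.ppf([0.025, 0.975], k, scale=mean / k)
        return float((q[0] - lo) ** 2 + (q[1] - hi) ** 2)

    res = optimize.minimize_scalar(loss, bounds=(np.log(1e-3), np.log(1e8)), method="bounded")
    k = float(np.exp(res.x))
    return DistributionSpec("gamma", (k, mean / k), source=(mean, lo, hi))
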