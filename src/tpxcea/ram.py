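"""Risk assessment model (RAM) operating points and the logit-scale ROC
regression used to explore the sensitivity/specificity trade-off.

An operating point is a (sensitivity, specificity) pair at a named score
threshold.  The bundled defaults are the two Padua sets validated in a
medical inpatient cohort (Greene 2016) and in a mixed medical/surgical
cohort (Elias 2017); other RAMs and cohorts are user-supplied.  All values
are stored as fractions; rendering multiplies by 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import ValidationError

__all__ = [
    "RamOperatingPoint",
    "RocFit",
    "treated_fraction",
    "fit_roc_logit",
    "sensitivity_at",
    "optimal_curve_point",
    "load_operating_points",
    "default_operating_points",
    "padua_point",
]


@dataclass(frozen=True)
class RamOperatingPoint:
    ram_name: str
    threshold_label: str
    sensitivity: float
    specificity: float
    source_cohort: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.sensitivity <= 1 and 0 <= self.specificity <= 1):
            raise ValidationError("sensitivity and specificity must lie in [0, 1]")


def treated_fraction(op: RamOperatingPoint, prevalence) -> float:
    """Fraction of the cohort flagged high-risk (hence treated).

    ``prevalence * sensitivity + (1 - prevalence) * (1 - specificity)``,
    where prevalence is the total 90-day VTE risk without prophylaxis
    (PE + symptomatic DVT + asymptomatic DVT; 0.3386 at defaults).
    """
    if np.any(np.asarray(prevalence) < 0) or np.any(np.asarray(prevalence) > 1):
        raise ValidationError("prevalence must lie in [0, 1]")
    return prevalence * op.sensitivity + (1.0 - prevalence) * (1.0 - op.specificity)


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class RocFit:
    """Ordinary-least-squares fit of logit(TPR) on logit(FPR) across RAM
    operating points — a binormal-style summary ROC used to interpolate
    sensitivity at any specificity."""

    intercept: float
    slope: float
    fit_points: list[RamOperatingPoint] = field(default_factory=list)
    residuals: np.ndarray | None = None


def fit_roc_logit(points: list[RamOperatingPoint]) -> RocFit:
    """Fit the logit-scale ROC regression.

    Degenerate points (sensitivity or false-positive rate of exactly 0 or 1)
    cannot be mapped to the logit scale; they are excluded with a warning.
    Fewer than two usable points is an error.
    """
    usable = [
        p
        for p in points
        if 0 < p.sensitivity < 1 and 0 < 1.0 - p.specificity < 1
    ]
    if len(usable) < len(points):
        warnings.warn("degenerate operating points excluded from the ROC regression")
    if len(usable) < 2:
        raise ValidationError("need at least two non-degenerate operating points")
    x = _logit(np.array([1.0 - p.specificity for p in usable]))
    y = _logit(np.array([p.sensitivity for p in usable]))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return RocFit(float(intercept), float(slope), usable, resid)


def sensitivity_at(fit: RocFit, specificity: float) -> float:
    """Sensitivity on the fitted curve at a given specificity.

    The curve's limits are used at the endpoints: specificity 0 maps to
    sensitivity 1 and specificity 1 to sensitivity 0 (for positive slope).
    """
    if specificity <= 0.0:
        return 1.0 if fit.slope > 0 else float(_expit(fit.intercept))
    if specificity >= 1.0:
        return 0.0 if fit.slope > 0 else float(_expit(fit.intercept))
    return float(_expit(fit.intercept + fit.slope * _logit(1.0 - specificity)))


def optimal_curve_point(
    fit: RocFit,
    lam: float,
    model,
    step: float = 0.001,
) -> dict:
    """Locate the operating point on the fitted ROC curve that maximises net
    monetary benefit at willingness-to-pay ``lam``.

    ``model`` is a callback ``(sensitivity, specificity) -> (cost, qalys)``
    evaluating the full lifetime model for an arbitrary operating point.
    A grid search over specificity (default step 0.001, endpoints included)
    is used; ties are broken toward higher sensitivity.
    """
    grid = np.arange(0.0, 1.0 + step / 2, step)
    best = None
    for spec in grid:
        sens = sensitivity_at(fit, float(spec))
        cost, qalys = model(sens, float(spec))
        nmb = lam * qalys - cost
        key = (nmb, sens)
        if best is None or key > best[0]:
            best = (key, float(spec), sens, float(nmb))
    _, spec, sens, nmb = best
    return {"specificity": spec, "sensitivity": sens, "nmb": nmb}


# ---------------------------------------------------------------------------
# Bundled operating points
# ---------------------------------------------------------------------------


def load_operating_points(path: str | Path) -> pd.DataFrame:
    """Read an operating-point table (ram, cohort, threshold, sensitivity,
    specificity) from CSV; values as fractions."""
    df = pd.read_csv(path, comment="#")
    required = {"ram", "cohort", "threshold", "sensitivity", "specificity"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"operating-point table missing columns: {sorted(missing)}")
    return df


def default_operating_points() -> pd.DataFrame:
    """The bundled Padua operating points (Greene 2016 and Elias 2017)."""
    with resources.files("tpxcea").joinpath("data/padua_operating_points.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def padua_point(threshold: int, cohort: str = "Greene2016") -> RamOperatingPoint:
    """Convenience lookup into the bundled Padua table."""
    df = default_operating_points()
    row = df[(df["cohort"] == cohort) & (df["threshold"] == threshold)]
    if row.empty:
        raise KeyError(f"no bundled Padua >= {threshold} point for cohort {cohort}")
    r = row.iloc[0]
    return RamOperatingPoint(
        ram_name="Padua",
        threshold_label=f"Padua >={threshold}",
        sensitivity=float(r["sensitivity"]),
        specificity=float(r["specificity"]),
        source_cohort=cohort,
    )
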