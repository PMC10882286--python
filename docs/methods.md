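# Methods

## Model structure

The analysis couples a six-month decision tree to a lifetime Markov
cohort model, the standard architecture for prophylaxis questions where
acute events are concentrated in a short window and their sequelae play
out over decades.

**Decision tree (months 0–6).** The tree is an expectation machine: it
propagates cohort-level probabilities, not individual patients, so every
"count" is an expected value per 10,000 admissions. Three strategy kinds
are supported — prophylaxis for none, for all, or for patients flagged by
a risk assessment model (RAM). RAM arithmetic assumes the score flags
VTE-destined patients with probability equal to its sensitivity, so VTE
risks scale by `sens·RR_VTE + (1 − sens)`, while bleeding follows
treatment receipt and scales by `f·RR_bleed + (1 − f)` with `f` the
treated fraction at prevalence 0.3386 (total 90-day VTE risk including
asymptomatic DVT; this prevalence, not the symptomatic-only 3.4%,
reproduces the published treated percentages). VTE and major bleeding are
independent; treated risks are always unrounded products of baseline risk
and relative risk — chaining rounded intermediate values fails to
reproduce the published cells. Symptomatic VTE survivors
(non-fatal PE + symptomatic DVT) receive three months of anticoagulation
and carry the treatment-phase bleed risks. In rendered tables the
"fatal bleed" column is hospital-phase only, while the ICH and
other-major-bleed columns include treatment-phase events; treatment-phase
fatal bleeds still count toward mortality. Asymptomatic DVT is
undiagnosed: no treatment, no acute cost or utility decrement, but full
PTS risk.

**Chronic complication assignment (at six months).** Diagnosis of
post-thrombotic syndrome (PTS) and chronic thromboembolic pulmonary
hypertension (CTEPH) is deferred to the end of the tree phase, where the
full cumulative risks (3-year PTS, 2-year CTEPH) are applied as a
one-time assignment — the simplest structure consistent with deferred
diagnosis; spreading onset over several cycles would shift a small amount
of discounting and mortality attrition but not the strategy ordering.
PTS entrants are DVT survivors weighted by location and symptom status;
CTEPH entrants are PE survivors times 3.2%, split 50:50 between medical
and surgical management; ICH survivors enter a post-ICH state. No
recurrent VTE and no post-ICH PTS/CTEPH are modelled.

**Markov phase (six months to age 100).** Eight states; the only
transition is death. A six-month cycle spans months 6–12 with the full
first-year all-cause mortality applied at its start (at six months);
annual cycles follow with half-cycle-corrected occupancy (transitions at
mid-cycle). Discounting (3.5%/year, configurable) uses cycle-midpoint
times throughout; acute event costs and tree-phase utility effects are
discounted to t = 0.25 years and prophylaxis/assessment costs fall at
admission.

**Mortality.** A sex-weighted life table supplies baseline annual death
probabilities (linear interpolation in age; the year-1 probability is
evaluated at its application time, age₀ + 0.5; terminal probability 1 at
the age cap of 100). Multipliers: 9.4 for every state in the first year
after admission (this also covers ICH survivors, whose own first-year
ratio of 4.5 is below the cohort-wide 9.4); 2.2 for post-ICH in years
2–6; a CTEPH multiplier (default 3.0, an unprinted placeholder —
configure to taste) throughout time in a CTEPH state; products capped at
probability 1. Sex is handled as a weighted average of the life-table
columns rather than two sub-cohorts; for a cohort-level expectation model
the difference is second order.

## Parameters

All defaults live in `tpxcea.parameters` and are overridable through a
YAML/JSON config (sections `cohort`, `risks`, `effects`, `costs`,
`utilities`, `mortality`; probabilities as fractions, costs in 2020 GBP,
durations in days or years as named). Key values: 90-day VTE risks
without prophylaxis 1.38% (PE), 2.02% (symptomatic DVT), 30.46%
(asymptomatic DVT); hospital-phase bleed risks 0.10/0.06/0.51%
(fatal/ICH/other), treatment-phase 0.21/0.08/0.56%; PE case fatality
26.8%; prophylaxis relative risks 0.49 (VTE) and 1.53 (bleeding); PTS
risks 32.4/56.5/15.6% (symptomatic proximal / asymptomatic proximal /
distal); CTEPH 3.2%; cohort age 65.8, 44.5% male, five days of LMWH at
£23.91 per course, £9.08 per risk assessment; utility 0.800 in year one
with a multiplicative age-band index thereafter, chronic multipliers
0.895 (PTS), 0.629 (CTEPH), 0.888 (post-ICH).

Unprinted quantities carry package defaults, flagged here: proximal
fractions of symptomatic (0.6) and asymptomatic (0.2) DVT, chosen so the
cumulative PTS count for the no-prophylaxis strategy lands near the
published five-year figure; CTEPH surgical share 0.5 and mortality
multiplier 3.0; the age–utility index table (shaped like published
general-population EQ-5D norms, normalised to 1 at the 65–74 band); the
anticoagulation cost components inside the symptomatic-VTE event costs
(£182 phased vs £130 DOAC at a 60:40 split — only the *difference*
matters, because the bundled event-cost totals are quoted at the default
split and shifting the DOAC share moves costs by the component
difference alone); the per-extra-day LMWH cost (course/5) plus a
configurable community-administration cost (default £0) for the
seven-day scenario.

## Economic accounting conventions

- Deaths during the tree phase receive half-phase utility credit.
- Acute event utilities replace the background utility for six months
  (one month for non-intracranial bleeds); the prophylaxis decrement
  (0.007) runs for the treated days and the anticoagulation decrement
  (0.011) for three months among treated VTE. Discontinuation of
  anticoagulation after a major bleed is handled at expectation level;
  its effect on the expected decrement duration is below 1e-5 QALYs and
  is ignored.
- PTS costs: the first-year cost is charged as an entry lump
  (£293.16 − £78) plus the £78 annual cost over person-years in state;
  surgical CTEPH is a single entry lump; medical CTEPH and post-ICH are
  annual per-person-year costs. The ICH 90-day cost is an acute event
  cost; the ICH annual cost accrues from Markov entry (the three-month
  overlap is ignored).
- In five-year output tables the PTS column reports cumulative incidence
  (entrants, including those who later die), matching the convention of
  the six-month event columns; the other chronic columns report survivors
  in state at five years and the death column cumulative deaths.

## Probabilistic sensitivity analysis

Every numeric parameter may hold a vector of Monte-Carlo draws; the whole
pipeline is elementwise, so one vectorised evaluation per strategy covers
all draws (10,000 draws × 9 strategies in roughly a second). Default
distributions (the source tables print means and 95% CIs but not
families): beta for probabilities fitted from mean + CI by a 1-D search
over the effective sample size; lognormal for relative risks and SMRs
(log-mean at the point estimate, log-sd from the CI width); gamma for
event costs with an assumed ±20% interval; beta for utilities and
multipliers with an assumed sd of 0.02. The three bleed subtypes share a
single "any major bleed" draw split by the fixed subtype proportions, so
type ratios are preserved in every draw. RAM sensitivity/specificity and
the unit costs of assessment and prophylaxis are fixed; RAM performance
uncertainty is explored through scenarios instead. Draws violating model
validity are rejected (abort above 1% rejection). Where a beta
constrained to the printed mean cannot reproduce a strongly asymmetric
printed interval (notably PE case fatality, 26.8% with CI 11.3–33.1%),
the least-squares fit is used and the limitation noted — no distribution
family with that mean matches those quantiles.

## Scenarios and searches

Named scenarios cover seven-day LMWH (two post-discharge days costed),
all-DOAC treatment, a 2% PTS utility decrement, zero PTS after
asymptomatic distal DVT, low/high PE case fatality (13%/67%), the
high-performance (mixed-cohort) Padua operating points, and VTE/bleed
risk multipliers. Threshold searches bisect a risk multiplier (tolerance
1e-3, bounds [1/100, 100], shrinking an endpoint that leaves the valid
parameter space) for the smallest change that alters the argmax-NMB
strategy; two-way grids label the optimal strategy per cell. Scenario
conclusions are structural, not numeric: under this package's lifetime
model and synthetic life table the seven-day scenario leaves treat-all
marginally cost-saving rather than pushing it to a small positive ICER,
while removing asymptomatic-distal PTS does produce a positive ICER;
the optimal-strategy orderings are unchanged throughout.

## Synthetic data: what it does and does not emulate

`tpxcea.synth` generates (a) Gompertz life tables
(h(age) = a·exp(b·age); defaults give q(65) ≈ 1.3%/0.9% for men/women,
doubling roughly every seven years — the shape of a contemporary UK
national life table, not a copy of one) and (b) RAM validation cohorts
from a latent-risk model: outcome first (Bernoulli prevalence), then a
latent score from the class-conditional distribution, discretised to an
integer score. The binormal latent (default) has the closed-form
AUC = Φ(δ/√2) used for generator checks; the logistic latent produces a
ROC that is exactly linear on the logit scale (slope 1, intercept δ) and
is the appropriate truth for validating the logit-scale ROC regression —
against a binormal truth that regression carries an irreducible
approximation gap of about 0.03 in sensitivity at the extremes, which is
a property of the functional forms, not an estimation error. An
individual-level microsimulation of the six-month pathway provides an
independent stochastic oracle for the expectation tree.

Passing tests on these fixtures demonstrate internal correctness —
expectation arithmetic, estimator recovery, accounting identities — not
external validity: real cohorts have miscalibration, correlated risks,
time-varying hazards and messier score distributions than any latent
model, and a real national life table differs from a two-parameter
Gompertz. Absolute lifetime costs/QALYs therefore depend on the supplied
life table and the unprinted defaults above; the deterministic six-month
table, treated fractions and frontier logic do not.

## Numerical choices

- Integer rendering of per-10,000 counts uses round-half-up; exact
  fractional expectations are kept internally.
- Frontier construction: weak dominance removal (naming the cheapest
  dominator), then iterative extended-dominance removal until ICERs
  strictly increase; exact ties on both axes keep the first-listed
  strategy. CEAC ties split probability equally.
- The meta-analysis implements DerSimonian–Laird directly (method of
  moments, truncated at zero — truncation is part of the contract:
  τ² = 0 whenever Q ≤ df) with Paule–Mandel as the alternative
  estimator; zero cells get a 0.5 continuity correction on all four
  cells of the affected study.
- ROC grid search over specificity (default step 0.001) maximises NMB
  with ties broken toward higher sensitivity; curve endpoints map to
  (sens 1, spec 0) and (sens 0, spec 1).
- Distribution fits use bounded scalar minimisation on a log scale for
  the free shape parameter.

## Limitations

Single-admission cohort; no recurrent VTE, heparin-induced
thrombocytopenia, or post-ICH thrombotic sequelae; no within-admission
event timing; no correlation structure in the PSA; NHS & Personal Social
Services perspective only, 2020 GBP, no currency or inflation machinery.
RAM scores are taken as (sensitivity, specificity) pairs — the package
does not rebuild scores from patient covariates.
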