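# tpxcea

Cost-effectiveness modelling of pharmacological thromboprophylaxis
strategies for eligible adult medical inpatients.

Medical inpatients are at elevated risk of venous thromboembolism (VTE —
deep vein thrombosis and pulmonary embolism) for about 90 days after
admission. Low-molecular-weight heparin (LMWH) prophylaxis roughly halves
that risk (pooled relative risk 0.49) but raises the risk of major
bleeding (relative risk 1.53) and costs money and nursing time. Hospitals
can give prophylaxis to **everyone**, to **no one**, or use a **risk
assessment model** (RAM, e.g. the Padua score) to treat only patients
flagged as high risk. `tpxcea` quantifies that trade-off for health
economists and guideline developers: which strategy buys the most
quality-adjusted life years (QALYs) for the least NHS cost?

## Model

A **six-month decision tree** turns baseline risks into expected event
counts per 10,000 patients. For a RAM with sensitivity *se* and
specificity *sp* at VTE prevalence *π* (= 0.3386 at defaults, including
asymptomatic DVT):

- treated fraction  *f = π·se + (1 − π)(1 − sp)*
- VTE risks scale by  *se·RR_VTE + (1 − se)*  (VTE-destined patients are
  flagged with probability *se*)
- hospital-phase bleed risks scale by  *f·RR_bleed + (1 − f)*
- symptomatic VTE survivors receive three months of anticoagulation,
  carrying treatment-phase bleed risks.

A **lifetime Markov cohort model** (states: well, post-DVT, post-PE,
post-thrombotic syndrome, medically/surgically managed chronic
thromboembolic pulmonary hypertension, post intracranial haemorrhage,
dead) extrapolates survival and chronic morbidity with standardised
mortality ratios layered on a life table, a six-month cycle to one year
(first-year mortality applied at six months) and half-cycle-corrected
annual cycles thereafter. Costs (2020 GBP) and utilities are attached per
state and discounted at 3.5%/year; strategies are compared on the
incremental cost-effectiveness frontier and by net monetary benefit
(NMB = λ·QALYs − cost). A vectorised Monte-Carlo probabilistic
sensitivity analysis (PSA), a scenario engine, one/two-way threshold
searches, a DerSimonian–Laird meta-analysis of trial 2×2 tables, and a
logit-scale ROC regression across RAM operating points complete the
toolkit. A synthetic-data module generates Gompertz life tables and
latent-risk validation cohorts so everything runs with no downloads.

## Worked example

```bash
tpxcea --out-dir out ce
```

```
      strategy   tpx_pct  sensitivity_pct  specificity_pct       cost    qalys                      status
          None   0.00000              0.0            100.0 220.620762 9.095520 dominated_by All inpatients
     Padua >=3  34.55078             49.3             73.0 214.750614 9.120879 dominated_by All inpatients
All inpatients 100.00000            100.0              0.0 209.220210 9.145335                    frontier
```

(abridged; the full table has one row per strategy). Read: treating every
eligible inpatient costs £209.22 per patient over a discounted lifetime
and yields 9.1453 QALYs — cheaper *and* more effective than treating no
one (£220.62, 9.0955) or than Padua-guided prophylaxis at any threshold,
so every alternative is dominated. `tpxcea outcomes` prints the event
table per 10,000 patients (for "None": 37 fatal and 101 non-fatal
pulmonary embolisms, 53 other major bleeds at six months);
`tpxcea psa --n 10000` runs the PSA (treat-all has the highest NMB at
£20,000/QALY in ≈96% of draws and dominates treat-none in ≈64%);
`tpxcea scenario elias_operating_points` shows that with a very high
sensitivity RAM (99.9% at Padua ≥3), threshold-based prophylaxis becomes
optimal. In Python:

```python
from tpxcea import load_parameter_set, evaluate_strategy, strategy_all

params = load_parameter_set()          # bundled defaults, or a YAML path
res = evaluate_strategy(strategy_all(), params)
print(res.cost, res.qalys)             # 209.22 9.1453
```

## Layout

| Module | Role |
| --- | --- |
| `tpxcea.parameters` | defaults, validation, config loading, distribution fitting |
| `tpxcea.evidence` | random-effects meta-analysis of relative risks |
| `tpxcea.ram` | operating points, treated fractions, ROC logit regression |
| `tpxcea.tree` | six-month decision tree |
| `tpxcea.markov` | lifetime Markov extrapolation |
| `tpxcea.economics` | costs, QALYs, NMB, frontier |
| `tpxcea.psa` | probabilistic sensitivity analysis, CEAC |
| `tpxcea.scenarios` | named scenarios, threshold searches, two-way grids |
| `tpxcea.synth` | synthetic life tables, cohorts, microsimulation oracle |
| `tpxcea.cli` | `tpxcea` command-line interface |

See `docs/methods.md` for modelling assumptions, parameter provenance and
known limitations.
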