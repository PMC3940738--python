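# spinecea

Cost-effectiveness analysis of lumbar discectomy that accounts for worker
productivity. The package is aimed at health economists and outcomes
researchers who want a tested, scriptable implementation of a societal-
perspective cost-utility comparison of surgical versus nonsurgical treatment
of lumbar disc herniation in privately insured, working-age patients.

## What it computes

A deterministic annual-cycle **Markov cohort model** tracks each treatment
arm over states *satisfactory outcome*, *unsatisfactory outcome*, a temporary
*revision surgery* state (surgical arm only, at most two revisions), and
absorbing *death*. Utilities (0.89 / 0.56 / 0.69) and direct medical costs
accrue per cycle at a 3% annual discount rate; natural mortality comes from a
packaged life table and surgical mortality (0.0013 per operation) applies to
every operation.

Indirect costs use the **human-capital approach**: regressions on
survey-style microdata (ordinary least squares for household earnings,
negative-binomial NB2 for missed workdays, both on a functional-limitations
index score with age-group terms) are evaluated at the trial functional
scores of the two arms, giving an annual earnings premium of surgery and a
missed-workday change, with a missed day worth 1/240th of annual earnings and
a one-time 20-workday recovery absence after the initial operation.

With discounted direct costs A (surgical) and F (nonsurgical), QALYs E and G,
earnings offset B and signed missed-workday offset C, the package reports

```
net surgical cost  D = A - B - C
ICER               = (D - F) / (E - G)      [USD per QALY]
```

plus the direct-cost-only ratio (A - F)/(E - G), per-setting variants
(blended / inpatient-only / outpatient-only surgery payment), per-age-cohort
results, a benefit-horizon sweep with the first cost-saving year, and a
twelve-parameter one-way sensitivity analysis for a 40-year-old reference
patient. Cost-saving (dominant) results are flagged, never reported as
negative ratios.

Because the underlying survey microdata are not redistributable, the
`synthetic_nhis` module generates worker populations with the statistical
structure the regressions assume (calibrated so the fitted pipeline
reproduces the published weighted productivity row), and the published
productivity table is packaged so the economic model can also run without
any regression stage.

## Worked example

```python
from spinecea import run_cea

res = run_cea(horizon=4)                 # base case, all age cohorts weighted
print(f"E={res.surgical_qaly:.3f}  G={res.nonsurgical_qaly:.3f}")
print(f"A=${res.surgical_cost:,.0f}  F=${res.nonsurgical_cost:,.0f}")
print(f"B=${res.earnings_offset:,.0f}  C=${res.missed_workday_offset:,.0f}")
print(f"ICER=${res.icer:,.0f}/QALY  "
      f"(direct costs only: ${run_cea(horizon=4, include_productivity=False).icer:,.0f})")
```

prints

```
E=3.055  G=2.740
A=$30,918  F=$14,435
B=$7,314  C=$-1,821
ICER=$34,838/QALY  (direct costs only: $52,251)
```

Surgery adds 0.32 discounted QALYs and $16,483 in direct medical cost over
four years; the earnings premium returns $7,314 while extra missed workdays
(the 20-day recovery outweighs the ~3 days/year regained) cost $1,821, so
accounting for productivity lowers the cost per QALY from ~$52k to ~$35k.
The same run from the shell, writing all result tables as CSV/JSON:

```
spinecea run --out results/            # tables 3-5 analogues + horizon sweep
spinecea sensitivity --all             # one-way sweep, 40-year-old patient
spinecea simulate-nhis --n 100000 --seed 1 --out micro.csv
spinecea fit-productivity --microdata micro.csv --out results/
```

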