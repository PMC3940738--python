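# Methods

## Model structure

The decision model is a deterministic Markov cohort simulation with a
one-year cycle (all rates, costs and productivity flows are annual). A
cohort enters at treatment with lumbar disc herniation and follows one of
two arms:

* **Nonsurgical**: the cohort splits once into *satisfactory* (p = 0.485)
  and *unsatisfactory* (0.515) outcomes and remains there until natural
  death.
* **Surgical**: per-operation mortality (0.0013) applies at t = 0; of the
  survivors, 6% undergo revision surgery within the first year (incurring
  the operative mortality again) and the rest split into satisfactory
  (p = 0.753) / unsatisfactory outcomes. In each later year, patients in
  either outcome state may need a revision (3%/year); the revision year is
  spent in a temporary state with utility 0.69 and resolves the next cycle
  into satisfactory/unsatisfactory with the same success probability as
  primary surgery (0.753, also used for the second revision). At most two
  revisions are allowed, enforced by expanding the outcome states with a
  revision count r = 0, 1, 2; states at r = 2 have no revision exit.

Death is absorbing. Natural mortality is looked up by current age
(band midpoint + elapsed cycles) in a life table; the packaged table is a
synthetic stand-in built by log-linear interpolation of both-sex US annual
mortality anchors of roughly 2009 magnitude (ages 18–100). At 4–8-year
horizons, results are insensitive to fine life-table detail (well under 1%).

Occupancy is recorded at the start of each cycle and must sum to one to
1e-12 at every cycle (checked at run time and by property tests). The
engine is verified against an independent exhaustive path-enumeration
oracle (agreement to 1e-10 for short horizons), and against closed-form
annuity expressions when revisions are disabled.

## Accrual and discounting conventions

All streams discount at 3%/year. The published analysis does not state its
cycle-timing convention, so each stream's timing is an explicit flag,
calibrated once so that the pipeline reproduces the published 4-year
cost-effectiveness table and then frozen as the defaults:

* **Utilities and annual medical costs**: cycle-start (annuity-due),
  survival-weighted through the state occupancy.
* **Initial surgery cost**: t = 0, undiscounted, charged to the whole
  cohort. **Revision cost** equals the initial surgery cost (the source is
  silent) and is charged at the cycle in which the revision state is
  occupied, discounted; revision-year patients also accrue the annual
  medical cost (both choices configurable).
* **Productivity offsets in the Markov pipeline**: cycle-start, weighted by
  the surgical arm's alive fraction; the 20 recovery days are charged
  undiscounted at t = 0 at the baseline (nonsurgical) daily wage.
* **Plain annuity convention** (unweighted, cycle-end; recovery discounted
  one cycle): exposed separately — it reproduces the published narrative
  quantities such as the $1925 × 3.7171 ≈ $7.2k four-year premium value.
* **Sensitivity module**: unweighted cycle-end offsets with recovery at
  t = 0, which best matches the published sensitivity table's base ratio
  and its recovery-day row spread.

The recurring missed-workday term uses the productivity table's
value-change column (each arm's missed days valued at that arm's earnings
per workday) rather than day-count × single wage; the day-count is kept for
reporting (≈3 days/year weighted, ≈11 days over four years discounted).

## Economic parameters

Direct medical costs (2009 USD, private-payer level): surgery $16,423
blended ($20,585 inpatient-only, $11,616 outpatient-only); annual
non-surgery medical costs $3,208 (surgical arm) and $3,794 (nonsurgical).
The productivity table carries, per age group (<40, 40–44, …, 60–64,
weighted by the surgical age distribution 32/15/17/15/12/9%): functional
scores of the two arms, predicted household earnings, and the predicted
value of missed workdays, with the weighted row at scores 0.86/0.76 giving
the $1,925/yr earnings premium and $523/yr missed-day value change used by
the base case. A 240-workday year converts earnings to a daily wage.

The ICER identity D = A − B − C, ICER = (D − F)/(E − G) is computed on
unrounded values; incremental QALY of zero yields an undefined ratio
(reported as NaN with no dominance flag), and a negative incremental net
cost with positive QALY gain is reported as dominance (cost saving) rather
than a negative ratio.

## Reference patient for sensitivity analysis

The one-way sweep uses a 40-year-old: mortality from age 40 with the
youngest cohort's productivity row (premium $1,810/yr; missed-day reduction
2.7 days/yr, $503/yr value change; earnings $44,713/$42,903). This row was
chosen over the 40–44 band because the published sensitivity table's base
values ($1,810 and 2.7 days) match it. When the day-count is swept, the
value change scales proportionally from the base row. Twelve parameters are
swept over the published ranges (±10% or the 95% CI); endpoints are
reported in the printed orientation, so a pair is inverted when the
parameter relationship is negative.

## Synthetic microdata generator

The generator emulates survey respondents with back pain radiating below
the knee: an age group drawn from the surgical age mix, a
functional-limitations score from a normal distribution (mean 0.75,
sd 0.18) truncated to [0, 1], household earnings linear in score
(slope $19,250 per score unit, age-group offsets, Gaussian noise sd $8,000,
negatives resampled rather than censored to avoid a point mass at zero),
and missed workdays from an NB2 distribution (variance μ + μ²/k, k = 1.5)
with log-link mean (slope −3.71, age offsets normalised so the weighted
exp-offset is one), capped at 240 days.

Coefficients were calibrated once so that fitting the two regressions on a
large generated sample and predicting at the trial scores reproduces the
published weighted productivity row (earnings levels/premium and
missed-day values within ~1% in the population limit, tested at 3%
including sampling noise). The earnings noise level is a calibration choice
that keeps the n = 10⁵ end-to-end reproduction within that band; real
household-earnings dispersion is considerably larger, so the generator
demonstrates correctness of the econometric pipeline, not survey realism.
Also not emulated: survey weights and design effects, employment-status
changes, covariates beyond score and age, and per-age-group score/earnings
inconsistencies present in the published per-age rows (which cannot all be
generated by a common-slope model; the weighted row is the calibration
anchor). Passing tests therefore show parameter recovery and pipeline
correctness on NB2/linear data, not validity of the published regressions.

## Numerical and degenerate-input choices

Probabilities, utilities, weights and ranges are validated with named
errors; transition rows must sum to 1 (1e-12). The NB2 fit is statsmodels
maximum likelihood (nb2 log-likelihood); non-convergence raises with the
last gradient norm, and an all-zero count vector is rejected (log-link mean
0 unrepresentable). A saturated OLS fit (e.g. two points) reports residual
sd 0. Life-table lookups clamp to the tabulated age range. Horizons must be
≥ 1 year; problem sizes used by the test suite (n = 10⁴ microdata × 50
replicates for coverage, n = 10⁵ for the end-to-end row, 1,000 random
parameter draws for conservation) keep the full suite under a minute on one
CPU while leaving Monte-Carlo margins comfortable.

## Known limitations

* The published per-age cost-effectiveness rows and two sensitivity rows
  (surgery cost, surgical annual spend) are internally asymmetric in ways a
  single-parameter linear response cannot reproduce; the package matches
  the overall/weighted results and the symmetric rows, and reproduces those
  two rows directionally.
* Uncertainty is first-order only (one-way sweeps); no probabilistic
  sensitivity analysis, and no propagation of regression standard errors
  into the ICER.
* Nonsurgical patients never cross over to surgery; microdiscectomy and
  open discectomy are not distinguished; recovery absenteeism applies to
  the initial operation only (configurable).
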