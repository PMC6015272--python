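# Methods

This note records the models, parameter choices and numerical decisions
behind `trialcea`, and what the synthetic-data validation does and does
not demonstrate.

## Costing

**Health-service costs.** Resource-use counts are multiplied by national
average unit costs (packaged table; £ 2014, VAT/on-costs/overheads already
embedded in the unit costs, so never re-applied). Costs are aggregated
into three sections per window — nurse-recorded services, nurse-recorded
medications, self-reported services, over 12 months pre-baseline, 0–3
months and 3–12 months — mirroring how the data were collected. A missing
count for any single item makes the whole section missing; the rule is
idempotent and order-invariant (tested by permutation). Prescriptions are
assumed chronic and issued monthly: the summed monthly cost of current
items is multiplied by 12, 3 or 9 months. A blank prescription record is
missing data unless an explicit no-medication flag was recorded. No
discounting (12-month horizon).

**Intervention cost.** Fixed annual operating cost = staff activities +
infrastructure. The staff schedule is costed as time × hourly rate ×
annual frequency, with the published row values authoritative: three rows
(£6,675 emails/newsletters, £890 forum monitoring, £1,780 content
checking) are not reproducible from any single annualisation convention
(52 weeks, 26 fortnights, 7.5-hour day), so the formula column exists as
an audit (rows flagged above 2% relative discrepancy) while totals use
the printed figures. Per-user training (£3,863 / 185) is conservatively
held constant per user as the base grows; facilitation is 20 minutes of a
practice nurse's hour (£44) plus a £0.95 booklet. The default
"component rounding" mode rounds each per-participant component to the
nearest pound before summing (226 + 21 + 16 = 263); unrounded mode
(≈ £262.4) is available by flag. The control arm incurs no intervention
cost. Capacity is bounded at 10,000 active users (server limit).

## Outcomes

EQ-5D-3L profiles map to utilities through the UK TTO tariff in additive
decrement form; the packaged value-set file carries a provenance header
and an md5 checksum of its data rows, and the scorer refuses to run
without a verifying file. PAID is 20 items scored 0–4, total rescaled to
0–100 (×1.25), with ≥ 40 flagging significant distress. QALYs are the
trapezoid through the 0/3/12-month utilities (0.25- and 0.75-year
segments), using the baseline utility as the 0-month point with no
pre-randomization extrapolation. Twelve-month assessments are valid as
outcomes only within the closed interval [10, 14] months (the boundary is
inclusive; the published rule does not state open/closed); out-of-window
measurements are kept as auxiliary imputation predictors.

## Missing data

Chained equations with predictive mean matching, separately by arm, on
the aggregated variables (9 section costs, 6 outcome scores, 2 auxiliary
raw 12-month measurements, plus any incomplete baseline covariate).
Details the published analysis leaves open were fixed as: variables
visited in ascending missingness; 10 chained cycles; predicted means from
a lightly ridge-stabilised linear regression of each variable on all
others plus baseline covariates (binary covariates as indicators); k = 5
nearest donors with ties broken by a seeded uniform jitter; m = 30 by
default (the rule of thumb of one imputation per percentage point of
missingness, with ≤ 30% missing), configurable. Because every fill is an
observed donor value from the same arm, imputations never leave the
observed support. Estimates are pooled with Rubin's rules; when the
between-imputation variance vanishes the t reference degenerates to the
normal.

## Inference

Each outcome (total 12-month cost, QALY, 12-month PAID) is regressed on
arm, age, sex, cardiovascular history, smoking, diabetes duration and the
corresponding baseline outcome, with a random centre intercept (REML, no
interactions or time terms). When REML estimates the centre variance at
the boundary (zero), the model collapses to ordinary least squares and
the exact OLS solution is returned — this also underpins the 1e-6
mixed-versus-OLS oracle equivalence in the tests. A singular or
non-finite mixed fit falls back to a fixed-intercept model with a
warning.

Uncertainty: nonparametric bootstrap, participants resampled with
replacement within arm (arm sizes fixed). The published analysis does not
state how the bootstrap and the imputation were combined; here each
replicate resamples the original incomplete data, runs one stochastic
imputation and fits the models, while the m = 30 imputation is reserved
for the point estimates and their Rubin CIs. Replicate fits use the
fixed-intercept regression: at B = 5,000 the mixed fit is two orders of
magnitude more expensive, the centre intraclass correlation is small, and
the two coincide exactly at zero centre variance. Confidence intervals
from the cloud are percentile (the published analysis says only
"construct 95% CI"). The CEAC reports P(λ·ΔE − ΔC > 0) on a £0–50,000
grid in £500 steps (the £20,000 and £30,000 thresholds always on-grid);
replicates with ΔE exactly 0 count as not cost-effective (measure-zero
for continuous data). The CEAC is defined for the QALY effect only —
there is no accepted willingness-to-pay scale per PAID unit.

## User-scaling sensitivity

ICER(n) = (F/n + v + ΔC_hs)/ΔQALY with fixed annual cost F, per-user
variable cost v, and the health-service cost difference ΔC_hs (adjusted
incremental total cost minus the per-participant intervention cost) held
fixed — the assumption being that per-user health-service impact and
QALY gain generalize as the base grows. In the default rounded-component
mode v and ΔC_hs are first rounded to whole pounds (37 and −152) while
F/n stays continuous, making the curve smooth and the break-even root
exact: n* = F/−(v + ΔC_hs) = 41,796/115 ≈ 363.4, reported as 363 users;
unrounded mode reports its own root alongside. The curve is strictly
decreasing while ΔQALY > 0 and crosses zero at most once.

## Synthetic trial generator

The generator emulates the published trial's structure, with defaults set
to the published conditions: 374 participants (the realized arm split is
an outcome of stratified permuted-block randomization with block sizes
2/4/6, so per-centre imbalance never exceeds 3), 21 unevenly recruiting
centres, baseline covariates at the published means (age ≈ 64.8 ± 9.3,
69% male, diabetes duration ≈ 8 years; cardiovascular history 30% and
smoking 15% chosen as typical for a UK type 2 diabetes population, the
trial report not printing them), arm-level utility/PAID/cost means per
the published summary table, and questionnaire nonresponse at the
published completion rates (23%/20% at 3 months, 30%/29% at 12 months).

* **Utilities** are sampled on the 243-state tariff grid: a latent normal
  per timepoint (sharing a within-person factor, correlation 0.6, and a
  centre intercept carrying 15% of the latent SD) is snapped to the
  nearest tariff value, and a concrete profile with that value is
  emitted, so the tariff scorer runs end to end. The latent location is
  calibrated by root-finding on the exact post-snapping expectation, so
  sampled utilities are unbiased for the target mean; snapping and the
  ceiling at full health compress the SD somewhat (≈ 0.19 realized vs
  0.23 latent target). A direct-utility mode (clipped normal) exists for
  degenerate cases such as zero-noise checks, where grid quantization
  would forbid hitting an arbitrary mean exactly.
* **PAID** items are correlated ordinal 0–4 draws: a per-person response
  tendency p from a beta distribution (calibrated so the rescaled total
  matches the target mean exactly and the target SD through a
  beta-binomial variance decomposition) drives 20 conditionally
  independent Binomial(4, p) items.
* **Costs** are Poisson service counts with a gamma participant frailty
  per section (dispersion 1, so section costs are right-skewed with SD on
  the order of the mean) and a log-normal centre multiplier (SD 0.1);
  expected section costs equal their targets exactly. Window totals split
  55/30/15 over services/medications/self-report and 25/75 over the 0–3
  and 3–12 month windows. Prescriptions are a Poisson number of items
  (mean 4) with gamma monthly costs; zero items sets the explicit
  no-medication flag.
* **Assessment months** are jittered: N(3, 0.3) for the 3-month visit and
  N(12, 1.0) for the 12-month visit, putting ≈ 5% of 12-month assessments
  outside the [10, 14] validity window — enough to exercise the filter
  while keeping complete-case retention near the published ≈ 52%. (A much
  wider jitter would invalidate a quarter of assessments and contradict
  the published retention.)
* **Effect embedding**: given targets (ΔC, ΔQALY), the intervention arm
  is rebuilt from the control arm with identical baselines, the QALY
  increment spread equally over the 3- and 12-month utilities
  (ΔQALY = 0.875·δ), and trial-window cost means shifted by
  ΔC − intervention cost. Adjusted contrasts then equal the targets in
  expectation, enabling parameter-recovery validation.
* **Missingness** is questionnaire-level (EQ-5D + PAID + self-reported
  services blank together), MCAR by default with an optional logistic
  tilt on the always-observed baseline PAID — missing-at-random by
  construction, never depending on removed values. Nurse-recorded
  sections blank at 0.5% per section-window and diabetes duration at
  1.1%, matching the published four participants with unknown duration.
* One root seed drives a named spawn sequence of per-operation generators
  (centres, randomization, covariates, costs, utilities, PAID,
  assessment, missingness), recorded in the metadata sidecar; identical
  configurations are byte-identical.

**What passing tests show, and what they do not.** The generator
reproduces the first moments, missingness structure and skewness of the
published data, so recovery tests validate the estimators' correctness
under the study's sample sizes and nonresponse. It does not reproduce
genuine electronic-record artifacts, item-level questionnaire
missingness, informative dropout, or the true joint dependence of costs
and utilities; performance on real trial data can differ accordingly.
PMM on heavily skewed cost sections shows a small finite-sample
attenuation (well within a tenth of the CI width at trial size), visible
in simulation and documented rather than corrected.

## Problem sizes and runtimes

Validation uses trial-scale data (374 participants) with m = 5
imputations in the 100-seed recovery study (a few minutes on one core);
examples use B = 200 bootstrap replicates. The production defaults remain
m = 30 and B = 5,000, matching the published analysis; at those settings
a full analysis takes tens of minutes on one core.

## Known limitations

* The bootstrap replicates use single imputation and fixed-intercept
  fits (see above); replicate-level between-imputation variance is
  therefore folded into the resampling variability rather than separated.
* The cost–effect correlation among replicates was never published, so
  CEAC values are validated as a bracket (0.85–0.91 at £20,000/QALY over
  correlations 0–0.3) rather than a point.
* No EQ-5D-5L, crosswalks or non-UK tariffs; no PAID subscales; no
  probabilistic or multi-way sensitivity analysis; no extrapolation
  beyond the 12-month horizon.
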