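# Methods

This note documents the models, the default parameters and the design
decisions of `hfcoi`, in the order of the analysis pipeline. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Synthetic cohort generator

**What it emulates.** A 502-patient hospital heart-failure sample measured
bottom-up: categorical covariates drawn from the published marginals (NYHA
class 106/189/88/119, male 61.1%, basic insurance 91.2%, complementary
42.4%, comorbidity 61%, household head 72%), age from a normal
(63.46, 14.27²) truncated by rejection to the observed range [8, 95], and
follow-up equiprobable over {2, 4, 6} months (only the min/max are
published). Cost components are observed per person-month as zero-inflated
right-skewed mixtures: zero with probability `zero_prob`, else lognormal
(default) or gamma with given mean and CV. Calibration inverts the mixture
moments so the marginal mean/SD equal annual targets exactly; the implied
SD floor `mean·√(p₀/(1−p₀))` is enforced with an explicit error.

**Defaults and why.**

| parameter | default | rationale |
|---|---|---|
| component annual targets | published annual means/SDs | the one published description of the cost distributions |
| treatment split | monthly non-hospital mean = (44.98M − 0.6·17.4M)/12 | hospitalization is stated to be ~20% of direct-medical cost; with 60% hospitalized the admission mean is 17.4M Toman |
| `zero_prob` per component | 0.10/0.35/0.45/0.50 | zero-cost prevalence per component is unpublished; assumptions, config-exposed |
| `p_zero_cost` (no cost at all) | 35/502 ≈ 7% | the published per-observation AIC is consistent only with 467 positive-cost observations of 502 |
| `p_death_in_year` | 0.05 | annual heart-failure mortality in the clinical literature is ~5–10% |
| employment mix | 35% employed / 40% housewife / 25% retired | the study population is described as mostly housewives or retired |
| monthly wage | 4,179,750 Toman | Iranian statutory minimum monthly wage, 2022 |
| unpaid shadow wage | 50,000 Toman/h | replacement-cost convention; no published value |
| unpaid hours lost | mean 330 h/month, 15% zeros | chosen so the marginal annual unpaid-work cost ≈ the published 168M Toman |
| PPP factor | 11,900 Toman/PPP$ | the ratio of all three published Toman/PPP pairs (they agree to 0.0002%) |

Covariates and components are drawn independently (only marginals are
published); an optional per-class cost multiplier can induce a
class–severity gradient. **What passing tests do not show:** real cost data
have correlated components, class-dependent utilization and seasonal
effects; the generator makes no claim about them, so downstream estimates on
synthetic cohorts validate the *machinery* (estimators, engines,
arithmetic), not the study's empirical cost levels. The generated cohort's
annual totals land in the same order of magnitude as the published table
(~190–240M vs 261M Toman grand total) but are not calibrated to equality,
since the productivity-loss inputs behind the published indirect costs
(days absent, wage structure) are unpublished.

## 2. Prevalence-based annual costing

Person-month monthly means ×12; the admission bill enters once per year
(invariant to follow-up length). Human-capital valuation as in the README;
non-employed patients contribute zero absenteeism/presenteeism by
construction, unpaid work is valued for everyone. Premature death is valued
as lost earnings to retirement age (default 65) with a configurable annual
discount rate; the default is 0 because the study states none, and a
fractional final year contributes its fraction discounted at the following
year-end (so integer horizons reproduce the plain geometric sum exactly).
Job change is a wage-differential cost whose default of 0 matches the
published finding of no job-change cost.

Aggregation: arithmetic means, sample SDs (n−1); a single-observation
cohort reports SD 0 with a warning rather than NaN. Shares are
`100·component/total`, kept raw and also half-up rounded with
largest-remainder reconciliation so rounded shares sum to 100. The
published direct-medical *total* exceeds the sum of its three published
components by ≈42,610 Toman; the package always reports component sums and
flags that discrepancy in the reference fixture's consistency report rather
than reproducing it.

## 3. Six-state Markov lifetime model

States NYHA I–IV plus heart-failure death and other-cause death (both
absorbing); 25 one-year cycles; occupancy propagated as `π_{t+1} = π_t P`.
Cycle-*t* accrual = alive occupancy at cycle start × state annual cost +
newly absorbed HF-death mass × entry cost, discounted by `(1+r)^{−t}`.
Choices where the design was open:

- **Discounting** defaults to 0 (the study does not mention it); 3%/5% are
  one config field away.
- **Half-cycle correction** defaults off; when on, adjacent occupancies are
  averaged for the occupancy costs (the entry cost is event-based and needs
  no correction). At zero discount the correction telescopes to
  `½·Σ_s(π_T[s]−π_0[s])·c_s`, which the tests verify.
- **HF-death costing**: a one-time entry cost (present value of earnings
  lost at premature death), not a recurring annual cost. This is the only
  reading under which a death state can accumulate the largest share of
  lifetime cost, and it is documented as an interpretation.
- **State costs** default to the per-class annual means of the prevalence
  stage (that is how the study derives them); the shipped transition matrix
  is a clearly labelled synthetic placeholder with plausible
  progression/mortality gradients — the real per-cycle probabilities come
  from treatment-effectiveness literature and are config-supplied. A
  least-squares helper can search alive-row probabilities (softmax-logit
  parameterized) to match a target per-state cost attribution; it is a
  convenience for exploration, not an estimation method.
- **Cycle convention**: costs accrue at t = 0…24 with occupancy evaluated
  at cycle starts; life years are the undiscounted alive occupancy sum.

Validation is structural (row sums within 1e-9, absorbing death states,
no initial mass in death states) and returns *every* violation. The engine
is cross-checked against `hfcoi.microsim`, an independent per-trajectory
implementation of the same accrual rules; agreement within 3 Monte-Carlo
SEs at 10⁵ paths is part of the acceptance suite. Per-state attributions
sum to the lifetime total at machine precision.

## 4. Two-part regression

Probit (Newton, tolerance 1e-12, gradient norm checked; separation and
non-convergence raise) for `P(cost > 0)` on the full sample; gamma/log GLM
(IRLS, Pearson dispersion) on the positive subsample. Gamma/log is the
default because costs are positive and right-skewed and the published
log-scale intercept (~19.6 ≈ ln of annual Toman costs) is consistent with a
log link; family and link are configurable. Disease class enters as one
linear term (matching the published single coefficient row); gender is
coded female = 1 (the published coding is unstated; ours is documented and
recodable). The parts' log-likelihoods add: the any-cost indicator and the
positive density partition the semicontinuous likelihood.

A constant positive response is handled analytically (intercept `g(c)`,
slopes 0, zero deviance, SEs 0 with undefined test statistics) because the
IRLS variance estimate collapses there.

Information criteria are all labelled: whole-model `2k − 2ℓ`,
per-observation `(2k − 2ℓ)/n` (the convention under which the published
footer AIC of 40.87735 with ℓ = −9538.861943 and k = 6 reconciles at
n = 467), Schwarz `k·ln n − 2ℓ`, and the deviance-based
`D − df_resid·ln n`. No convention is claimed to reproduce the published
BIC, whose inputs are unpublished.

**Simulation studies.** The shipped data-generating process uses
realistic-magnitude coefficients and a unit-shape gamma. Coverage of the
nominal 95% CIs is checked at n = 5,000 over 2,000 replicates against a
93–97% band; 2,000 replicates put the Monte-Carlo SE of each coverage
estimate near 0.5%, so the band is a ≈4σ check rather than one a correct
estimator would fail by chance. Predicted-vs-observed cohort-mean parity is
checked within 2% at n = 10,000.

## 5. Numerical conventions and limitations

- Percent shares round half-up; reconciliation is largest-remainder.
- All monetary arithmetic is float64; totals of means are formed before any
  rounding.
- Cohort CSVs round-trip bit-exactly (floats serialized at full precision,
  parsed with the round-trip parser).
- Problem sizes used by the checks: 10⁵ microsimulation paths and 10⁶
  calibration draws (3-SE and 2% bands respectively), chosen so Monte-Carlo
  error is well inside each band.
- Limitations: no probabilistic sensitivity analysis, no QALY arm, no
  censoring model (zeros are modelled, censoring is not), no real tariff
  schedules, and no claim that synthetic-cohort regression coefficients
  estimate the study's (the patient data are unavailable; coefficient
  recovery is demonstrated only against the package's own known process).
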