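# Methods

## The model

A participant's day is a four-part composition `x = (Sleep, SB, LPA,
MVPA)` of strictly positive durations. All analysis happens after the
isometric log-ratio (ilr) map built from the sequential binary partition
that peels parts off in a fixed order ("pivot coordinates"):

    z_k = sqrt((D-k)/(D-k+1)) * ln( x_k / gmean(x_{k+1..D}) ),  k = 1..D-1.

The canonical part order is (Sleep, SB, LPA, MVPA). The map is an
isometry between the simplex with Aitchison geometry and R^3, invariant
to the closure constant, and invertible (softmax of the contrast matrix
times z, re-closed). Rotated pivot bases put each behavior first while
keeping the remaining parts in canonical order; any two such bases are
related by an orthogonal 3x3 rotation, so fits are basis-invariant and
the first coordinate's coefficient under the basis pivoting behavior *b*
is the per-behavior summary gamma(b): *b relative to the geometric mean
of everything else*.

Outcome models are ordinary least squares with classical (non-robust)
standard errors:

    y ~ 1 + z1 + z2 + z3 + covariates

with y either the wave-0 score (cross-sectional) or the wave-1 minus
wave-0 change (prospective; the wave-0 score always enters as a
covariate). Adjustment is cumulative — model 1: sex, age; model 2 adds
education, marital status, household economy; model 3 adds smoking,
alcohol, energy intake, BMI, MMSE, gait-speed category and
chronic-disease count. Categorical covariates are treatment-coded with
the first *observed* level as reference (declared orders: no_studies,
single, difficult economy, current smoker, heavy drinker, gait score 0,
no conditions first); rank-deficient designs are rejected with the
collinear columns named. Gamma p-values are two-sided t-tests on the
residual df; no multiple-testing correction is applied across the four
outcomes. The "composition model p" is the nested F-test (3 numerator
df) of the full model against the model without z1..z3; a
likelihood-ratio variant is available (`joint_method="lr"`). Gamma can
be obtained by refitting under each pivot basis (default) or by rotating
the canonical-basis coefficients and covariance (`gamma_method="rotate"`);
the two agree to machine precision and both are exposed because the
choice is sometimes audited.

## Isotemporal substitution

For a reallocation of `delta` minutes from part A to part B at a
reference day r, the estimate is the linear contrast

    ES = (ilr(r') - ilr(r))' beta_comp,   r' = r with A-delta, B+delta,

whose exact 95% interval under the linear model is
`ES ± t(0.975, df) * sqrt(c' Sigma_comp c)`. Covariate columns are shared
by the two predictions and cancel identically, so ES does not depend on
where covariates are held. The reference day defaults to the analytic
sample's compositional mean closed to 1440 min — the standard choice in
compositional isotemporal work; it is an argument, not a constant,
because estimates at other reference days differ (the surface is linear
in ilr space, not in minutes). A seeded parametric bootstrap over the
coefficient distribution is available as an alternative interval. The
donor part must stay positive; `delta = 0` returns exactly zero.

Near-antisymmetry of opposite moves (ES(A->B) ≈ -ES(B->A)) holds only
while `delta` is small relative to *both* parts; 30-min moves in or out
of a ~48-min MVPA part are far outside that locally linear regime, and
the asymmetry there is a property of the log-ratio surface, not an error.

## Instruments

GDS-10 (0-10): negative answers to the three positively worded items
(1, 5, 8; 1-based questionnaire order) and positive answers to the rest
are summed. Missing items are rejected by default; an optional proration
(requiring >= 8 answered items, rescaling to 10 and rounding) is provided
for reuse on messier data but is an extension beyond the instrument's
published rule. Loneliness is the sum of three items coded 1-3 (range
3-9). Happiness is the 0-10 Cantril ladder. The SF-12 MCS enters as a
pre-computed 0-100 score (norm mean 50, SD 10); its proprietary scoring
coefficients are deliberately not implemented. Change scores are wave 1
minus wave 0, and missing outcomes are handled listwise *per outcome*, so
per-outcome sample sizes differ slightly.

## The synthetic-data generator

The generator emulates the structure of a two-wave accelerometer cohort
of community-dwelling adults aged >= 65:

- **Compositions**: multivariate normal on the ilr scale, centred at the
  ilr image of the geometric-mean day (470.59, 778.61, 143.28, 47.52
  min), mapped back to the simplex — i.e. logistic-normal, strictly
  positive by construction. The default covariance is diagonal
  (0.04, 0.04, 0.09): MVPA gets the largest relative variability, making
  it the least co-dependent part in the implied variation matrix, which
  matches how such cohorts look; the matrix is fully configurable since
  no empirical covariance is pinned down.
- **Covariates**: categorical frequencies (53.07% women, 66.05% married,
  85.74% easy household economy, ...) and normal continuous marginals
  (age 71.68 ± 4.33 y, energy 1944.99 ± 345.03 kcal/d, BMI 27.76 ± 4.42,
  MMSE 27.99 ± 2.00, rounded and capped at 30), drawn independently of
  composition.
- **Outcomes**: linear in the canonical ilr coordinates plus optional
  covariate effects plus Gaussian noise, then mapped to the instrument
  scale (rounded/clipped for the ordinal scales, clipped for MCS; the
  truncation rate is logged and stored in `DataFrame.attrs`). Default
  effect directions make relative MVPA beneficial for all four outcomes,
  with intercepts placing means near 0.93 (depression), 3.69
  (loneliness), 7.49 (happiness) and 50.4 (MCS). For estimator checks
  (calibration, coverage, the substitution oracle) the transform is set
  to `"none"`: rounding to a 0-10 scale attenuates coefficients, and
  those checks are about the estimator, not the measurement model.
- **Wave 1**: retention is Bernoulli with default loss 810/2489 ≈ 32.5%
  (missing completely at random; a covariate-dependent mechanism is out
  of scope), follow-up time is normal 2.31 ± 0.31 y, and wave-1 scores
  are wave-0 plus drift (+0.06 depression, +0.08 loneliness, −0.14
  happiness, −0.59 MCS — worsening mood, declining well-being) plus
  noise, with an optional baseline-composition effect on the change for
  prospective-recovery experiments.
- **Day records**: 7 days per participant (days 6-7 weekend); wear hours
  normal 23.8 ± 1.5 h truncated to [0, 24] (near-continuous wrist wear);
  the day's composition is the participant's mean perturbed by ilr noise
  (SD 0.25) and closed to the worn minutes, so behavior minutes never
  exceed wear time. The validity filter then mirrors field practice: a
  day is valid at >= 16 h wear, a participant at >= 4 valid days with at
  least one weekend day, and retained participants get the arithmetic
  mean of valid-day minutes re-closed to 1440.

All randomness derives from one seed through fixed stream ids (one per
operation), so regenerating day records does not perturb the cohort draw.

What the generator does **not** emulate: correlated covariates,
informative attrition, outcome-outcome correlation beyond the shared
composition signal, day-of-week structure in behavior (weekends differ
only by label), floor/ceiling-induced skew beyond simple truncation, and
measurement error in the accelerometer classification itself. Passing
tests therefore demonstrate the estimators and plumbing are correct under
the assumed data-generating process, not that the scientific conclusions
transfer to any particular real cohort.

## Numerical choices

- Zeros in compositions are a hard error naming the offending part
  (full-day time-use has none); `replace_zeros` offers multiplicative
  replacement below a user-supplied detection limit for other data types.
- Closure is short-circuited when the input already sums to the target
  within 1e-12 relative tolerance, making it exactly idempotent;
  downstream identities are asserted at 1e-9.
- Ternary densities bin into `resolution^2` equal-area upward/downward
  triangular cells (default 50 per edge), keep empty cells as zeros, and
  export cell centroids in barycentric coordinates — equal-area cells
  make a uniform simplex sample uniform across cells, which a
  nearest-lattice-point scheme would not.
- The day-record tables and cohort CSVs round-trip through pandas with
  pinned categorical level orders (`timecoda.cohort`).
- Sensitivity analyses: the random-10%-removal check is repeated (default
  5 sub-seeded replicates) and reported as a distribution of gamma
  shifts, with "significant shift" operationalised descriptively as any
  gamma changing sign or crossing alpha = 0.05; the MMSE >= 24 rerun and
  the cross-sectional-on-prospective-subsample rerun reuse the same
  machinery.

## Problem sizes

The test suite and `scripts/acceptance.py` use n = 500-2000 cohorts, 1000
replicates for null calibration, and 200 replicates for CI coverage —
sizes at which the Monte-Carlo error of the checked rates (about ±0.007
for a 5% rejection rate at 1000 replicates) is comfortably inside the
asserted bands.

## Known limitations

Single-level OLS only (no mixed models, survey weights or imputation);
one-to-one reallocations only (no one-vs-remaining variant); ilr-linear
outcome surfaces (no splines or interactions with composition); the SF-12
scoring algorithm is consumed, not computed; and raw accelerometer signal
processing (ENMO thresholds of <45 mg SB, 45-100 mg LPA, >= 100 mg MVPA
on the non-dominant wrist; sleep detection) is upstream of this package,
which starts from daily minutes per behavior.
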