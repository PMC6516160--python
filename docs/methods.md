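# Methods

`murihaz` analyses age-specific mortality in sex-structured rodent
survival cohorts. This note records the statistical models, the defaults
and why they were chosen, what the synthetic-cohort generator does and
does not emulate, and the numerical decisions a maintainer would want to
know about.

## Smoothed hazard estimation

The central engine is a penalized B-spline Poisson (P-spline) model of the
age-specific hazard. Follow-up from weaning (entry at 21 days; no
person-time or events are counted earlier — left truncation) is aggregated
into age bins of width 30 days: deaths `d_j` and animal-days at risk `R_j`
per bin, with half-open bins `[e_j, e_{j+1})` except the last (closed).
Each animal contributes the overlap of `(entry, age]` with each bin, so
`sum_j R_j` equals total follow-up exactly. Conditionally on exposure,
`d_j ~ Poisson(R_j h_j)` and the log hazard at bin midpoints is expanded
in a uniform cubic B-spline basis (12 interior knots, equally spaced over
the observed age range, with `degree` extension knots of the same spacing
beyond each boundary). The penalized log likelihood

    sum_j [ d_j log(R_j h_j) - R_j h_j ] - (lambda / 2) ||D_2 theta||^2

is maximized by penalized IRLS (converged when the largest coefficient
change is below 1e-8, with step-halving on likelihood decreases and an
explicit stop on flat-likelihood plateaus in data-free regions). The
uniform (unclamped) basis is deliberate: with equal knot spacing the null
space of the second-order difference penalty is exactly the affine
functions of age, so `lambda -> infinity` shrinks the fit to a Gompertz
(log-linear) hazard rather than to a basis-dependent curve. With
`lambda = 0`, degree 0 and one basis per bin the fit reproduces the raw
occurrence/exposure rates `d_j / R_j` — the two limits bracketing the
smoother.

`lambda` is selected by a variance-component (mixed-model) argument: the
penalized coefficients are random effects whose second differences have
variance `phi / lambda`. The update `sigma^2 = (||D theta||^2 +
tr(D C D')) / rank(D)`, alternated with refitting, is solved as a fixed
point in `log lambda` with secant acceleration, because the plain
iteration crawls geometrically whenever the truth is (near-)log-linear
and the optimum sits at the smooth boundary; `lambda` is clamped to
`[1e-8, 1e8]` and a boundary solution is reported as converged.
Overdispersion `phi` is fixed at 1 by default (a Pearson estimate is
available). Pointwise 95% intervals are `exp(log h +/- 1.96 se)` with the
standard error from the penalized-information covariance of the linear
predictor; the fitted spline is evaluated on a 1-day grid.

## Hazard-ratio curve and bootstrap bands

The male:female ratio divides two hazards fitted with identical settings
on shared bin edges. The ratio grid (5-day step) covers ages where both
sexes have positive person-time **and** at least `max(10, 2% of the
sex's n)` animals still at risk: smoothed ratios on the last handful of
animals are boundary extrapolation, and the nonparametric bootstrap
undercovers there because too few distinct animals support the resample.
Uncertainty comes from resampling animals with replacement within sex
(optionally within sex-site-cohort), refitting both hazards per replicate
with the smoothing parameter re-selected (propagating smoothing
uncertainty; fixing `lambda` is a speed option), and taking pointwise
2.5th/97.5th order-statistic percentiles across replicates. Order
statistics (rather than interpolated quantiles) make the band exactly
symmetric under curve inversion and degenerate to the min/max envelope at
`B = 2`. A replicate in which either sex has no events is redrawn and
counted.

The summary reports the peak (argmax of the point estimate; first age on
ties; a curve with range below 0.05 is flagged as having no distinct
peak) and the convergence age: the smallest post-peak age from which the
band contains 1 at **every** later grid age. Convergence is a sustained
state — a single touch of the band is noise. The sustained rule is
honest but brittle at the right boundary: a terminal wiggle of the
smoothed ratio in the last few bins can postpone or suppress the reported
convergence age in some realizations; the at-risk grid cutoff mitigates
but does not eliminate this.

## Classical survival comparisons

Kaplan–Meier curves are computed directly (ties by simultaneous
multiplication; censorings tied with a death remain at risk for it), with
the cumulative variance of `log S` by Greenwood (`sum d/(n(n-d))`,
default) or Aalen (`sum d/n^2`). The median is the smallest age with
`S <= 0.5` (with a 1e-12 slack so cumulative-product rounding cannot
shift the crossing); its CI inverts the log-transformed pointwise band of
S. The log-rank test is the standard one-degree-of-freedom hypergeometric
O−E sum. Maximum lifespan is operationalized as the age by which the
pooled two-sex population reaches 90% mortality (KM-based, hence
censoring-consistent); within each sex the proportion of animals still
alive at that age is compared by a two-sided Fisher exact test
(probability ordering of tables; `scipy.stats.fisher_exact`), with
Clopper–Pearson proportion CIs. Animals censored before the threshold
have unknown status there and are excluded by default (`censored_rule`
switches this); the proportion can be taken from raw counts (default) or
from the per-sex KM at the threshold.

## Association models

The Cox model of lifespan on sex, site and sex-by-site uses lifelines
with the Efron tie correction; factors are dummy-coded against reference
levels F and TJL, and the interaction block is judged by a likelihood
ratio test against the additive model (the LRT is invariant to the
coding, which is why it, not a single coefficient, carries the
conclusion). Bodyweight analyses first exclude weights of censored
animals and "post-mortem" weights (measurement age after the recorded
age at death; when the measurement day is not recorded, the nominal age
`months x 30.44` days stands in), counting every exclusion per rule and
sex. Lifespan (days) is then regressed on weight (grams) by OLS within
sex-by-measurement-age strata; the standardized coefficient is
`beta * sd(weight) / sd(lifespan)`, whose square equals R² in the
univariate fit — an identity the tests assert at 1e-10. Interaction
models add the moderator (sex or site) and product terms, with an F-test
of the interaction block. A sensitivity filter can drop animals above a
weight threshold; it is idempotent and order-independent with the other
exclusions.

## The synthetic cohort generator

Because the real multi-site dataset is available only on request, every
stage is exercised against a generator with known ground truth:

* **Female hazard**: Gompertz, `h_F(t) = a e^{bt}` with defaults
  `a = 1.0516e-4 /day`, `b = 0.0035819 /day` (doubling time ~193 days).
* **Male hazard**: `h_F(t)` times a unimodal excess-mortality bump
  `exp(B(t) log(peak_ratio * m_site))`, with `B` piecewise cubic — a
  smoothstep from 0 at weaning to 1 at the peak age (350 d), then
  `1 - 1.5u^2 + 0.5u^3` down to 0 at the convergence age (800 d) and 0
  beyond. The falling flank meets zero with nonzero slope so the ratio
  declines steadily into convergence rather than approaching 1
  tangentially (a flat-tailed shape makes the band-based convergence age
  land far too early, and a discontinuous slope larger than this one
  biases the smoother locally). The male-only site effect multiplies the
  peak ratio (`TJL = UT = 1`, `UM = 0.55`), confining it to the same
  mid-life window: at UM the sex gap in medians nearly vanishes while a
  reduced mid-life excess remains, and all sites share identical
  late-life mortality.
* **Frailty**: one standard-normal latent `z` per animal multiplies the
  hazard by `exp(c z g(t))` with sex-shared coupling `c = 0.5` and an age
  profile `g` that is 1 until 200 days before the convergence age and
  smoothsteps to 0 by 100 days after it. Tapering the heterogeneity out
  by the convergence age keeps the marginal hazard continuous, makes the
  pooled male:female ratio settle at exactly 1 in late life (survivor
  selection would otherwise hold it below 1), and lets the oldest-age
  weight-lifespan slope reverse. Death ages are drawn by inverse
  transform on a dense cumulative-hazard surface (daily ages x 181
  frailty nodes, linear blending between nodes); the grid extends far
  enough into the Gompertz tail that the survival mass beyond it is
  numerically zero.
* **Calibration**: `(a, b)` are solved (Gauss–Hermite integration over
  frailty) so the population medians are 887 days for females and 803
  days for pooled males — the anchors the preset is meant to reproduce.
* **Censoring**: males are caged three to a cage (females four); each
  male cage is independently censored with probability 0.06, all members
  at one age drawn uniformly between weaning and the cage's earliest
  death (whole-cage censoring on fight wounds, without modelling
  aggression). Optional administrative censoring at a fixed age.
* **Bodyweight**: growth toward a frailty-shifted asymptote
  `A_i = mu_sex + c_w z_i` (`mu` 30 g females / 38 g males; `c_w` 0.8 /
  2.0 g; growth rate `ln 10 / 180` per day, i.e. 90% of the asymptote by
  6 months), minus a terminal loss of up to 10% of `A_i` ramping over the
  final 120 days of life, plus N(0, 1.5 g) measurement noise, measured at
  6/12/18/24 months for animals still under observation. The shared
  frailty makes heavier animals die younger (strongly in males, weakly in
  females, via the sex-specific weight couplings); the terminal loss
  flips the slope positive among 24-month survivors.
* **Reproducibility**: one pseudo-random stream per cohort-site-sex
  block, spawned hierarchically from the seed; identical configs yield
  bit-identical tables.

What the generator does **not** emulate: cause-of-death structure,
litter/maternal effects, seasonal or cohort-year heterogeneity (cohorts
are exchangeable replicates), drug arms, and the full variance structure
of real lifespans. In particular, with a Gompertz baseline flat enough
for the mid-life excess to carry an ~84-day median gap, the intrinsic
(Gumbel) lifespan spread is large, so weight explains only a few percent
of lifespan variance; the generator reproduces the sign pattern, the
male-dominant magnitude ordering and the 24-month reversal of the
weight-lifespan slopes, but not the large standardized coefficients seen
in real data. Similarly, the mid-life-confined site effect yields a
time-averaged Cox interaction that is weaker than a proportional-hazards
site effect would be. Passing tests therefore demonstrate correct
recovery of the encoded structure, not distributional realism of real
husbandry data.

## Numerical and interface choices

* Ages are days since birth everywhere; months appear only as the
  categorical measurement-age label (nominal month = 30.44 days).
* On-disk formats are headered CSV (`cohort.csv`, `weights.csv`),
  round-trip exact for all valid rows; rows failing validation are
  rejected with file line numbers, duplicate animal ids are a hard
  error, and orphan weights (unknown animal id) are excluded with a
  warning and counted.
* The pipeline writes a manifest with a SHA-256 checksum per output and a
  config hash that excludes the output directory, so re-running an
  identical analysis in a different location is recognized as identical.
* Simulation sizes in the test suite are scaled to the property being
  checked: single-seed recovery runs use ~2,000-5,000 animals per sex;
  repeated-seed calibration and coverage runs use 100 seeds at ~500-1,800
  per sex with 200 bootstrap replicates (the analysis default is 1,000).

## Known limitations

* The convergence-age statistic inherits the brittleness of its
  sustained-containment definition near the right grid boundary (above).
* No time-varying covariates inside the smoother, no competing risks, no
  restricted-mean survival, no Gompertz parameter inference (the smoother
  exists precisely to avoid relying on the Gompertz form), and no
  multiplicity correction across the four measurement ages.
* Cage-level censoring is drawn before the cage's earliest death, which
  is mildly informative; at the default 6% cage rate the effect on KM
  and hazard estimates is negligible, and the brute-force checks of the
  marginal hazard include it.
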