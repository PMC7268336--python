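# Methods

`refcurve` estimates *continuous reference intervals* (RIs) for pediatric
laboratory analytes: the 2.5th and 97.5th percentiles of an analyte in a
healthy population, expressed as smooth functions of age rather than
constants per age bracket.  Four estimation methods are implemented and
compared under a common validation protocol.  This note records the
models, the defaults and why, and the known limitations.

## Data model and cleaning

Input is a per-subject table `(age, sex, value)` with ages in decimal
years on [1, 20) and positive analyte values.  Records missing any field
are rejected at ingest.  All fitting is sex-stratified; no covariates
beyond age and sex are modelled.

Outlier removal follows Tukey's rule per (sex, one-year age) group:
values outside `[Q1 - 1.5 IQR, Q3 + 1.5 IQR]` are dropped.  Because the
quartile geometry underlying the rule presumes rough normality, each
group is first checked with a Shapiro-Wilk test (alpha = 0.05); on
rejection the group is Box-Cox transformed (power chosen by profile
maximum likelihood over a lambda grid [-3, 3] in steps of 0.01, shift
c = 0 for positive analytes) and the fences are applied on the
transformed scale.  Since the transform is strictly increasing, this is
equivalent to applying back-transformed fences to the raw values.
Groups under 20 records skip the normality test (no power) and use raw
fences; groups under 4 records pass through untouched, flagged.
Quantiles use linear interpolation of order statistics (numpy default)
package-wide.

## The four estimation methods

### Improved non-parametric

The age-sorted stratum is cut into overlapping *time frames* of
`n = 120` subjects whose starts advance by `m = 2` subjects.  The
default n is the CLSI minimum sample size for a reference interval; the
small offset keeps adjacent frames nearly identical so rapid changes
(the pubertal ALP fall) are tracked.  Within each frame the 2.5th/97.5th
percentiles are bootstrapped: B = 500 resamples of size n, limit = mean
of the resample percentiles, SE = their standard deviation.  The
(mean age, limit) point sets are then smoothed — penalized spline by
default; cubic smoothing spline and fractional polynomials are
available and comparable by AIC.  If the smoothed lower and upper curves
cross anywhere the fit raises an error naming the age interval (a real
failure mode of fractional polynomials on noisy limits) rather than
returning a silently invalid interval.

A caveat found in simulation and worth stating: because adjacent frames
share n − m members, the discrete limit series is strongly
autocorrelated, and automatic smoothing-parameter selection (GCV or
profile ML) interprets that correlation as signal and undersmooths.
This is precisely why practitioners adjust the smoothing of this method
by eye.  The package keeps the automatic default but exposes
`smoother_params` (basis size, fixed smoothing parameter) as the
explicit, reproducible counterpart of that manual adjustment;
truth-recovery tests use a stiffer basis for this reason.

### Radial smoothing (RS)

Stage one fits the conditional mean of value given age by penalized
radial-basis regression: cubic radial basis `|t - kappa|^3` at 20
equally spaced knots plus an unpenalized linear part, ridge penalty on
the radial coefficients, penalty chosen by GCV.  Ages are rescaled to
[0, 1] internally for conditioning.  The same machinery smooths the
2nd-4th powers of the residuals — each stage selecting its own GCV
penalty, since the higher-moment responses are far noisier than the
mean — giving curves for the conditional SD, skewness g1 and excess
kurtosis g2.  Percentiles come from the third-order Cornish-Fisher
expansion

    w_p = z_p + (z_p^2 - 1) g1/6 + (z_p^3 - 3 z_p) g2/24
          - (2 z_p^3 - 5 z_p) g1^2/36,

applied as `mu(t) + sigma(t) w_p(t)`; a switch drops the g1^2 term for
the second-order variant.  Numerical guards: fitted variance is floored
at a small positive value (flagged), and the shape curves are clipped to
|g1| <= 1, g1^2 - 2 <= g2 <= 4 — outside that region the expansion is
unreliable (and g2 < g1^2 - 2 is infeasible for any distribution);
unclipped tail estimates otherwise produce crossing percentile curves at
the data-sparse edges.  The expansion assumes mild non-normality, so
`transform_first=True` Box-Cox-transforms the values (single profile-ML
power per stratum) before moment fitting and back-transforms the
percentile curves; without it the fit warns when residual skewness
around the age trend exceeds 0.5.  An `edge_diagnostic` reports the
difference between each curve at the domain boundary and the empirical
quantile of the nearest 120 subjects, since edge drift is this method's
characteristic weakness.

### LMS and GAMLSS

Both model the response at age t with a Box-Cox family: z-score
`z = ((y/mu)^nu - 1)/(nu sigma)` (log branch at nu = 0) referred to a
standard distribution.  LMS is the Box-Cox Cole-Green model (BCCG,
normal reference; age-varying skewness L = nu, median M = mu,
coefficient of variation S = sigma).  GAMLSS extends it with a kurtosis
parameter tau: Box-Cox t (BCT, t_tau reference) and Box-Cox power
exponential (BCPE; tau = 2 recovers BCCG exactly, tau < 2 heavy tails).
Densities carry the truncation normalization `F_z(1/(sigma |nu|))`
required by the positive domain; it is numerically irrelevant for
S < 0.3 but included.  Quantiles invert the z-score at the reference
quantile without the truncation correction, the common convention at
clinical S values.

Fitting maximizes a penalized likelihood by backfitting.  Each
parameter's predictor — log mu, log sigma, nu, log tau — is a penalized
B-spline in age (20 cubic basis functions, second-order difference
penalty) at fixed target effective degrees of freedom: mu 6, sigma 4,
nu 2, tau constant (intercept) by default, freed only when worm plots
show kurtosis structure.  Per cycle and parameter, the score of the
log-likelihood in the predictor is computed by central differences and
converted to a working response with a *scalar* curvature weight (the
mean positive observed curvature, a Fisher-information proxy).
Per-point observed curvature is deliberately not used: for the scale and
shape predictors it vanishes near z = 0 while the score does not, which
inflates working residuals there and can turn the smoothed proposal
into an ascent direction for the deviance.  With a constant weight the
proposal is a descent direction, and a step-halving line search makes
the global deviance non-increasing by construction (asserted in tests).
Convergence: deviance change < 1e-4 over a full cycle, max 100 cycles;
non-convergence returns the model flagged `converged=False` with a
warning, never a silent success.  Initialization: log mu from a
penalized spline of log y, sigma from the residual log-SD (constant),
nu = 1, tau = 10 (BCT) or 2 (BCPE).

Diagnostics: normalized quantile residuals, per-age-bin detrended QQ
("worm") plots with pointwise 95% bands `1.96 sqrt(p(1-p)/n)/phi(z)`;
nine equal-count age bins by default, bins under 20 points dropped.  A
bin is flagged when more than 10% of its points leave the bands.  Model
choice across families/smoothing specifications ranks candidates by
AIC = deviance + 2 edf, ties broken by smaller edf then listed order.
The AIC per-df penalty is exposed (`penalty_per_df`) for users who want
a different charge; rankings, not absolute values, are what matter.

### Discrete baseline

The conventional comparator: empirical 2.5th/97.5th percentiles per
fixed-width age bin (default 1 year), yielding ladder-shaped step
curves.  Empty bins merge leftward; bins under 120 records are flagged.

## Validation protocol

Per sex stratum: an 8:2 train/test split, accepted only if a two-sided
Wilcoxon rank-sum test on age finds train and test comparable
(P >= 0.05; otherwise redraw, new sub-seed).  Each method is fitted on
the training part and scored by the out-of-range (OOR) percentage of
test records below the lower or above the upper curve, overall and per
one-year age bin.  A correctly calibrated 95% interval gives ~5% total
(2.5% per tail); the CLSI acceptability bound is total OOR < 10%.  The
split-fit-score cycle is repeated (100 times in the full design; 10 in
the fast mode used by the acceptance checks) and OOR summaries are
averaged per method.  OOR is computed on the held-out test set.  A
method failing on more than half the repetitions is reported as failed
without aborting the run.

## Synthetic cohorts

Real cohort data of this kind are not publicly deposited, so the
package ships two generators that define the study conditions for all
tests.

*Calibrated cohorts.*  Published per-age-bin summary tables (n, mean,
SD for each one-year bin, ages 1-19, by sex) for alkaline phosphatase
(ALP, U/L) and serum creatinine (Cr, umol/L) are built in.  Ages are
uniform within bins (only bin totals are published); values are
Gaussian truncated at a floor of 1 unit — the simplest model consistent
with the printed moments — with a moment-matched lognormal option to
exercise the Box-Cox cleaning branch on skewed data.  These cohorts
reproduce the analytes' signature trends: ALP's rise to a pubertal peak
followed by a steep fall, Cr's monotone increase.  What they do not
contain: within-bin age-value correlation, site or instrument effects,
true within-bin skewness (in the Gaussian default), or the real tails
of biological data.  Passing OOR bounds on them shows the pipeline is
correctly calibrated under its own assumptions, not that any specific
published interval is reproduced.

*Ground-truth cohorts.*  Draws from a Box-Cox normal with known smooth
L(t), M(t), S(t) curves (z restricted to the family's positive domain),
with closed-form percentile curves for parameter-recovery tests;
recovery targets are 3% on M(t) and 5% on the outer percentiles over
the central 80% of the age span at n = 5000.

## Problem sizes and numerical choices

Repeated-validation checks use 10 repetitions on full-size calibrated
cohorts (about 4400-4700 training records per stratum), bootstrap
B = 500, and all four methods; recovery tests use n = 5000; oracle
calibration uses a 100,000-record test set.  These sizes give binomial/
Monte-Carlo noise comfortably below the asserted tolerances.  Numerical
details fixed package-wide: linear-interpolation quantiles; B-spline
penalty null spaces preserved exactly (eigenvalue clipping) so infinite
penalties reproduce polynomial limits; Cholesky jitter escalated from
1e-13 only as needed; smoothing-parameter searches on log10 lambda in
[-8, 10]; Box-Cox lambda grid [-3, 3] step 0.01.  Ties in
fractional-polynomial power search go to the first tuple in the fixed
enumeration order.

## Known limitations

- The non-parametric and RS methods inherit edge effects from sparse
  boundary data; the RS edge diagnostic quantifies but does not remove
  them.  LMS/GAMLSS degrade more gracefully there.
- Automatic smoothing selection undersmooths the overlapping-frame
  limit series (see above); the manual override is the remedy.
- The Cornish-Fisher expansion is a tail approximation, not a density:
  for strongly skewed strata it requires the Box-Cox pre-transform, and
  its shape inputs are clipped to its validity region.
- Per-parameter effective degrees of freedom are fixed targets, not
  jointly optimized; model choice across edf settings goes through AIC.
- Only age and sex are modelled; height, weight, fasting status and
  site effects are out of scope.
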