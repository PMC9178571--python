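# Methods

This note documents the scientific and numerical choices behind
`milkpay`: how the payment schedule is encoded, what the synthetic panel
generator does and does not emulate, how the mixed model is estimated,
and how the monthly contrasts are adjusted for multiplicity.

## Payment schedule encoding

The Thai milk-quality payment schedule is shipped as data
(`data/schedule_th2016.yaml`): per component an ordered list of bands,
each with inclusive bounds, a class label (A++ … E), and a signed
adjustment in baht per 1000 kg.  The printed USD figures are display
metadata and never enter computation.  Two conventions make the printed
bands a partition:

* **Comparison resolution.**  Fat and SNF are rounded
  half-away-from-zero to 2 decimals before lookup; SCC (stored in
  thousands of cells/mL) is compared as integer cells/mL.  At these
  resolutions there are no representable values between adjacent bands.
* **Shared boundaries go to the more severe class.**  Where a printed
  boundary appears in two bands (fat 3.2 in both C "3.39–3.2" and D
  "≤3.2"; SNF 8.25 in both C "8.34–8.25" and D "≤8.25"), the value is
  assigned to the lower class.  This follows the program's own prose,
  which prices SNF ≤ 8.25 at the D deduction.  The rule is applied
  uniformly, so the packaged bands are stored already-resolved
  (e.g. fat C as 3.21–3.39) and a dense-grid partition test enforces
  exhaustiveness and uniqueness.
* The SCC top-bonus bound, printed with a garbled thousands separator,
  is read as 200,000 cells/mL, consistent with the next band starting
  at 200,001.

The final price is the sum of the three component adjustments; benefit
groups are its sign.  Compliance with the national raw-milk standards
(SCC ≤ 500,000 cells/mL, fat ≥ 3.35 %, SNF ≥ 8.25 %) is a separate,
boundary-inclusive check — a record can violate the standard yet still
gain under the payment program, and vice versa.

## Descriptive layer

Category percentages, benefit proportions, and pattern tables are
straightforward tabulations; all are property-tested against plain-loop
recounts on random panels.  Two deterministic conventions: calendar
(year, month) pairs map to a chronological index t = 1..T, and
equal-count patterns are ordered by category rank (bonus < base <
penalty) component-wise, since frequency alone does not give a unique
order.

## Synthetic panel generator

The generator emulates the sampling structure of a two-region monthly
BTM testing program: 1,580 northern and 1,562 central farms, 24 monthly
samples each (Jan 2018 – Dec 2019), thinned uniformly at random to
37,077 records to mimic missed samplings.  Per component and region,
values follow

    value_it = mu_r + farm_i + A * sin(2*pi*(month-1)/12 + phi) + eps_it

with `farm_i ~ N(0, sd_farm)` persistent per farm and `eps_it` i.i.d.
Gaussian.  Fat and SNF are Gaussian with clipping to physiologic bounds
(fat 1.5–8.0 %, SNF 6.0–11.0 %) and 2-decimal rounding; SCC follows the
same structure on the log scale (somatic cell counts are right-skewed;
the log-normal is the standard working distribution), reported as
integer thousands of cells/mL.  One master seed drives independent
substreams per component, so resizing one component never perturbs the
draws of another.

### Parameter defaults and calibration

SDs and seasonal terms are fixed at values realistic for bulk-tank milk
testing: fat farm/residual SD 0.25/0.28 %, SNF 0.14/0.17 %, log-SCC
0.50/0.45, seasonal amplitudes 0.10 % (fat), 0.05 % (SNF), 0.12
(log-SCC) with fat/SNF peaking in the cool season and SCC in the hot
season.  The regional means were then set by `calibrate_defaults`: a
Nelder–Mead search over the means most directly tied to each target,
minimizing the squared deviation of simulated scored fractions from the
published marginal percentages — central SNF penalty 44 %, central SCC
penalty 40 %, central benefit-gain 57.1 %, northern benefit-gain
88.7 %.  The objective uses common random numbers averaged over six
replicate seeds of 20,000-record panels, so it approximates the
*expected* fraction rather than one realization; the search is
deterministic given its seed.  The resulting means (north fat 3.8667 %,
central fat 3.8685 %, central SNF 8.3803 %, central log-SCC 6.0403; the
remaining means kept at their realistic starting values) are frozen in
`data/generator_defaults.yaml`.  At n = 20,000 records the simulated
fractions vary by roughly ±1 percentage point across seeds — binomial
noise inflated by farm-level clustering — and sit within ±2 points of
the calibration targets.

The generator reproduces the study's *marginal* percentages and its
clustering structure, not the real data's joint distribution: it assumes
independence between components within a record, stationary seasonality,
missingness completely at random, and no farm-management covariates
(feeding, mastitis control, herd genetics).  Passing tests therefore
validate the pipeline's machinery on data with the assumed structure,
not the published study's real-data figures, which are available only on
request.

## Mixed-effects logistic model

The benefit indicator is modelled with fixed effects for region (north
reference), month as a 24-level categorical factor, and their
interaction, plus a farm random intercept `u_i ~ N(0, sigma_u^2)`.
Month enters as a factor — not a trend — because the scientific question
is a per-month regional contrast.  Region is both a fixed effect and the
nesting level of farms; with a single random intercept per farm the
nesting adds nothing beyond farm identity, so the model is exactly a
two-level random-intercept logistic regression.

### Estimation

The marginal likelihood integrates each farm's random intercept out of
its Bernoulli product.  Each one-dimensional integral is evaluated by
**adaptive Gauss–Hermite quadrature**: a damped, vectorized Newton
iteration locates every farm's posterior mode and curvature
simultaneously, and the Gauss–Hermite rule (15 nodes by default) is
recentred and rescaled there.  On test panels, moving from 15 to 41
nodes changes the log-likelihood by under 1e-4, and single-farm cases
agree with dense trapezoid integration to a relative error below 1e-6.

Optimization is L-BFGS-B on (beta, log sigma_u), started from an
in-house IRLS logistic fit and log sigma_u = log 0.5, with the analytic
gradient — the quadrature-weighted posterior expectation of the
complete-data score, which matches a numerical gradient to ~1e-7.
`log sigma_u` is bounded below at log 1e-4; data with no farm-level
heterogeneity drive the estimate to that boundary, where the fit
reduces to ordinary logistic regression (checked to 1e-3 against an
independent GLM).  A line-search abort at a point whose gradient
infinity-norm is below 1e-3 is still reported as converged; genuine
non-convergence is flagged on the returned fit, never raised.  Runaway
coefficients (|beta| > 10) trigger a separation warning, since
separation inflates both estimates and standard errors.

Standard errors come from the observed information computed by central
finite differences of the analytic gradient (step 1e-5·max(1, |theta|)),
symmetrized and inverted; the fixed-effect block is exposed as the
coefficient covariance.  Unbalanced panels are supported; interaction
columns of empty region×month cells are dropped with a warning so the
design stays full rank.

### Monthly contrasts and multiplicity

The contrast of interest is central − north on the log-odds scale in
each of the T months: a Wald statistic per month from the fitted
coefficients and covariance.  The family of T tests is adjusted with a
**single-step max-|z| adjustment**: the adjusted p-value of month t is
P(max_j |Z_j| ≥ |z_t|) under Z ~ N(0, R), with R the estimated contrast
correlation matrix — the same construction estimated-marginal-means
software uses for Tukey-style families, specialized to one contrast per
month.  The quantile is computed by seeded Monte Carlo (100,000 draws by
default), so identical data and seed give identical tables; Šidák is
available as a cheap conservative alternative and as the automatic
fallback when the contrast covariance cannot be simulated from.
Adjusted p-values are clamped to be at least the raw ones.  Simulation
with identical regions (200 replicates, 200 farms, 12 months) keeps the
family-wise error within two binomial standard errors of the nominal
0.05, and a single-month log-odds gap of 2.0 at 400 farms is detected in
well over 80 % of replicates.

### Problem sizes

The full default panel (3,142 farms, 37,077 records, 49 fixed
parameters) fits in a few seconds on one core, including standard
errors.  The test suite's simulation studies use 300 farms × 24 months
(50 replicates) for parameter recovery, 200 farms × 12 months (200
replicates) for family-wise error, and 400 farms × 12 months (30
replicates) for power — sizes chosen so the whole suite runs in a few
minutes while leaving the Monte-Carlo standard errors small relative to
the tolerances tested.

## Known limitations

* The schedule's gap-and-overlap conventions are this package's
  resolution of ambiguous printed bounds; an official rulebook could
  differ at exactly the shared boundaries.
* The generator's independence and stationarity assumptions understate
  the dependence structure of real BTM data (fat–SNF correlation,
  SCC autocorrelation within farm, seasonal missingness).
* Population-level predicted proportions use u = 0 (median farm), not
  the population-averaged probability; with sigma_u ≈ 1.5 the two differ
  noticeably away from 0.5.
* The max-|z| adjustment relies on the asymptotic normality of the Wald
  statistics; with few farms or near-separated months it can be
  anti-conservative.
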