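# Methods

## The procedure

The package estimates delta check limits (DCLs) from paired
current/previous laboratory results and validates them on held-out data.

**Pairing and exclusions.** Input rows are read as raw strings so that
censored results (`<0.04`, `>2000`) survive to the exclusion stage.
Record-level rules run in a fixed first-match order: unparseable values or
timestamps; inequality signs; pair interval under 24 h (the results would
not reflect independent physiological states) or over 3 years (taken as
1095 days; the day-count convention is configurable); age under 19; and
non-positive values, which would make a percent change undefined.  Finally
any (analyte × group) stratum with fewer than 1000 surviving pairs is
dropped whole — small strata give unstable tail percentiles.  The stratum
rule is defined on survivors, so it necessarily runs after the
record-level rules.  Counts always reconcile: retained + excluded =
input.  Multiple pairs from one patient are treated as independent
observations throughout.

**Metrics and limits.** absDD = |curr − prev| (analyte units) and
absDPC = |curr − prev| / prev × 100 (%).  Within each stratum the data are
split at random 6:4 into development and validation sets (per-stratum
permutation; development size rounds half up; the seed is a required,
logged parameter).  The DCL is the development-set 95th percentile,
computed by linear interpolation between order statistics (Hyndman–Fan
type 7, numpy's default).  At stratum sizes ≥ 1000 any of the standard
percentile conventions moves the limit by less than one
inter-order-statistic gap; a fixed convention is still needed for
reproducibility, and the estimator is configurable.  The combined-group
limit is the *unweighted* mean of the IE and O limits, so the larger group
does not dominate.  Sex-stratified 2.5th/97.5th percentiles of the signed
deltas use the same percentile rule.

**Validation.** A validation result counts as "outside" when it is
strictly greater than the limit (a value exactly at the limit was observed
within the development distribution; the comparison is configurable).
Own-group application checks the 5% design level; cross-group application
checks interchangeability of the IE and O limits; combined-limit
application is compared between groups with Pearson's chi-squared on the
2×2 outside/inside table, without continuity correction by default (Yates
available — software environments differ in their default and the choice
is logged in the report).  Proportions are reported to one decimal in
percent.

**Quantile regression.** Whether the groups differ at the 95th percentile
is tested by minimizing the pinball loss
Σ ρ_τ(y − b0 − b1·1[group=IE]) at τ = 0.95.  With a single binary
covariate the problem separates exactly: b0 is the pinball-optimal
τ-quantile of group O (the ⌈nτ⌉-th order statistic; when nτ is an integer
the optimum is an interval and its lower endpoint is returned) and
b0 + b1 that of group IE, so no iterative solver is involved; the fit is
verified in tests against brute-force breakpoint search and an
independent linear-programming implementation.  Inference on b1 uses a
seeded within-group case-resampling bootstrap (default 1000 replicates)
with a two-sided percentile p-value; the regression software a laboratory
might use instead does not document its inference method, so an explicit,
reproducible bootstrap was preferred.

**Reference change values.** Under a lognormal model with within-subject
CV_I and analytical CV_A (percent), the per-result log variance is
σ² = ln(1 + CV_I²/10⁴) + ln(1 + CV_A²/10⁴) and the change thresholds at
two-sided z are increase = 100(e^{z√2σ} − 1), decrease = 100(e^{−z√2σ} − 1);
the √2 accounts for two independent measurements.  Increase and decrease
are exact reciprocals, (1 + inc/100)(1 + dec/100) = 1, and the increase
always dominates in magnitude.  The sum-of-log-variances form matches the
EFLM biological-variation calculator's published formulation; a pooled
variant ln(1 + (CV_I² + CV_A²)/10⁴) is selectable and agrees closely for
CVs under ~50%.  Confidence limits are propagated by plugging
lower-with-lower and upper-with-upper CV limits into the same closed
form.  Published RCV tables computed from unrounded database CVs can
differ from values recomputed from CVs printed to 2–3 significant figures
by several tenths of a point on large increases (the sensitivity of a
~230% increase to the last printed CV digit is ≈ ±0.8 points); decreases,
being bounded by −100%, are far less sensitive.

## The synthetic generator

Each synthetic patient carries a lognormal homeostatic set-point; the
current and previous results share it and differ only by independent
multiplicative lognormal noise with the analyte's CV_I and CV_A.  This
yields strictly positive, right-skewed marginals and within-patient serial
correlation — the structure the RCV model assumes.  Specifics:

* the set-point log-SD is solved in closed form from the configured group
  median m and IQR width w: s = asinh(w / 2m) / z₀.₇₅, so the configured
  median and IQR are matched exactly in distribution;
* a CV of c percent maps to log-variance ln(1 + c²/10⁴), making the noise
  factor's CV exactly c and its median 1;
* values are clipped (not rejected) at the analytical measurement
  interval, mirroring instrument reporting limits and keeping n exact;
* sampling intervals are discretized lognormals with group-specific
  median/IQR, truncated to [1, 1095] days; sexes, ages (uniform 19–90) and
  institutions are drawn per pair; an optional multiplicative sex ratio
  shifts male set-points (used for testosterone);
* one pair per synthetic patient; a fixed seed gives byte-identical
  cohorts.

Default analyte presets (`deltacheck.reference.DEFAULT_ANALYTES`) carry
group medians/IQRs, measurement intervals and CVs typical of hormone
testing on a modern immunoassay platform.  ACTH has no published CV_I;
its preset uses a nominal 25% for simulation only and is excluded from RCV
tables.  For insulin, testosterone and thyroglobulin, inpatient volumes
are typically too low for stratum-level limits, so the outpatient
statistics stand in for both groups in the presets.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: circadian sampling-time effects (hormones like
cortisol and ACTH vary strongly by draw time), disease progression or
treatment response between visits (real deltas include clinical change, so
real DCLs sit *above* the pure-noise percentiles; under pure noise the
absDPC limit falls strictly between the RCV decrease magnitude and the RCV
increase), institution-specific assay bias, and correlated repeat testing
within a patient.  Real-data DCL magnitudes therefore cannot be reproduced
synthetically; what the synthetic cohorts validate is the machinery: the
5% coverage property, the cross-group asymmetry under unequal dispersion,
and all bookkeeping.

## Numerical and design choices

* Percentile convention: type 7; split rounding: half up; outside
  comparison: strict; chi-squared: no continuity correction — each
  documented above and configurable where ambiguity exists in practice.
* The bootstrap p-value is `2·min(P(b1* ≤ 0), P(b1* ≥ 0))`, capped at 1;
  with identical groups b1 = 0 exactly and p ≈ 1.
* Degenerate inputs: percentiles require ≥ 2 finite values; empty
  validation sets and zero chi-squared margins are flagged rather than
  silently computed; a pipeline run that yields no estimable stratum
  aborts and removes its partial output bundle.
* Problem sizes in the shipped tests and the acceptance script (10,000
  pairs per group for coverage checks, 10⁶ draws for Monte-Carlo oracles,
  50 × 200 bootstrap repetitions for the equal-groups calibration) were
  chosen so that binomial/Monte-Carlo error is well inside the asserted
  bands while the whole suite runs in minutes.

## Known limitations

* Cohorts are stationary by construction; the pipeline does not model
  drift, diurnal structure or concentration-dependent imprecision.
* The stratum-size floor (1000) and the 6:4 ratio are conventions, not
  optimized quantities; both are parameters.
* RCV confidence intervals use simple CV-limit plugging, not error
  propagation; they inherit the database CIs' asymmetry.
* No multiple-testing adjustment is applied across analytes or metrics;
  reported p-values are per-comparison.
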