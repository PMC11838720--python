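# deltacheck

Delta check limits for clinical laboratory tests.

A *delta check* compares a patient's current result with their previous one
and flags changes too large to be plausible, catching sample mix-ups,
mislabeling and analytical errors in the post-analytical phase.  For that
you need a threshold — a **delta check limit (DCL)** — and for hormones
(ACTH, cortisol, PTH, prolactin, insulin, testosterone, thyroglobulin)
published limits are scarce, so laboratories often use arbitrary cutoffs.

`deltacheck` implements a data-driven procedure for establishing and
validating such limits, aimed at laboratory informaticians and clinical
chemists:

* **Delta metrics.** For each current/previous pair, the absolute delta
  difference `absDD = |curr − prev|` (analyte units) and the absolute delta
  percent change `absDPC = absDD / prev × 100` (%), plus their signed
  versions for two-sided tables.
* **Limit estimation.** Pairs are stratified into inpatient/emergency (IE)
  and outpatient (O) groups, split 6:4 into development and validation sets
  within each stratum, and the DCL is the development-set 95th percentile
  of the metric (Hyndman–Fan type 7).  By construction ~5% of comparable
  results fall outside the limit.
* **Validation.** Own-group coverage (should be ≈5%), cross-group
  application (are the IE and O limits interchangeable?), combined limits
  (the unweighted mean of the group limits) with a Pearson chi-squared
  comparison of the groups, and quantile regression (pinball loss with a
  binary group covariate, bootstrap inference) testing whether the groups
  differ at the 95th percentile itself.
* **Reference change values.** Asymmetric RCVs from within-subject
  biological variation CV_I and analytical imprecision CV_A under a
  lognormal model: `increase = 100(e^{z√2σ} − 1)`,
  `decrease = 100(e^{−z√2σ} − 1)` with
  `σ² = ln(1 + CV_I²/10⁴) + ln(1 + CV_A²/10⁴)`, at z = 1.96 (95%) and
  2.57 (99%).  Increase and decrease thresholds are exact reciprocals.
* **Synthetic cohorts.** Real paired hospital extracts are rarely
  shareable, so a generator produces cohorts with the assumed structure:
  lognormal patient set-points matched to group medians/IQRs,
  multiplicative CV_I/CV_A noise shared through the set-point (serial
  correlation), sex/age/institution strata, and heavy-tailed sampling
  intervals — enough to exercise and test every stage without data access.

## Worked example

Estimate and validate limits on a synthetic cortisol-like cohort
(CV_I = 16.1%, CV_A = 2.12%, 10,000 pairs per group):

```python
import deltacheck as dc
from deltacheck.reference import DEFAULT_ANALYTES

cfg = dc.CohortConfig(analytes=(DEFAULT_ANALYTES["cortisol"],),
                      n_pairs_ie=10_000, n_pairs_o=10_000, seed=42)
rec = dc.compute_deltas(dc.generate_cohort(cfg))
split = dc.split_dev_val(rec, ratio=0.6, seed=42)
dev, val = rec.loc[split.dev_index()], rec.loc[split.val_index()]
for d in dc.estimate_dcls(dev):
    r = dc.proportion_outside(val[val["group"] == d.group], d,
                              applied_to=d.group)
    print(f"{d.group:2s} {d.metric:6s} DCL={d.limit:8.2f} "
          f"-> {r.proportion_outside:.1f}% outside (n={r.n_val})")
```

prints

```
IE absDD  DCL=  245.02 -> 5.1% outside (n=4000)
IE absDPC DCL=   46.24 -> 5.4% outside (n=4000)
O  absDD  DCL=  169.28 -> 5.6% outside (n=4000)
O  absDPC DCL=   46.14 -> 4.9% outside (n=4000)
```

i.e. an IE cortisol result moving more than 245 nmol/L (or 46% in percent
terms) from its predecessor would be flagged, and on held-out data each
limit flags ≈5% — the design level.  The absDD limits differ between the
clinical groups (sicker inpatients move more in absolute terms) while the
absDPC limits nearly coincide, the pattern that motivates combined
percent-change limits.

The same flow is available from a shell — `deltacheck generate`, `filter`,
`estimate`, `rcv`, and `run` for the whole bundle:

```console
$ deltacheck rcv --cvi 16.1 --cva 2.12 --cvi-ci 15.5,26.6 --cva-ci 2.02,2.22 --z 1.96
{
  "decrease": -36.06435588609153,
  "increase": 56.40727701411573,
  ...
}
```

— a cortisol decrease beyond −36.1% or increase beyond +56.4% exceeds what
combined biological and analytical variation explains at 95% probability.

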