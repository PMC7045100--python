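# ehrshift

Temporal variability analysis for routinely collected electronic health
records.

Routine clinical databases — primary-care records coded in Read codes,
hospital activity coded in ICD-10 — are not recorded under a fixed protocol.
Coding guidance changes, pay-for-performance schemes arrive, practices join
and leave, software is replaced. Each of these events can bend the recorded
distribution of diagnoses and demographics over time without any change in
the underlying population, and a study that pools years of such data
inherits those artefacts. `ehrshift` gives data managers and
epidemiologists a data-driven way to find them *before* an analysis: it
measures how much the monthly distribution of a dataset changes, draws the
data's trajectory through time, and flags gradual trends, abrupt breaks and
period clusters, attributing each to the variables that drive it.

## Method

1. **Monthly slicing.** The data are divided into monthly cross-sections.
   For longitudinal primary-care records a patient contributes to month
   *m* if, on the first day of *m*, they are 20–110 years old and have been
   registered for at least a year; a condition is present if any code from
   its codelist appears strictly before that day (ever-recorded phenotype).
   For preaggregated hospital counts the denominator is the month's total
   of included 3-character codes.

2. **Data temporal map (DTM).** Each month's joint histogram over the
   categorical variables (age band, gender, deprivation quintile,
   conditions or codes), divided by the monthly total, forms one row
   `P_m` of the map, over a support aligned across months.

3. **Jensen-Shannon dissimilarity.** Months are compared with

   `JS(P, Q) = ½ KL(P ‖ M) + ½ KL(Q ‖ M)`, `M = (P + Q)/2`.

   With log base 2, `JS ∈ [0, 1]`: 0 for identical distributions, 1 for
   distributions with no overlap, independent of sample size. Its square
   root `√JS` is a metric. Both scales are exposed: the divergence for
   month-to-month *rates* of change, the distance for embedding.

4. **Information-geometric temporal (IGT) plot.** Classical (Torgerson)
   multidimensional scaling of the month-by-month distance matrix
   (`B = −½ J D² J`, eigendecomposition, top 3 dimensions) places each
   month in a Euclidean space; joining the months in calendar order traces
   the data's recording trajectory.

5. **Detection.** Replacing visual inspection with reproducible rules:
   abrupt steps are consecutive-month values above
   `median + 5 · 1.4826 · MAD`; gradual trends are |Spearman ρ| ≥ 0.8
   between calendar order and the first embedding dimension; period
   clusters (e.g. NHS financial years, April–March) are candidate
   groupings with silhouette ≥ 0.5. Each flag is attributed by re-scoring
   the step on every single-variable marginal of the DTM.

A synthetic EHR generator (`ehrshift.synthetic`, with ready-made scenarios
in `ehrshift.scenarios`) produces both dataset shapes with planted drifts,
steps, demographic mix shifts and practice dropout, plus a ground-truth
manifest, so the whole pipeline is testable end to end against known truth.

## Worked example

A hospital-style scenario with 50 000 cardiovascular codes per month over
180 months (January 2001 – December 2015) and one planted coding step: in
April 2012 the acute-myocardial-infarction code I21 jumps from 8.0% to
10.9% of included codes.

```python
from ehrshift.scenarios import hospital_step_scenario, hes_codelist
from ehrshift import (generate_hospital_counts, build_hospital_slices,
                      estimate_dtm, analyze, trend_summary)

cfg = hospital_step_scenario(seed=1)          # 180 months, 50 000 codes/month
counts, manifest = generate_hospital_counts(cfg)
slices = build_hospital_slices(counts, hes_codelist(), cfg.months)
dtm = estimate_dtm(slices)                    # 180 x 800 joint temporal map

report, artifacts = analyze(dtm)
for flag in report.of_kind("abrupt"):
    top_var, score = flag.attributed_variables[0]
    print(f"abrupt change at {flag.location}: robust z = {flag.score:.1f}, "
          f"driven by {top_var!r} (marginal JSD {score:.2e})")

i21 = trend_summary(dtm, "code", "I21", period=("2012-03", "2012-04"))
print(f"I21 share {100*i21.start_value:.1f}% -> {100*i21.end_value:.1f}% "
      f"({i21.relative_change_pct:+.0f}%)")
```

prints

```
abrupt change at 2012-04: robust z = 10.2, driven by 'code' (marginal JSD 2.87e-03)
I21 share 7.9% -> 10.7% (+36%)
```

— the detector finds exactly one abrupt step, at the planted month, far
above the control limit (robust z = 10.2 against a threshold of 5), and
the per-variable attribution points at the code distribution rather than
demographics; the realized share step reproduces the configured +36%
relative change up to multinomial noise.

The same flow is available from a shell via the `ehrshift` CLI
(`simulate`, `slice`, `dtm`, `dissimilarity`, `igt`, `detect`, `report`)
driven by a single YAML config; see `ehrshift.cli --help`.

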