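# Methods

This note records the modelling choices behind `ehrshift`: what each stage
computes, the defaults and why, what the synthetic generator does and does
not emulate, and the numerical conventions.

## Monthly slicing

A month's cross-section is ascertained on the first day of the month
(00:00 of day 1). A patient is eligible for month *m* when

- age on the first of *m* is within the configured range (default 20–110),
- `registration_start ≤ first-of-m − 365 days` ("registered for at least a
  year" is day arithmetic, not calendar-year arithmetic; configurable via
  `min_registration_days`), and
- `registration_end` is absent or ≥ the first of *m* — so a patient who
  deregisters mid-month still contributes to that month.

Condition flags are ever-recorded phenotypes: a flag is 1 in month *m* iff
a codelist code is dated **strictly before** the first of *m*. Records with
missing age, gender or deprivation are dropped before slicing. ICD-10
codes are truncated to 3 characters before codelist matching; Read-style
codes match exactly.

**Age convention.** With only a year of birth available, age is computed
as `year(m) − yob` from July onward and one less before July: the entire
birth cohort ages one year each 1 July. This deliberately reproduces the
July jump that year-of-birth-only databases show, so users see the same
artefact they will meet in real data (and can exclude the age variable
when it obscures other structure). An exact date-of-birth mode is the
obvious extension; the July convention is the default because the target
data shape carries no birth date.

**Empty months** are kept as explicit zero-denominator slices by the
slicer and excluded, with a warning, when the temporal map is estimated;
the dissimilarity series treats the resulting calendar gap as a break
rather than comparing across it.

## Data temporal map

Row *m* is the joint histogram of the declared categorical variables
divided by the month's denominator. The support is the union of cells
observed in any month, ordered lexicographically by variable order then
declared category order, so serialization and plotting are deterministic.
No smoothing is applied: unobserved cells are exactly zero and counts are
exactly recoverable as `probabilities × denominator`. (A kernel or Laplace
smoothing hook would only matter for continuous variables, which this
pipeline does not model; all variables here are categorical.) The dense
months × support matrix is small by construction — the largest realistic
joint (8 age bands × 2 genders × 5 quintiles × ~10 codes) is well under
10⁴ columns.

Marginalization sums counts over the omitted variables **before**
renormalising, so it commutes exactly with estimation — a property the
test-suite asserts.

## Jensen-Shannon dissimilarity

`JS(P, Q) = ½KL(P‖M) + ½KL(Q‖M)`, `M = (P+Q)/2`, with `0·log(0/x) := 0`;
`M` is strictly positive wherever either argument is, so no other
singularity arises. Defaults and rationale:

- **log base 2** so that both the divergence and its square root are
  bounded by 1 — 0 means identical monthly distributions, 1 means
  non-overlapping support.
- **distance scale** (`√JS`, a metric) is the default for the pairwise
  matrix because the embedding step requires (approximate) Euclidean
  embeddability.
- **divergence scale** is used for month-to-month *rate* reporting
  (JSD/month) and for the abrupt-change series and period clustering:
  squaring suppresses the sampling-noise floor relative to real shifts,
  exactly as silhouette analysis on squared Euclidean distances sharpens
  cluster contrast. For the reference binary example (prevalence 1.0% vs
  2.2%) the divergence is 1.171×10⁻³ nats = 1.690×10⁻³ bits, i.e. the
  ~1.5×10⁻³ order of magnitude quoted for typical month-on-month change
  in mature primary-care data; the distance scale would put the same
  comparison at ≈ 4×10⁻². Both scales are always exposed and labelled —
  user-facing output never silently picks one.

## IGT embedding

Classical (Torgerson) multidimensional scaling: square the
dissimilarities, double-centre (`B = −½ J D² J`), eigendecompose, scale
the top eigenvectors by √eigenvalue. Three dimensions by default, matching
how the trajectory plots are read. Numerical conventions:

- Negative eigenvalues (non-Euclidean input, e.g. a divergence-scale
  matrix) are clamped to zero; the clamped fraction of the absolute
  eigenvalue mass is recorded on the embedding, and above 10% a warning
  suggests the divergence scale was passed where the distance scale was
  intended.
- Axes are defined only up to rotation/reflection. For stable
  serialization each dimension is oriented so its largest-magnitude
  coordinate is positive; ties in eigenvalues are resolved by stable
  ordering (eigenvalue, then index). All tests compare inter-point
  distances or Procrustes-aligned configurations, never raw axes.
- Month labels use one glyph per month (`J F M A m j x a S O N D`,
  July = `x`) prefixed by the two-digit year.

## Detection

The detectors replace visual inspection of the trajectory plots with
explicit statistical-process-control-style rules. All thresholds are this
package's own defaults, chosen a priori and justified by the null-scenario
calibration suite (no planted effects ⇒ flags in ≤ 5% of seeds):

- **Abrupt** (`detect_abrupt`): a consecutive-month value above
  `median + k·1.4826·MAD`, k = 5, both statistics from the full series.
  The robust pair (median, MAD) keeps a single genuine step from inflating
  its own control limit. If MAD = 0 (an exactly constant series) the rule
  degenerates to "strictly above the median", documented and tested. The
  pipeline applies this rule to the **joint** DTM's divergence series:
  with a joint support of several hundred cells the sampling noise of the
  series is a high-degree-of-freedom quadratic form — tightly concentrated
  — so the 5-MAD limit sits safely above it while a single-code step of
  the size worth flagging (tens of percent relative on a share of a few
  percent) clears it by an order of magnitude. Low-dimensional marginal
  series are *not* scanned by default: their skewed, few-degree-of-freedom
  noise would push the same rule's false-flag rate far above the
  calibration target. Marginals enter through attribution instead.
- **Trend** (`detect_trend`): |Spearman ρ| ≥ 0.8 between calendar index
  and the first embedding dimension over a period of ≥ 12 months. A
  drift-with-reversal is localised by splitting the period at the
  suspected turning point; the two sub-period flags carry opposite signs.
- **Period clusters** (`detect_period_clusters`): silhouette ≥ 0.5 on the
  (divergence-scale) matrix for a candidate partition of the months.
  Default candidates: calendar year, NHS financial year (April–March, the
  boundary at which English coding guidance takes effect), and
  month-of-year (the seasonality probe — kept as a candidate grouping
  only, since no seasonal clustering is expected a priori). Singleton
  groups are excluded with a warning; a partition with fewer than two
  usable groups is rejected.
- **Attribution** (`attribute_source`): at a flagged step, the joint map
  is marginalised onto each variable and the step's divergence recomputed;
  variables are ranked by that marginal score, and
  `category_contributions` splits the top variable's score into additive
  per-category terms (each category's summand of the two KL sums).

Detection is invariant to category relabeling and to the arbitrary sign of
embedding axes (tested).

## Synthetic generator

The generator produces the two dataset shapes the pipeline consumes, with
every planted effect recorded in a manifest.

**Hospital mode.** Each month's configured volume (default 50 000 included
codes/month) is one multinomial draw over code × age band × gender ×
deprivation cells. Code shares follow piecewise-linear trajectories with
optional multiplicative step changes applying from the first day of their
month; a remainder pseudo-code (`IXX`) absorbs unallocated share so the
code marginal always normalises. Demographics are independent of code and
stable unless a mix shift reweights a marginal over a period. The default
code set is the ten 3-character groups central to cardiovascular
admission coding (G45, I20, I21, I22, I25, I48, I50, I63, I64, remainder)
with baseline shares matching published January-2001 values where
available (I20 18.8%, I21 8.0%, I22 1.4%) and realistic magnitudes
otherwise. Scenarios not tied to the 50 000/month reference condition
(gradual drift, financial-year clustering) use 200 000 codes/month, the
realistic scale of national monthly cardiovascular code volume.

**Primary-care mode.** Patients (default 200 000) carry year of birth,
gender, deprivation quintile and a registration interval; the initial
cohort registers well before the window so the 1-year rule passes from
month one. Per condition, each patient draws a single latent uniform *u*;
their first event is dated so that the flag turns on in the first month
whose (running-maximum) target prevalence reaches *u* — historic
diagnoses are dated at registration, incident ones in the month before
their first flagged month. In a closed cohort this makes the expected
cross-sectional prevalence track the configured trajectory exactly.
Because an ever-recorded flag is monotone within a patient, declining
trajectories are rejected unless monthly registration churn is enabled;
with churn, entrants reflect the current (lower) target and prevalence
falls gradually, emulating how open-cohort recorded prevalence genuinely
declines. A dropout schedule (non-increasing retained fractions) removes
patients without replacement, optionally concentrated on demographic
categories via mix-shift weights — the mechanism behind selective
practice attrition and its deprivation-mix signature.

All randomness descends from one integer seed through a fixed
`SeedSequence` spawn order (demographics, churn, one stream per condition,
event days; per-month streams in hospital mode); outputs are
byte-identical for a fixed config.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: comorbidity correlation between conditions;
within-patient correlation between demographics and disease risk; secular
demographic change (ageing) other than planted mix shifts; multi-practice
hierarchy beyond the dropout schedule; free text, drugs, and transfer of
care records. Detection performance on real extracts will differ where
those structures dominate.

## Problem sizes and tolerances

- Reference recovery condition: 180 months × 50 000 codes/month, step at
  month index 135 (April 2012 for a January-2001 start) moving I21 from
  8.0% to 10.9%; recovery and null calibration are each evaluated over 20
  seeds in the acceptance tests.
- Probability vectors must sum to 1 within 1e-9; dissimilarity matrices
  are symmetric within 1e-12 with zero diagonal; DTM rows sum to 1 within
  1e-9; MDS recovers a planted 12-point Euclidean configuration within
  1e-6 after Procrustes (equilateral triangle to 1e-9).
- Relative changes are computed in exact rational arithmetic on the
  decimal values as printed and rounded half-away-from-zero at the
  caller's precision (0 dp for integer percentages, 1 dp otherwise).

## Known limitations

- The abrupt-step rule assumes a stable baseline; a strong gradual trend
  superimposed on a step raises the median/MAD and can mask small steps.
  Detrending the series first is a natural extension.
- Classical MDS is exact only for Euclidean-embeddable input; with the
  (non-metric) divergence scale the clamped-eigenvalue diagnostic should
  be inspected before reading the plot.
- The July age convention creates a real discontinuity every July in any
  age-including map; exclude the age variable (by marginalizing it away)
  when it dominates.
- Silhouette-based cluster flagging needs the between-period shift to
  exceed the multinomial noise floor; at small monthly volumes genuine
  but small period structure will not reach the 0.5 default.
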