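# Methods

## The question

When a 1:1 propensity-score matched sample is analysed, should the matched
treated and control groups be treated as two independent samples or as
paired data?  For a dichotomous outcome analysed on the risk-difference
(absolute risk reduction) scale, the point estimate is identical either
way, but the test statistic and the variance estimate are not.  `psmpairs`
quantifies the difference by Monte Carlo simulation: it generates cohorts
with known confounding and a known marginal ATT risk difference, matches
them, and measures how each inferential tradition performs.

## Data-generating process

Each cohort has ten baseline covariates X1–X10 entering both of

* a treatment-selection model:
  `logit P(Z=1|X) = α0,treat + Σ αj Xj`,
* an outcome model:
  `logit P(Y=1|X,Z) = α0,outcome + Σ αj Xj + β Z`,

so every covariate is a confounder.  Five covariate laws are provided
(independent standard normal; exchangeably correlated normal, ρ = 0.25 via
Cholesky factorisation; two mixed Bernoulli/normal designs; independent
Bernoulli(0.5)).  The slopes take four magnitudes — low, medium, high,
very high — with a *weak* set (log 1.1, log 1.25, log 1.5, log 2) and a
*strong* set (log 1.5, log 1.75, log 2, log 2.5) controlling how strongly
selection depends on the covariates.

**Allocation of magnitudes to covariates.**  The mapping of the four
magnitudes to X1–X10 is a free design choice; the default cycles
L, M, H, VH across X1–X10 (so 3 L, 3 M, 2 H, 2 VH) and is identical in
both models.  It is exposed in configuration because some scenario-level
quantities (notably the matched percentage and the independent-method
variance ratio) are mildly sensitive to it.  Under the default allocation
the shipped reference constants for the weak/independent-normal design
land within 0.01 of the marginal targets, which is why those constants are
retained as cross-checks — but the package never uses them at run time.

**Calibration.**  Three marginal targets define each scenario cell: a
treated fraction of 0.25, a marginal outcome probability under no
treatment of 0.29 or 0.15, and an ATT risk difference
RD ∈ {0, −0.02, −0.05, −0.10, −0.15}, defined as
`E[P(Y=1|X,Z=1) − P(Y=1|X,Z=0) | Z=1]`.  Intercepts and β are found by
bracketed root finding (Brent) on Monte Carlo estimates of these marginals
over a fixed calibration sample (default m = 10⁶ draws; the reduced-scale
grid preset uses m = 4×10⁵), to a tolerance of 10⁻⁴ on the probability
scale.  Both marginals are strictly monotone in their parameter, so the
roots are unique.  All cells of one covariate-law × strength family share
one calibration sample and one treated draw (common random numbers), which
makes the solved constants independent of which cells are requested and
reproducible from the master seed alone.  RD = 0 short-circuits to β = 0.

**Strong-selection cohorts.**  Strong selection leaves too few comparable
controls, so those cells start from 1 000 subjects and append ten extra
copies of every untreated subject; copies share the original's covariates
and outcome probability but draw outcomes independently.  Weak cells use
10 000 subjects and no augmentation.

## Matching

The propensity score is re-estimated per replicate by logistic regression
(statsmodels, Newton, tolerance 10⁻⁸, 100-iteration cap); replicates with
non-convergent fits are flagged invalid and excluded (with counts
reported) rather than patched.  Matching is greedy nearest-neighbor on the
logit propensity score, 1:1 without replacement, within a caliper of
0.2 × the pooled SD `sqrt((s1² + s2²)/2)` of the logit score across
treatment groups — the multiplier shown elsewhere to be near-optimal for
risk-difference estimation, exposed as a knob.  Treated subjects are
processed in a uniformly random order drawn from the replicate stream;
distance ties between candidate controls break to the lower subject
index, making a replicate fully deterministic given its seed.  Unmatched
treated subjects are dropped (matched-sample ATT) and their frequency is
the matched-percentage metric.

## Inference in the matched sample

With pairs cross-classified as a (both events), b (treated-only), c
(control-only), d (neither), n = a+b+c+d:

* point estimate (both traditions): `rd = (b − c)/n`;
* independent-samples: `var = (p_T(1−p_T) + p_C(1−p_C))/n`,
  Pearson chi-squared on the 2×2 treatment-by-outcome table of the 2n
  matched subjects;
* paired: `var = ((b + c) − (c − b)²/n)/n²`, McNemar chi-squared
  `(b − c)²/(b + c)`.

The two variances obey the exact identity
`var_ind − var_pair = 2(ad − bc)/n³`: whenever outcomes are positively
associated within pairs (ad > bc, the signature of confounder-driven
matching), the paired variance is strictly smaller.  Both tests are
uncorrected by default (continuity corrections are available but off;
empirical type I error near 0.05 for the uncorrected McNemar statistic
supports that choice).  Degenerate tables (b + c = 0 for McNemar, a zero
margin for Pearson) score statistic 0, p = 1 — conservative, and counted
rather than hidden.  95% intervals are `rd ± 1.96·se`, deliberately not
clipped to [−1, 1] so coverage is assessed on the raw interval.

## Evaluation harness

The full design is 2 strengths × 2 outcome probabilities × 5 covariate
laws × 5 risk differences = 100 cells × 1825 replicates.  Per cell the
harness reports: mean matched percentage; empirical type I error of each
test (null cells, rejection strictly at p < 0.05); empirical coverage of
each interval (proportion containing the target RD); mean interval widths
and their ratio; and each method's variance ratio
`(mean estimated SE / empirical SD of rd)²` — 1.0 means the estimator
tracks the true sampling variability.  At 1825 replicates, rates outside
0.05 ± 0.01 (tests) or 0.95 ± 0.01 (coverage) differ significantly from
nominal; `mc_significance_bounds` computes these bands for any replicate
count.  Cross-scenario summaries use medians and quartiles with linear
interpolation between order statistics.

**Seeding.**  Replicate r of cell s under master seed M uses the stream
seeded by (M, s, r); calibration streams derive from M and the family
coordinates.  Results are therefore identical whether cells or replicates
run serially or in parallel, and any subset of the grid reproduces the
full grid's numbers.

**Problem sizes.**  Three presets: `full` (100 × 1825, weak cohorts of
10 000); `grid-desk` (100 × 150, weak cohorts of 2 500, calibration
m = 4×10⁵) — the package's reduced-scale working set for exercising the
whole grid; `null-desk` (20 null cells × 400, full-size cohorts).  The
test suite exercises the full-scale independent-Bernoulli/weak/0.29 null
cell at 1825 replicates and the complete grid at `grid-desk` scale.
Quantities that are per-replicate (coverage, width ratio, variance
ratios) are essentially scale-free; absolute interval widths in weak
cells are wider at 2 500 subjects than at 10 000 (∝ n^{−1/2}), and
non-null weak cells show less coverage erosion at the reduced size
because the matching bias shrinks relative to the wider SE — the
reduced-scale medians remain comparable because those cells sit in the
distribution's tails.

## What the simulations do and do not show

The generator emulates confounded treatment assignment with known,
correctly specified logistic models — the propensity model fitted at
analysis time contains exactly the true covariates.  Real data add model
misspecification, unmeasured confounding, covariate measurement error and
outcome dependence between subjects, none of which are simulated; results
here isolate the pure effect of ignoring the matched design, not the
robustness of matching itself.  Conclusions are about risk differences;
odds ratios, relative risks, NNT and time-to-event effects are out of
scope.  Matching is 1:1 greedy within-caliper without replacement; other
matching schemes may change the within-pair correlation and hence the gap
between the two traditions.

## Known limitations

* The magnitude-to-covariate allocation is a convention; quantities tied
  to the absolute degree of confounding (matched percentage, independent
  variance ratio) shift by a few tenths of a point under different
  allocations, which is why tolerances on those quantities are looser.
* The greedy order is randomized per replicate; a sorted processing order
  would change individual matches (summary metrics are insensitive in
  these designs, but this is only verified for the random order).
* Variance-ratio estimates need many replicates: at 150 replicates a
  single cell's ratio carries ≈ 12% relative noise, so only cross-grid
  medians are meaningful at reduced scale.
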