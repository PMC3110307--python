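# psmpairs

Paired versus independent-samples inference for risk differences in
propensity-score matched samples, evaluated by Monte Carlo simulation.

## The problem

Propensity-score matching builds a sample of 1:1 treated–control pairs in
which baseline covariates are balanced, so the effect of a binary
treatment on a binary outcome can be read off as a risk difference
`rd = p_T − p_C`.  Applied analyses often test and interval-estimate that
difference with independent-samples machinery (Pearson chi-squared,
two-proportion variance `(p_T(1−p_T) + p_C(1−p_C))/N`).  But matched
pairs share covariates, and under confounding shared covariates induce
positively correlated outcomes within pairs — the matched sample is
paired data.  The paired alternatives are McNemar's test
`(b − c)²/(b + c)` and the matched-pairs variance
`((b + c) − (c − b)²/n)/n²`, where b and c count the discordant pairs.
The two variances differ by exactly `2(ad − bc)/n³`, so positive
within-pair association makes the independent-samples variance an
overestimate.

`psmpairs` measures the practical consequences: it simulates cohorts with
known confounding and a known marginal ATT risk difference, fits the
propensity score, matches greedily on the logit scale within a caliper of
0.2 pooled SDs, and compares the two traditions on empirical type I
error, 95% CI coverage, CI width, and variance-estimator calibration
across a 100-scenario grid (5 covariate laws × weak/strong selection ×
2 baseline outcome probabilities × 5 risk differences).  It is intended
for biostatisticians and simulation methodologists who want to reproduce,
extend, or stress-test that comparison.

## Worked example

```python
import numpy as np
from psmpairs import (
    ScenarioSpec, calibrate_scenario, run_scenario, mc_significance_bounds,
)

# the null cell with ten Bernoulli(0.5) covariates and weak selection
spec = ScenarioSpec("independent_bernoulli", "weak",
                    baseline_outcome_prob=0.29, target_rd=0.0)
coeffs = calibrate_scenario(spec, seed=1, m=1_000_000)
print(f"alpha0_treat={coeffs.alpha0_treat:.4f} "
      f"alpha0_outcome={coeffs.alpha0_outcome:.4f} beta={coeffs.beta}")

m = run_scenario(spec, coeffs, n_replicates=200, master_seed=1,
                 scenario_index=20)
band = mc_significance_bounds(0.05, 200)
print(f"matched %        : {m.mean_matched_pct:.1f}")
print(f"type I  McNemar  : {m.type1_mcnemar:.4f}")
print(f"type I  Pearson  : {m.type1_pearson:.4f}")
print(f"band at 200 reps : ({band.lower:.3f}, {band.upper:.3f})")
print(f"var ratio paired/independent: "
      f"{m.var_ratio_paired:.3f} / {m.var_ratio_independent:.3f}")
```

prints

```
alpha0_treat=-2.7619 alpha0_outcome=-2.5445 beta=0.0
matched %        : 99.3
type I  McNemar  : 0.0450
type I  Pearson  : 0.0400
band at 200 reps : (0.020, 0.080)
var ratio paired/independent: 1.011 / 1.078
```

The calibrated intercepts put 25% of subjects on treatment and a 29%
marginal outcome probability if nobody were treated; `beta = 0` is the
null.  Nearly all treated subjects find a control (ties are plentiful
with ten binary covariates).  Both tests reject at close to the nominal
rate in this mildly confounded cell, but the paired variance tracks the
empirical sampling variance (ratio ≈ 1) while the independent-samples
variance overestimates it — the gap widens sharply in the correlated and
strong-selection scenarios.

The same machinery is scriptable from the shell:

```bash
psmpairs run --preset grid-desk --seed 1 --out results/grid
psmpairs calibrate --preset full --seed 1 --out results/coeffs.csv
```

which writes per-scenario metrics (`scenarios.csv`), null-cell type I
error rates (`type1.csv`), per-cell coverage/width/variance-ratio detail
(`detail.csv`), cross-scenario medians (`summary.csv`), significance-band
exceedance counts (`band_counts.csv`) and a run manifest.

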