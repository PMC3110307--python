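"""Data-generating process: covariate laws, coefficients, calibration."""

import math

import numpy as np
import pytest
from scipy.special import expit, logit

from psmpairs import (
    CoefficientSet,
    ScenarioSpec,
    augment_controls,
    build_coefficients,
    calibrate_beta,
    calibrate_intercept,
    generate_covariates,
    simulate_cohort,
)
from psmpairs.dgp import (
    DEFAULT_ALLOCATION,
    STRONG_LEVEL_VALUES,
    WEAK_LEVEL_VALUES,
    CalibrationError,
    ConfigurationError,
)

N = 50_000


class TestCovariateLaws:
    def test_independent_normal_moments(self, rng):
        X = generate_covariates("independent_normal", N, rng)
        assert X.shape == (N, 10)
        se_mean, se_var = 1 / math.sqrt(N), math.sqrt(2 / N)
        assert np.all(np.abs(X.mean(axis=0)) < 3 * se_mean)
        assert np.all(np.abs(X.var(axis=0, ddof=1) - 1) < 3 * se_var)

    def test_correlated_normal_exchangeable(self, rng):
        X = generate_covariates("correlated_normal", N, rng)
        corr = np.corrcoef(X.T)
        off = corr[np.triu_indices(10, k=1)]
        se = (1 - 0.25**2) / math.sqrt(N)
        assert np.all(np.abs(off - 0.25) < 3 * se)
        assert np.all(np.abs(X.var(axis=0, ddof=1) - 1) < 3 * math.sqrt(2 / N))

    def test_independent_bernoulli_means(self, rng):
        X = generate_covariates("independent_bernoulli", N, rng)
        se = 0.5 / math.sqrt(N)
        assert set(np.unique(X)) == {0.0, 1.0}
        assert np.all(np.abs(X.mean(axis=0) - 0.5) < 3 * se)

    @pytest.mark.parametrize(
        "scenario,n_binary", [("mixed1", 5), ("mixed2", 9)]
    )
    def test_mixed_scenarios(self, scenario, n_binary, rng):
        X = generate_covariates(scenario, N, rng)
        binary, normal = X[:, :n_binary], X[:, n_binary:]
        assert set(np.unique(binary)) == {0.0, 1.0}
        assert np.all(np.abs(binary.mean(axis=0) - 0.5) < 3 * 0.5 / math.sqrt(N))
        assert np.all(np.abs(normal.mean(axis=0)) < 3 / math.sqrt(N))
        assert np.all(
            np.abs(normal.var(axis=0, ddof=1) - 1) < 3 * math.sqrt(2 / N)
        )

    def test_unknown_scenario_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            generate_covariates("cauchy", 100, rng)


class TestCoefficients:
    def test_weak_default_allocation(self):
        c = build_coefficients("weak")
        assert c.level_values == WEAK_LEVEL_VALUES
        # cyclic L,M,H,VH puts the very-high slope log 2 on X4 and X8
        assert c.slopes[3] == pytest.approx(math.log(2))
        assert c.slopes[7] == pytest.approx(math.log(2))
        assert c.alpha0_treat is None and c.beta is None

    def test_strong_levels(self):
        c = build_coefficients("strong")
        assert c.level_values == STRONG_LEVEL_VALUES
        assert c.slopes[0] == pytest.approx(math.log(1.5))

    def test_degenerate_all_low_allocation(self):
        c = build_coefficients("weak", allocation=("L",) * 10)
        assert np.allclose(c.slopes, math.log(1.1))

    def test_bad_allocation_rejected(self):
        with pytest.raises(ConfigurationError):
            build_coefficients("weak", allocation=("L", "M"))
        with pytest.raises(ConfigurationError):
            build_coefficients("weak", allocation=("L",) * 9 + ("XL",))


class TestScenarioSpec:
    def test_defaults_by_strength(self):
        weak = ScenarioSpec("mixed1", "weak", 0.29, -0.05)
        strong = ScenarioSpec("mixed1", "strong", 0.29, -0.05)
        assert (weak.n_initial, weak.control_copies) == (10_000, 0)
        assert (strong.n_initial, strong.control_copies) == (1_000, 10)

    def test_augmentation_requires_strong(self):
        with pytest.raises(ConfigurationError):
            ScenarioSpec("mixed1", "weak", 0.29, 0.0, control_copies=5)


class TestCalibrateIntercept:
    def test_zero_slopes_closed_form(self, rng):
        # without covariate noise the marginal mean is expit(a0) exactly
        a0 = calibrate_intercept(0.25, np.zeros(10), "independent_normal",
                                 rng, m=10_000)
        assert a0 == pytest.approx(logit(0.25), abs=1e-5)
        a0 = calibrate_intercept(0.5, np.zeros(10), "independent_normal",
                                 rng, m=10_000)
        assert a0 == pytest.approx(0.0, abs=1e-5)

    def test_matches_grid_search_oracle(self, rng):
        # independent brute-force oracle: scan a0 on a fine grid over the
        # same fixed covariate sample and take the best marginal fit
        slopes = build_coefficients("weak").slopes
        X = generate_covariates("independent_normal", 200_000, rng)
        a0 = calibrate_intercept(0.25, slopes, "independent_normal", rng,
                                 X=X, tol=1e-4)
        grid = np.arange(-2.0, -0.8, 1e-3)
        eta = X @ slopes
        means = np.array([expit(g + eta).mean() for g in grid])
        oracle = grid[np.argmin(np.abs(means - 0.25))]
        assert a0 == pytest.approx(oracle, abs=2e-3)

    def test_prevalence_monotone_in_intercept(self, rng):
        slopes = build_coefficients("strong").slopes
        X = generate_covariates("mixed1", 50_000, rng)
        eta = X @ slopes
        means = [expit(a0 + eta).mean() for a0 in np.linspace(-4, 2, 13)]
        assert np.all(np.diff(means) > 0)


class TestCalibrateBeta:
    def _calibrated(self, rng, prob=0.29):
        spec_scenario = "independent_normal"
        base = build_coefficients("weak")
        X = generate_covariates(spec_scenario, 200_000, rng)
        a_t = calibrate_intercept(0.25, base.slopes, spec_scenario, rng, X=X)
        a_o = calibrate_intercept(prob, base.slopes, spec_scenario, rng, X=X)
        return CoefficientSet(base.level_values, base.allocation,
                              alpha0_treat=a_t, alpha0_outcome=a_o), X

    def test_null_short_circuits(self, rng):
        coeffs, X = self._calibrated(rng)
        assert calibrate_beta(0.0, coeffs, "independent_normal", rng, X=X) == 0.0

    def test_matches_grid_search_oracle(self, rng):
        coeffs, X = self._calibrated(rng)
        eta = coeffs.alpha0_treat + X @ coeffs.slopes
        treated = rng.random(X.shape[0]) < expit(eta)
        beta = calibrate_beta(-0.05, coeffs, "independent_normal", rng,
                              X=X, treated_mask=treated)
        eta_out = coeffs.alpha0_outcome + (X @ coeffs.slopes)[treated]
        p0 = expit(eta_out)
        grid = np.arange(-0.6, 0.0, 1e-3)
        rds = np.array([np.mean(expit(eta_out + g) - p0) for g in grid])
        oracle = grid[np.argmin(np.abs(rds + 0.05))]
        assert beta == pytest.approx(oracle, abs=2e-3)

    def test_monotone_in_target(self, rng):
        coeffs, X = self._calibrated(rng)
        treated = rng.random(X.shape[0]) < expit(
            coeffs.alpha0_treat + X @ coeffs.slopes
        )
        betas = [
            calibrate_beta(rd, coeffs, "independent_normal", rng, X=X,
                           treated_mask=treated)
            for rd in (-0.02, -0.05, -0.15)
        ]
        assert betas[0] > betas[1] > betas[2]

    def test_impossible_target_raises(self, rng):
        coeffs, X = self._calibrated(rng, prob=0.15)
        with pytest.raises(CalibrationError):
            calibrate_beta(-0.9, coeffs, "independent_normal", rng, X=X)


class TestSimulateCohort:
    def test_probability_identities(self, bernoulli_weak_null, rng):
        spec, coeffs = bernoulli_weak_null
        c = simulate_cohort(spec, coeffs, rng)
        eta = c.X @ coeffs.slopes
        assert np.allclose(c.p_treat, expit(coeffs.alpha0_treat + eta))
        assert np.allclose(
            c.p_outcome,
            expit(coeffs.alpha0_outcome + eta + coeffs.beta * c.Z),
        )
        assert np.all((c.p_treat > 0) & (c.p_treat < 1))
        assert np.all((c.p_outcome > 0) & (c.p_outcome < 1))

    def test_marginal_targets(self, bernoulli_weak_null, rng):
        spec, coeffs = bernoulli_weak_null
        c = simulate_cohort(spec, coeffs, rng)
        n = spec.n_initial
        assert abs(c.Z.mean() - 0.25) < 3 * math.sqrt(0.25 * 0.75 / n) + 1e-3
        # outcome probability if nobody were treated
        p_untreated = expit(coeffs.alpha0_outcome + c.X @ coeffs.slopes)
        assert abs(p_untreated.mean() - 0.29) < 3 * math.sqrt(
            0.29 * 0.71 / n
        ) + 1e-3

    def test_zero_covariate_subject_closed_form(self):
        coeffs = CoefficientSet(
            WEAK_LEVEL_VALUES, DEFAULT_ALLOCATION,
            alpha0_treat=-1.0, alpha0_outcome=-0.5, beta=-0.3,
        )
        spec = ScenarioSpec("independent_bernoulli", "weak", 0.29, -0.05,
                            n_initial=2000)
        c = simulate_cohort(spec, coeffs, np.random.default_rng(3))
        zero_treated = (c.X.sum(axis=1) == 0) & (c.Z == 1)
        assert np.allclose(
            c.p_outcome[zero_treated], expit(-0.5 - 0.3)
        )

    def test_requires_calibrated_coefficients(self, rng):
        spec = ScenarioSpec("mixed2", "weak", 0.29, 0.0)
        with pytest.raises(CalibrationError):
            simulate_cohort(spec, build_coefficients("weak"), rng)


class TestAugmentControls:
    def test_zero_copies_is_identity(self, bernoulli_weak_null, rng):
        spec, coeffs = bernoulli_weak_null
        c = simulate_cohort(spec, coeffs, rng)
        assert augment_controls(c, 0, rng) is c

    def test_counts_and_treated_untouched(self, bernoulli_weak_null, rng):
        spec, coeffs = bernoulli_weak_null
        c = simulate_cohort(spec, coeffs, rng)
        n_untreated = c.n - c.n_treated
        aug = augment_controls(c, 10, rng)
        assert aug.n_treated == c.n_treated
        assert aug.n - aug.n_treated == 11 * n_untreated
        # original block is preserved bit-exactly, copies duplicate X rows
        assert np.array_equal(aug.X[: c.n], c.X)
        assert np.array_equal(aug.Z[: c.n], c.Z)
        assert np.array_equal(aug.Y[: c.n], c.Y)
        untreated = np.flatnonzero(c.Z == 0)
        assert np.array_equal(aug.X[c.n : c.n + untreated.size],
                              c.X[untreated])

    def test_copy_outcomes_are_fresh_draws(self, rng):
        # p = 0.5 rows: P(all 11 outcomes of a duplicate set agree) = 2*0.5^11
        from psmpairs.dgp import Cohort

        n = 2000
        c = Cohort(
            X=np.zeros((n, 10)),
            p_treat=np.full(n, 0.2),
            Z=np.zeros(n, dtype=np.int8),
            p_outcome=np.full(n, 0.5),
            Y=(rng.random(n) < 0.5).astype(np.int8),
        )
        aug = augment_controls(c, 10, rng)
        sets = np.column_stack(
            [c.Y] + [aug.Y[n * (k + 1) : n * (k + 2)] for k in range(10)]
        )
        frac_mixed = np.mean(sets.min(axis=1) != sets.max(axis=1))
        expected = 1 - 2 * 0.5**11
        assert abs(frac_mixed - expected) < 3 * math.sqrt(
            expected * (1 - expected) / n
        )

    def test_augmenting_all_treated_cohort_raises(self, rng):
        from psmpairs.dgp import Cohort

        c = Cohort(
            X=np.zeros((5, 10)), p_treat=np.full(5, 0.5),
            Z=np.ones(5, dtype=np.int8), p_outcome=np.full(5, 0.5),
            Y=np.zeros(5, dtype=np.int8),
        )
        with pytest.raises(ConfigurationError):
            augment_controls(c, 3, rng)
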