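"""Confounded-cohort data-generating process with calibrated marginal targets.

Cohorts carry ten baseline covariates that enter both a logistic
treatment-selection model and a logistic outcome model, so every covariate
is a confounder.  Intercepts are calibrated numerically so that the marginal
treatment prevalence and the marginal outcome probability under no treatment
hit their targets, and the treatment coefficient ``beta`` is calibrated so
that the marginal risk difference among the treated (the ATT risk
difference) equals a requested value.  Calibration is Monte Carlo root
finding on a fixed calibration sample, so common random numbers are shared
across candidate parameter values and the solved constants are reproducible
from the calibration seed.

Five covariate laws are supported:

``independent_normal``
    ten i.i.d. standard normal covariates;
``correlated_normal``
    multivariate normal, unit variances, exchangeable pairwise
    correlation 0.25;
``mixed1``
    X1-X5 Bernoulli(0.5), X6-X10 standard normal;
``mixed2``
    X1-X9 Bernoulli(0.5), X10 standard normal;
``independent_bernoulli``
    ten i.i.d. Bernoulli(0.5) covariates.

Covariate coefficients take one of four log-odds-ratio magnitudes (low,
medium, high, very high); a "weak" and a "strong" selection set are
provided.  The allocation of the four magnitudes to the ten covariates is a
configuration choice; the default cycles L, M, H, VH across X1-X10 and is
used identically in the treatment and outcome models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

COVARIATE_SCENARIOS = (
    "independent_normal",
    "correlated_normal",
    "mixed1",
    "mixed2",
    "independent_bernoulli",
)
SELECTION_STRENGTHS = ("weak", "strong")

LEVELS = ("L", "M", "H", "VH")

#: log-odds ratios (low, medium, high, very high) for the weak selection set
WEAK_LEVEL_VALUES = (
    math.log(1.1),
    math.log(1.25),
    math.log(1.5),
    math.log(2.0),
)
#: log-odds ratios for the strong selection set
STRONG_LEVEL_VALUES = (
    math.log(1.5),
    math.log(1.75),
    math.log(2.0),
    math.log(2.5),
)

#: default covariate-to-magnitude allocation: cycle L, M, H, VH across X1-X10
DEFAULT_ALLOCATION = ("L", "M", "H", "VH", "L", "M", "H", "VH", "L", "M")

# Reference intercepts for the weak, independent-normal design.  Under the
# default allocation they land close to the marginal targets (treated
# fraction 0.25, untreated outcome probability 0.29) and serve as
# plausibility cross-checks; runtime defaults always recalibrate.
REFERENCE_ALPHA0_TREAT_WEAK = -1.344090
REFERENCE_ALPHA0_OUTCOME_WEAK = -1.098537
#: reference treatment log-odds ratios for ATT risk differences
#: (-0.02, -0.05, -0.10, -0.15) in the weak, independent-normal design
REFERENCE_BETAS_WEAK = {
    -0.02: math.log(0.90619),
    -0.05: math.log(0.7795362),
    -0.10: math.log(0.6001387),
    -0.15: math.log(0.45292),
}

GRID_RISK_DIFFERENCES = (0.0, -0.02, -0.05, -0.10, -0.15)

N_COVARIATES = 10

# exchangeable correlation 0.25, unit variances; Cholesky factor cached
_EXCH_CORR = 0.25
_CHOL = np.linalg.cholesky(
    np.full((N_COVARIATES, N_COVARIATES), _EXCH_CORR)
    + (1.0 - _EXCH_CORR) * np.eye(N_COVARIATES)
)


class ConfigurationError(ValueError):
    """Raised for invalid scenario or coefficient configuration."""


class CalibrationError(RuntimeError):
    """Raised when Monte Carlo calibration fails to converge or bracket."""


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation grid.

    Parameters
    ----------
    covariate_scenario
        One of :data:`COVARIATE_SCENARIOS`.
    selection_strength
        ``"weak"`` or ``"strong"``; selects the coefficient magnitudes and
        the cohort-size convention (weak: 10 000 subjects, no augmentation;
        strong: 1 000 subjects, 10 extra copies of every untreated subject).
    baseline_outcome_prob
        Target marginal outcome probability if nobody were treated
        (grid values 0.29 and 0.15).
    target_rd
        Target ATT risk difference (grid values 0, -0.02, -0.05, -0.10,
        -0.15); 0 is the null.
    n_initial
        Initially generated cohort size; defaults by strength.
    control_copies
        Extra independent-outcome copies of each untreated subject added
        after generation; defaults by strength (0 weak, 10 strong).
    n_replicates
        Monte Carlo replicates for this cell.
    """

    covariate_scenario: str
    selection_strength: str
    baseline_outcome_prob: float
    target_rd: float
    n_initial: int | None = None
    control_copies: int | None = None
    n_replicates: int = 1825

    def __post_init__(self) -> None:
        if self.covariate_scenario not in COVARIATE_SCENARIOS:
            raise ConfigurationError(
                f"unknown covariate scenario {self.covariate_scenario!r}; "
                f"expected one of {COVARIATE_SCENARIOS}"
            )
        if self.selection_strength not in SELECTION_STRENGTHS:
            raise ConfigurationError(
                f"unknown selection strength {self.selection_strength!r}"
            )
        if not 0.0 < self.baseline_outcome_prob < 1.0:
            raise ConfigurationError("baseline_outcome_prob must lie in (0, 1)")
        if self.target_rd > 0.0 or self.target_rd <= -1.0:
            raise ConfigurationError("target_rd must lie in (-1, 0]")
        strong = self.selection_strength == "strong"
        if self.n_initial is None:
            object.__setattr__(self, "n_initial", 1_000 if strong else 10_000)
        if self.control_copies is None:
            object.__setattr__(self, "control_copies", 10 if strong else 0)
        if self.n_initial < 2:
            raise ConfigurationError("n_initial must be at least 2")
        if self.control_copies < 0:
            raise ConfigurationError("control_copies must be non-negative")
        if self.control_copies > 0 and not strong:
            raise ConfigurationError(
                "control augmentation is only used with strong selection"
            )
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be positive")

    @property
    def is_null(self) -> bool:
        return self.target_rd == 0.0

    @property
    def label(self) -> str:
        return (
            f"{self.selection_strength}/{self.baseline_outcome_prob:g}/"
            f"{self.covariate_scenario}/rd={self.target_rd:g}"
        )


@dataclass(frozen=True)
class CoefficientSet:
    """All parameters of the treatment-selection and outcome models.

    ``level_values`` are the four log-odds ratios (L, M, H, VH);
    ``allocation`` maps each of X1-X10 to one of the four levels and is
    shared by both models.  Intercepts and ``beta`` are ``None`` until
    calibrated.
    """

    level_values: tuple[float, float, float, float]
    allocation: tuple[str, ...] = DEFAULT_ALLOCATION
    alpha0_treat: float | None = None
    alpha0_outcome: float | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        if len(self.level_values) != len(LEVELS):
            raise ConfigurationError("level_values must have four entries")
        if len(self.allocation) != N_COVARIATES:
            raise ConfigurationError(
                f"allocation must map all {N_COVARIATES} covariates, "
                f"got {len(self.allocation)}"
            )
        unknown = set(self.allocation) - set(LEVELS)
        if unknown:
            raise ConfigurationError(f"unknown allocation levels {sorted(unknown)}")

    @property
    def slopes(self) -> np.ndarray:
        """Per-covariate log-odds ratios implied by the allocation."""
        table = dict(zip(LEVELS, self.level_values))
        return np.array([table[level] for level in self.allocation])

    @property
    def calibrated(self) -> bool:
        return None not in (self.alpha0_treat, self.alpha0_outcome, self.beta)


@dataclass
class Cohort:
    """A simulated cohort: covariates, true probabilities, treatment, outcome."""

    X: np.ndarray
    p_treat: np.ndarray
    Z: np.ndarray
    p_outcome: np.ndarray
    Y: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_treated(self) -> int:
        return int(self.Z.sum())


def generate_covariates(
    scenario: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw an ``n x 10`` covariate matrix under one of the five laws."""
    if n < 2:
        raise ConfigurationError("n must be at least 2")
    if scenario == "independent_normal":
        return rng.standard_normal((n, N_COVARIATES))
    if scenario == "correlated_normal":
        return rng.standard_normal((n, N_COVARIATES)) @ _CHOL.T
    if scenario == "mixed1":
        X = np.empty((n, N_COVARIATES))
        X[:, :5] = rng.binomial(1, 0.5, (n, 5))
        X[:, 5:] = rng.standard_normal((n, 5))
        return X
    if scenario == "mixed2":
        X = np.empty((n, N_COVARIATES))
        X[:, :9] = rng.binomial(1, 0.5, (n, 9))
        X[:, 9] = rng.standard_normal(n)
        return X
    if scenario == "independent_bernoulli":
        return rng.binomial(1, 0.5, (n, N_COVARIATES)).astype(float)
    raise ConfigurationError(f"unknown covariate scenario {scenario!r}")


def build_coefficients(
    selection_strength: str,
    allocation: Sequence[str] = DEFAULT_ALLOCATION,
) -> CoefficientSet:
    """Assemble the slope magnitudes for a selection strength.

    Intercepts and ``beta`` are left unset; calibrate them with
    :func:`calibrate_intercept` and :func:`calibrate_beta`.
    """
    if selection_strength == "weak":
        values = WEAK_LEVEL_VALUES
    elif selection_strength == "strong":
        values = STRONG_LEVEL_VALUES
    else:
        raise ConfigurationError(
            f"unknown selection strength {selection_strength!r}"
        )
    return CoefficientSet(level_values=values, allocation=tuple(allocation))


def _mc_bracketed_root(f, lo: float, hi: float, tol: float, what: str) -> float:
    flo, fhi = f(lo), f(hi)
    if not flo < 0.0 < fhi:
        raise CalibrationError(
            f"{what}: target not bracketed on [{lo}, {hi}] "
            f"(f(lo)={flo:.4g}, f(hi)={fhi:.4g})"
        )
    root = brentq(f, lo, hi, xtol=1e-6, maxiter=200)
    resid = f(root)
    if abs(resid) > tol:
        raise CalibrationError(
            f"{what}: residual {resid:.3g} exceeds tolerance {tol:.3g}"
        )
    return float(root)


def calibrate_intercept(
    target_prob: float,
    slopes: np.ndarray,
    scenario: str,
    rng: np.random.Generator,
    m: int = 1_000_000,
    tol: float = 1e-4,
    X: np.ndarray | None = None,
) -> float:
    """Solve for the logistic intercept hitting a marginal probability.

    Finds ``a0`` such that ``mean(expit(a0 + X @ slopes)) == target_prob``
    over a Monte Carlo sample of ``m`` covariate draws (or a caller-supplied
    fixed sample ``X``, enabling common random numbers across several
    calibrations).  The marginal mean is strictly increasing in ``a0`` so
    bracketed root finding applies.
    """
    if not 0.0 < target_prob < 1.0:
        raise ConfigurationError("target_prob must lie in (0, 1)")
    if X is None:
        X = generate_covariates(scenario, m, rng)
    eta = X @ np.asarray(slopes)
    center = float(logit(target_prob))

    def f(a0: float) -> float:
        return float(np.mean(expit(a0 + eta))) - target_prob

    return _mc_bracketed_root(
        f, center - 12.0, center + 12.0, tol, f"intercept for {target_prob}"
    )


def calibrate_beta(
    target_rd: float,
    coeffs: CoefficientSet,
    scenario: str,
    rng: np.random.Generator,
    m: int = 1_000_000,
    tol: float = 1e-4,
    X: np.ndarray | None = None,
    treated_mask: np.ndarray | None = None,
) -> float:
    """Solve for the treatment log-odds ratio inducing a marginal ATT risk
    difference.

    The estimand is ``E[p1 - p0 | treated]`` where ``p1``/``p0`` are the
    outcome-model probabilities with and without treatment; the expectation
    runs over subjects drawn treated under the calibrated selection model
    (a caller may fix that draw with ``treated_mask`` to share it across
    several calibrations).  ``target_rd = 0`` short-circuits to
    ``beta = 0``.
    """
    if target_rd == 0.0:
        return 0.0
    if not -1.0 < target_rd < 0.0:
        raise ConfigurationError("target_rd must lie in (-1, 0]")
    if coeffs.alpha0_treat is None or coeffs.alpha0_outcome is None:
        raise CalibrationError("intercepts must be calibrated before beta")
    if X is None:
        X = generate_covariates(scenario, m, rng)
    slopes = coeffs.slopes
    eta = X @ slopes
    if treated_mask is None:
        p_treat = expit(coeffs.alpha0_treat + eta)
        treated = rng.random(X.shape[0]) < p_treat
    else:
        treated = np.asarray(treated_mask, dtype=bool)
    if treated.sum() < 100:
        raise CalibrationError("too few treated draws in calibration sample")
    eta_out = coeffs.alpha0_outcome + eta[treated]
    p0 = expit(eta_out)

    def f(beta: float) -> float:
        # ATT RD is increasing in beta; shift sign so f is increasing with
        # a root at the requested (negative) target.
        return float(np.mean(expit(eta_out + beta) - p0)) - target_rd

    return _mc_bracketed_root(f, -12.0, 1.0, tol, f"beta for RD {target_rd}")


def simulate_cohort(
    spec: ScenarioSpec, coeffs: CoefficientSet, rng: np.random.Generator
) -> Cohort:
    """Generate one cohort of ``spec.n_initial`` subjects.

    Treatment is Bernoulli from the selection model; the outcome is
    Bernoulli from the outcome model evaluated at the assigned treatment.
    Control augmentation (strong selection) is a separate step; see
    :func:`augment_controls`.
    """
    if not coeffs.calibrated:
        raise CalibrationError("coefficients must be fully calibrated")
    X = generate_covariates(spec.covariate_scenario, spec.n_initial, rng)
    slopes = coeffs.slopes
    eta = X @ slopes
    p_treat = expit(coeffs.alpha0_treat + eta)
    Z = (rng.random(spec.n_initial) < p_treat).astype(np.int8)
    p_outcome = expit(coeffs.alpha0_outcome + eta + coeffs.beta * Z)
    Y = (rng.random(spec.n_initial) < p_outcome).astype(np.int8)
    return Cohort(X=X, p_treat=p_treat, Z=Z, p_outcome=p_outcome, Y=Y)


def augment_controls(
    cohort: Cohort, copies: int, rng: np.random.Generator
) -> Cohort:
    """Append ``copies`` extra copies of every untreated subject.

    Copies share the original subject's covariates and outcome probability
    but receive fresh independent Bernoulli outcomes, enlarging the control
    reservoir without changing the treated group.  ``copies = 0`` returns
    the cohort unchanged.
    """
    if copies < 0:
        raise ConfigurationError("copies must be non-negative")
    if copies == 0:
        return cohort
    untreated = np.flatnonzero(cohort.Z == 0)
    if untreated.size == 0:
        raise ConfigurationError("cannot augment a cohort with no untreated subjects")
    dup = np.tile(untreated, copies)
    p_new = cohort.p_outcome[dup]
    Y_new = (rng.random(dup.size) < p_new).astype(np.int8)
    return Cohort(
        X=np.vstack([cohort.X, cohort.X[dup]]),
        p_treat=np.concatenate([cohort.p_treat, cohort.p_treat[dup]]),
        Z=np.concatenate([cohort.Z, np.zeros(dup.size, dtype=np.int8)]),
        p_outcome=np.concatenate([cohort.p_outcome, p_new]),
        Y=np.concatenate([cohort.Y, Y_new]),
    )
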