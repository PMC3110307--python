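"""Propensity-score estimation and greedy 1:1 caliper matching.

The propensity score is estimated by maximum-likelihood logistic regression
of treatment on the ten baseline covariates; matching operates on the logit
of the estimated score.  The caliper is a multiple (default 0.2) of the
pooled standard deviation of the logit propensity score across the two
treatment groups.  Greedy nearest-neighbor matching processes treated
subjects in a random order, pairing each with the closest unmatched control
within the caliper, without replacement; distance ties go to the control
with the lower subject index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationWarning,
)


class DegenerateDataError(ValueError):
    """Raised when the data cannot support the requested operation."""


@dataclass
class PropensityFit:
    """Fitted propensity model: coefficients and per-subject logit score.

    ``coefficients[0]`` is the intercept, ``coefficients[1:]`` the ten
    covariate slopes; ``logit_ps`` is the linear predictor (the logit of
    the estimated propensity score) recomputable as
    ``coefficients[0] + X @ coefficients[1:]``.
    """

    coefficients: np.ndarray
    logit_ps: np.ndarray
    converged: bool


@dataclass
class MatchedSample:
    """1:1 matched pairs on the logit propensity score.

    ``pairs`` is a ``(k, 2)`` integer array of (treated index, control
    index) into the original cohort; every index appears at most once and
    every pair satisfies the caliper constraint.
    """

    pairs: np.ndarray
    caliper: float
    n_treated_total: int

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    @property
    def matched_pct(self) -> float:
        """Percentage of treated subjects that found a control."""
        return 100.0 * self.n_pairs / self.n_treated_total


def fit_propensity(X: np.ndarray, Z: np.ndarray) -> PropensityFit:
    """Logistic regression of treatment status on the baseline covariates.

    Newton's method with tolerance 1e-8 on the coefficient update and an
    iteration cap of 100.  Non-convergence (including quasi-separation) is
    reported through ``converged`` rather than raised, so callers can flag
    and exclude the replicate.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.sum() == 0 or Z.sum() == Z.size:
        raise DegenerateDataError("both treatment groups must be non-empty")
    exog = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(Z, exog).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0
            )
            params = np.asarray(res.params)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            params = np.full(exog.shape[1], np.nan)
            converged = False
    if not np.all(np.isfinite(params)):
        converged = False
        params = np.nan_to_num(params)
    logit_ps = params[0] + np.asarray(X, dtype=float) @ params[1:]
    return PropensityFit(coefficients=params, logit_ps=logit_ps, converged=converged)


def compute_caliper(
    logit_ps: np.ndarray, Z: np.ndarray, multiplier: float = 0.2
) -> float:
    """Caliper width: ``multiplier * sqrt((s1^2 + s2^2) / 2)``.

    ``s1^2`` and ``s2^2`` are the sample variances (denominator n-1) of the
    logit propensity score within the treated and control groups.  The
    default multiplier 0.2 of the pooled SD targets accurate risk-difference
    estimation.
    """
    logit_ps = np.asarray(logit_ps, dtype=float)
    Z = np.asarray(Z)
    s1 = logit_ps[Z == 1]
    s0 = logit_ps[Z == 0]
    if s1.size < 2 or s0.size < 2:
        raise DegenerateDataError("need at least two subjects per group")
    pooled = (s1.var(ddof=1) + s0.var(ddof=1)) / 2.0
    if pooled == 0.0:
        raise DegenerateDataError("logit propensity score has zero variance")
    return float(multiplier * np.sqrt(pooled))


def greedy_match(
    logit_ps: np.ndarray,
    Z: np.ndarray,
    caliper: float,
    rng: np.random.Generator,
    order: np.ndarray | None = None,
) -> MatchedSample:
    """Greedy nearest-neighbor 1:1 matching without replacement.

    Treated subjects are processed in a uniformly random order drawn from
    ``rng`` (or in the caller-supplied ``order`` over the treated array);
    each is paired with the unmatched control minimising the absolute
    logit-propensity-score difference, provided that distance is within the
    caliper.  Matched controls are removed; treated subjects with no
    eligible control stay unmatched.  An empty matched sample is a valid
    result.
    """
    if caliper < 0:
        raise ValueError("caliper must be non-negative")
    logit_ps = np.asarray(logit_ps, dtype=float)
    Z = np.asarray(Z)
    treated = np.flatnonzero(Z == 1)
    controls = np.flatnonzero(Z == 0)
    if order is None:
        order = rng.permutation(treated.size)
    else:
        order = np.asarray(order)

    # controls sorted by (logit PS, original index): ties in distance then
    # resolve to the lower original index automatically on the left scan
    sort_key = np.lexsort((controls, logit_ps[controls]))
    c_idx = controls[sort_key]
    c_val = logit_ps[c_idx]
    m = c_idx.size

    # union-find "nearest alive neighbour" pointers with path compression;
    # position m (right) and -1 (left) are exhausted-side sentinels
    nxt = np.arange(m + 1, dtype=np.int64)
    prv = np.arange(m, dtype=np.int64)

    def find_right(i: int) -> int:
        root = i
        while root < m and nxt[root] != root:
            root = nxt[root]
        while i < m and nxt[i] != i:
            nxt[i], i = root, nxt[i]
        return int(root)

    def find_left(i: int) -> int:
        root = i
        while root >= 0 and prv[root] != root:
            root = prv[root]
        while i >= 0 and prv[i] != i:
            prv[i], i = root, prv[i]
        return int(root)

    pairs = []
    for t in treated[order]:
        v = logit_ps[t]
        pos = int(np.searchsorted(c_val, v))
        right = find_right(pos) if pos < m else m
        left = find_left(pos - 1) if pos > 0 else -1
        # equal-valued controls sort by ascending index, so the run's
        # leftmost alive member carries the lowest index; walk to it so
        # distance ties resolve to the lower subject index
        while left > 0:
            further = find_left(left - 1)
            if further >= 0 and c_val[further] == c_val[left]:
                left = further
            else:
                break
        best = -1
        if right < m and left >= 0:
            dr = abs(c_val[right] - v)
            dl = abs(v - c_val[left])
            if dr < dl:
                best = right
            elif dl < dr:
                best = left
            else:
                best = left if c_idx[left] < c_idx[right] else right
        elif right < m:
            best = right
        elif left >= 0:
            best = left
        if best < 0 or abs(c_val[best] - v) > caliper:
            continue
        pairs.append((t, c_idx[best]))
        nxt[best] = best + 1
        prv[best] = best - 1

    pair_arr = (
        np.array(pairs, dtype=np.int64)
        if pairs
        else np.empty((0, 2), dtype=np.int64)
    )
    return MatchedSample(
        pairs=pair_arr, caliper=float(caliper), n_treated_total=int(treated.size)
    )


def standardized_differences(
    X: np.ndarray, Z: np.ndarray, pairs: np.ndarray | None = None
) -> np.ndarray:
    """Absolute standardized mean differences of each covariate.

    With ``pairs`` given, compares the matched treated and control members;
    otherwise compares the full treated and control groups.  The
    denominator pools the full-cohort group variances so matched and
    unmatched balance are measured on the same scale.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z)
    v1 = X[Z == 1].var(axis=0, ddof=1)
    v0 = X[Z == 0].var(axis=0, ddof=1)
    denom = np.sqrt((v1 + v0) / 2.0)
    denom[denom == 0] = np.nan
    if pairs is None:
        diff = X[Z == 1].mean(axis=0) - X[Z == 0].mean(axis=0)
    else:
        diff = X[pairs[:, 0]].mean(axis=0) - X[pairs[:, 1]].mean(axis=0)
    return np.abs(diff / denom)
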