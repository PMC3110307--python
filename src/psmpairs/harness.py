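"""Monte Carlo harness: scenario grid, replicate loop, evaluation metrics.

The full design crosses 2 selection strengths x 2 baseline outcome
probabilities x 5 covariate scenarios x 5 target risk differences = 100
scenario cells, each run for 1825 replicates.  Per replicate: simulate a
cohort (with control augmentation under strong selection), estimate the
propensity score, match greedily within the caliper, cross-classify pairs,
and record the risk difference with both paired and independent-samples
standard errors, intervals, and test p-values.

Per scenario the harness reports: mean percentage of treated matched;
empirical type I error of each test (null cells only, rejection at
p < 0.05); empirical coverage of each 95% interval; mean interval widths
and their ratio; and each method's variance ratio, the squared ratio of
the mean estimated standard error to the empirical standard deviation of
the risk-difference estimates — the yardstick for whether an estimator
tracks the true sampling variability.

Seeding: replicate r of scenario cell s under master seed M uses the
stream seeded by (M, s, r), so any subset of the grid, run serially or in
parallel, reproduces the same numbers.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed
from scipy.special import expit

from . import __version__ as _pkg_version
from .dgp import (
    COVARIATE_SCENARIOS,
    DEFAULT_ALLOCATION,
    GRID_RISK_DIFFERENCES,
    SELECTION_STRENGTHS,
    CoefficientSet,
    ScenarioSpec,
    augment_controls,
    build_coefficients,
    calibrate_beta,
    calibrate_intercept,
    generate_covariates,
    simulate_cohort,
)
from .inference import infer_risk_difference, paired_table
from .matching import compute_caliper, fit_propensity, greedy_match

logger = logging.getLogger(__name__)

#: entropy tag separating calibration streams from replicate streams
_CALIBRATION_TAG = 999_983

GRID_OUTCOME_PROBS = (0.29, 0.15)


class ScenarioFailure(RuntimeError):
    """Raised when too many replicates of a scenario are invalid."""


@dataclass(frozen=True)
class SignificanceBand:
    """Monte Carlo significance band around a nominal proportion."""

    nominal: float
    n_reps: int
    lower: float
    upper: float

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def mc_significance_bounds(nominal: float, n_reps: int) -> SignificanceBand:
    """Band ``nominal +/- 1.96 sqrt(nominal (1 - nominal) / n_reps)``.

    Empirical rejection or coverage rates outside the band differ
    statistically significantly from the nominal value given the number of
    simulated data sets (e.g. (0.040, 0.060) around 0.05 at 1825
    replicates).
    """
    if not 0.0 < nominal < 1.0:
        raise ValueError("nominal must lie in (0, 1)")
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    half = 1.96 * math.sqrt(nominal * (1.0 - nominal) / n_reps)
    return SignificanceBand(
        nominal=nominal, n_reps=n_reps, lower=nominal - half, upper=nominal + half
    )


@dataclass
class ReplicateRecord:
    """Inference results of a single simulated replicate."""

    rd: float
    se_independent: float
    se_paired: float
    ci_independent_low: float
    ci_independent_high: float
    ci_paired_low: float
    ci_paired_high: float
    p_pearson: float
    p_mcnemar: float
    n_pairs: int
    matched_pct: float
    valid: bool
    reason: str = ""


@dataclass
class ScenarioMetrics:
    """Evaluation metrics of one scenario cell."""

    scenario_index: int
    covariate_scenario: str
    selection_strength: str
    baseline_outcome_prob: float
    target_rd: float
    n_replicates_used: int
    n_invalid: int
    mean_matched_pct: float
    type1_pearson: float
    type1_mcnemar: float
    coverage_independent: float
    coverage_paired: float
    mean_width_independent: float
    mean_width_paired: float
    width_ratio: float
    var_ratio_independent: float
    var_ratio_paired: float


def run_replicate(
    spec: ScenarioSpec,
    coeffs: CoefficientSet,
    seed: int | np.random.SeedSequence,
    caliper_multiplier: float = 0.2,
) -> ReplicateRecord:
    """Simulate, match and analyse one replicate.

    Deterministic given (spec, coeffs, seed).  Replicates with a
    non-convergent propensity fit or an empty matched sample are returned
    flagged invalid rather than raised, so the scenario loop can count and
    exclude them.
    """
    rng = np.random.default_rng(seed)
    cohort = simulate_cohort(spec, coeffs, rng)
    if spec.control_copies:
        cohort = augment_controls(cohort, spec.control_copies, rng)

    invalid = ReplicateRecord(
        rd=np.nan, se_independent=np.nan, se_paired=np.nan,
        ci_independent_low=np.nan, ci_independent_high=np.nan,
        ci_paired_low=np.nan, ci_paired_high=np.nan,
        p_pearson=np.nan, p_mcnemar=np.nan, n_pairs=0,
        matched_pct=np.nan, valid=False,
    )
    fit = fit_propensity(cohort.X, cohort.Z)
    if not fit.converged:
        invalid.reason = "propensity fit did not converge"
        return invalid
    caliper = compute_caliper(fit.logit_ps, cohort.Z, caliper_multiplier)
    matched = greedy_match(fit.logit_ps, cohort.Z, caliper, rng)
    if matched.n_pairs == 0:
        invalid.reason = "empty matched sample"
        invalid.matched_pct = 0.0
        return invalid
    table = paired_table(matched, cohort.Y)
    inf = infer_risk_difference(table)
    return ReplicateRecord(
        rd=inf.rd,
        se_independent=inf.se_independent,
        se_paired=inf.se_paired,
        ci_independent_low=inf.ci_independent[0],
        ci_independent_high=inf.ci_independent[1],
        ci_paired_low=inf.ci_paired[0],
        ci_paired_high=inf.ci_paired[1],
        p_pearson=inf.p_pearson,
        p_mcnemar=inf.p_mcnemar,
        n_pairs=inf.n_pairs,
        matched_pct=matched.matched_pct,
        valid=True,
    )


def _replicate_seed(
    master_seed: int, scenario_index: int, replicate: int
) -> np.random.SeedSequence:
    return np.random.SeedSequence([master_seed, scenario_index, replicate])


def _metrics_from_records(
    spec: ScenarioSpec,
    scenario_index: int,
    records: Sequence[ReplicateRecord],
) -> ScenarioMetrics:
    valid = [r for r in records if r.valid]
    n_invalid = len(records) - len(valid)
    if len(valid) < max(2, len(records) // 2):
        raise ScenarioFailure(
            f"{spec.label}: {n_invalid} of {len(records)} replicates invalid"
        )
    rd = np.array([r.rd for r in valid])
    se_ind = np.array([r.se_independent for r in valid])
    se_pair = np.array([r.se_paired for r in valid])
    width_ind = np.array(
        [r.ci_independent_high - r.ci_independent_low for r in valid]
    )
    width_pair = np.array([r.ci_paired_high - r.ci_paired_low for r in valid])
    cover_ind = np.array(
        [r.ci_independent_low <= spec.target_rd <= r.ci_independent_high
         for r in valid]
    )
    cover_pair = np.array(
        [r.ci_paired_low <= spec.target_rd <= r.ci_paired_high for r in valid]
    )
    emp_sd = rd.std(ddof=1)
    if spec.is_null:
        type1_p = float(np.mean([r.p_pearson < 0.05 for r in valid]))
        type1_m = float(np.mean([r.p_mcnemar < 0.05 for r in valid]))
    else:
        type1_p = type1_m = np.nan
    return ScenarioMetrics(
        scenario_index=scenario_index,
        covariate_scenario=spec.covariate_scenario,
        selection_strength=spec.selection_strength,
        baseline_outcome_prob=spec.baseline_outcome_prob,
        target_rd=spec.target_rd,
        n_replicates_used=len(valid),
        n_invalid=n_invalid,
        mean_matched_pct=float(np.mean([r.matched_pct for r in valid])),
        type1_pearson=type1_p,
        type1_mcnemar=type1_m,
        coverage_independent=float(cover_ind.mean()),
        coverage_paired=float(cover_pair.mean()),
        mean_width_independent=float(width_ind.mean()),
        mean_width_paired=float(width_pair.mean()),
        width_ratio=float(width_ind.mean() / width_pair.mean()),
        var_ratio_independent=float((se_ind.mean() / emp_sd) ** 2),
        var_ratio_paired=float((se_pair.mean() / emp_sd) ** 2),
    )


def run_scenario(
    spec: ScenarioSpec,
    coeffs: CoefficientSet,
    n_replicates: int | None = None,
    master_seed: int = 0,
    scenario_index: int = 0,
    caliper_multiplier: float = 0.2,
    n_jobs: int = 1,
    return_records: bool = False,
):
    """Run all replicates of one scenario cell and compute its metrics.

    Returns the :class:`ScenarioMetrics`, or ``(metrics, records)`` with a
    per-replicate :class:`pandas.DataFrame` when ``return_records`` is set.
    Raises :class:`ScenarioFailure` when more than half the replicates are
    invalid.
    """
    n_reps = spec.n_replicates if n_replicates is None else n_replicates
    seeds = [
        _replicate_seed(master_seed, scenario_index, r) for r in range(n_reps)
    ]
    if n_jobs == 1:
        records = [
            run_replicate(spec, coeffs, s, caliper_multiplier) for s in seeds
        ]
    else:
        records = Parallel(n_jobs=n_jobs)(
            delayed(run_replicate)(spec, coeffs, s, caliper_multiplier)
            for s in seeds
        )
    metrics = _metrics_from_records(spec, scenario_index, records)
    if return_records:
        frame = pd.DataFrame([asdict(r) for r in records])
        frame.insert(0, "replicate", np.arange(n_reps))
        frame.insert(0, "scenario_index", scenario_index)
        return metrics, frame
    return metrics


def _calibrate_family(
    scenario: str,
    strength: str,
    targets: Sequence[tuple[float, float]],
    seed: int,
    m: int,
    allocation: Sequence[str],
    tol: float,
) -> dict[tuple, CoefficientSet]:
    """Calibrate every (outcome prob, target RD) cell of one covariate
    scenario x selection strength family on a shared calibration sample.

    One covariate draw of size ``m`` (from a dedicated calibration stream
    derived from ``seed`` and the family coordinates, so any subset of the
    grid reproduces the same constants) backs all root finds of the family:
    the treatment intercept, one outcome intercept per outcome probability,
    and one treatment coefficient per (probability, RD) pair, each compared
    across candidate values on common random numbers.
    """
    family = (
        COVARIATE_SCENARIOS.index(scenario),
        SELECTION_STRENGTHS.index(strength),
    )
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, _CALIBRATION_TAG, *family])
    )
    base = build_coefficients(strength, allocation)
    X = generate_covariates(scenario, m, rng)
    a_treat = calibrate_intercept(
        0.25, base.slopes, scenario, rng, m=m, tol=tol, X=X
    )
    # one treated draw shared by every beta calibration of the family, so
    # the solved constants do not depend on which cells were requested
    treated_mask = rng.random(X.shape[0]) < expit(a_treat + X @ base.slopes)
    out: dict[tuple, CoefficientSet] = {}
    a_out_cache: dict[float, float] = {}
    for prob, rd in targets:
        if prob not in a_out_cache:
            a_out_cache[prob] = calibrate_intercept(
                prob, base.slopes, scenario, rng, m=m, tol=tol, X=X
            )
        partial = CoefficientSet(
            level_values=base.level_values,
            allocation=base.allocation,
            alpha0_treat=a_treat,
            alpha0_outcome=a_out_cache[prob],
            beta=None,
        )
        beta = calibrate_beta(
            rd, partial, scenario, rng, m=m, tol=tol, X=X,
            treated_mask=treated_mask,
        )
        out[(scenario, strength, prob, rd)] = CoefficientSet(
            level_values=base.level_values,
            allocation=base.allocation,
            alpha0_treat=a_treat,
            alpha0_outcome=a_out_cache[prob],
            beta=beta,
        )
    return out


def calibrate_grid(
    specs: Sequence[ScenarioSpec],
    seed: int = 0,
    m: int = 1_000_000,
    allocation: Sequence[str] = DEFAULT_ALLOCATION,
    tol: float = 1e-4,
) -> dict[tuple, CoefficientSet]:
    """Calibrate every distinct coefficient set needed by ``specs``.

    Cells sharing (covariate scenario, strength, outcome probability,
    target RD) share a calibration; cells in the same covariate x strength
    family additionally share the calibration sample.  The returned
    mapping is keyed by that 4-tuple.
    """
    families: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for spec in specs:
        fam = (spec.covariate_scenario, spec.selection_strength)
        cell = (spec.baseline_outcome_prob, spec.target_rd)
        families.setdefault(fam, [])
        if cell not in families[fam]:
            families[fam].append(cell)
    out: dict[tuple, CoefficientSet] = {}
    for (scenario, strength), targets in families.items():
        logger.info(
            "calibrating %s/%s (%d cells)", strength, scenario, len(targets)
        )
        out.update(
            _calibrate_family(
                scenario, strength, targets, seed, m, allocation, tol
            )
        )
    return out


def calibrate_scenario(
    spec: ScenarioSpec,
    seed: int = 0,
    m: int = 1_000_000,
    allocation: Sequence[str] = DEFAULT_ALLOCATION,
    tol: float = 1e-4,
) -> CoefficientSet:
    """Calibrate intercepts and beta for one scenario cell.

    Equivalent to the family calibration restricted to this cell, so a
    single-cell run and a grid run produce identical constants for the
    same seed.
    """
    out = _calibrate_family(
        spec.covariate_scenario,
        spec.selection_strength,
        [(spec.baseline_outcome_prob, spec.target_rd)],
        seed,
        m,
        allocation,
        tol,
    )
    return out[
        (spec.covariate_scenario, spec.selection_strength,
         spec.baseline_outcome_prob, spec.target_rd)
    ]


def grid_specs(
    preset: str = "full",
    n_replicates: int | None = None,
    weak_n_initial: int | None = None,
) -> list[tuple[int, ScenarioSpec]]:
    """Enumerate scenario cells with their canonical indices.

    Presets:

    ``full``
        all 100 cells at 1825 replicates, weak cohorts of 10 000;
    ``grid-desk``
        all 100 cells at 150 replicates with weak cohorts of 2 500;
    ``null-desk``
        the 20 null cells at 400 replicates, full-size cohorts.

    ``n_replicates`` / ``weak_n_initial`` override the preset values.
    The canonical index orders cells as (strength, outcome probability,
    covariate scenario, risk difference) and is stable across presets, so
    seeds agree between subset and full runs.
    """
    if preset == "full":
        reps, weak_n, null_only = 1825, 10_000, False
    elif preset == "grid-desk":
        reps, weak_n, null_only = 150, 2_500, False
    elif preset == "null-desk":
        reps, weak_n, null_only = 400, 10_000, True
    else:
        raise ValueError(f"unknown preset {preset!r}")
    if n_replicates is not None:
        reps = n_replicates
    if weak_n_initial is not None:
        weak_n = weak_n_initial

    cells = []
    index = 0
    for strength in SELECTION_STRENGTHS:
        for prob in GRID_OUTCOME_PROBS:
            for scenario in COVARIATE_SCENARIOS:
                for rd in GRID_RISK_DIFFERENCES:
                    if not null_only or rd == 0.0:
                        spec = ScenarioSpec(
                            covariate_scenario=scenario,
                            selection_strength=strength,
                            baseline_outcome_prob=prob,
                            target_rd=rd,
                            n_initial=weak_n if strength == "weak" else 1_000,
                            n_replicates=reps,
                        )
                        cells.append((index, spec))
                    index += 1
    return cells


def run_grid(
    cells: Sequence[tuple[int, ScenarioSpec]],
    master_seed: int = 0,
    calib_m: int = 1_000_000,
    allocation: Sequence[str] = DEFAULT_ALLOCATION,
    caliper_multiplier: float = 0.2,
    n_jobs: int = 1,
    progress: bool = False,
) -> list[ScenarioMetrics]:
    """Calibrate and run a list of (index, spec) cells."""
    specs = [spec for _, spec in cells]
    coeff_map = calibrate_grid(
        specs, seed=master_seed, m=calib_m, allocation=allocation
    )
    metrics = []
    for i, (index, spec) in enumerate(cells):
        key = (spec.covariate_scenario, spec.selection_strength,
               spec.baseline_outcome_prob, spec.target_rd)
        if progress:
            print(f"[{i + 1}/{len(cells)}] {spec.label}", flush=True)
        logger.info("running %s (%d replicates)", spec.label, spec.n_replicates)
        metrics.append(
            run_scenario(
                spec,
                coeff_map[key],
                master_seed=master_seed,
                scenario_index=index,
                caliper_multiplier=caliper_multiplier,
                n_jobs=n_jobs,
            )
        )
    return metrics


def metrics_frame(metrics: Iterable[ScenarioMetrics]) -> pd.DataFrame:
    return pd.DataFrame([asdict(m) for m in metrics])


def summarize_grid(metrics: Sequence[ScenarioMetrics]) -> dict[str, pd.DataFrame]:
    """Aggregate per-scenario metrics into the study's summary tables.

    Returns a mapping of table name to DataFrame:

    * ``scenarios`` — one row per cell, all metrics;
    * ``type1`` — null cells only: matched percentage and both empirical
      type I error rates;
    * ``detail`` — coverage, widths, width ratio and variance ratios per
      cell, grouped by (outcome probability, strength) set;
    * ``summary`` — cross-scenario medians and quartiles (linear
      interpolation between order statistics) of coverage, width ratio and
      variance ratios per method, plus counts of cells outside the Monte
      Carlo significance bands.
    """
    if not metrics:
        raise ValueError("no scenario metrics to summarize")
    frame = metrics_frame(metrics)

    type1 = frame[frame.target_rd == 0.0][
        ["scenario_index", "baseline_outcome_prob", "selection_strength",
         "covariate_scenario", "mean_matched_pct", "type1_pearson",
         "type1_mcnemar", "n_replicates_used"]
    ].reset_index(drop=True)

    detail = frame[
        ["scenario_index", "baseline_outcome_prob", "selection_strength",
         "covariate_scenario", "target_rd", "coverage_independent",
         "coverage_paired", "mean_width_independent", "mean_width_paired",
         "width_ratio", "var_ratio_independent", "var_ratio_paired"]
    ].sort_values("scenario_index").reset_index(drop=True)

    def qtiles(col: str) -> dict[str, float]:
        vals = frame[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        return {"metric": col, "q25": q25, "median": q50, "q75": q75}

    rows = [
        qtiles("coverage_independent"),
        qtiles("coverage_paired"),
        qtiles("width_ratio"),
        qtiles("var_ratio_independent"),
        qtiles("var_ratio_paired"),
    ]
    summary = pd.DataFrame(rows)

    n_reps = int(frame.n_replicates_used.median())
    cov_band = mc_significance_bounds(0.95, n_reps)
    counts = {
        "n_scenarios": len(frame),
        "coverage_independent_outside_band": int(
            (~frame.coverage_independent.apply(cov_band.contains)).sum()
        ),
        "coverage_paired_outside_band": int(
            (~frame.coverage_paired.apply(cov_band.contains)).sum()
        ),
    }
    null_frame = frame[frame.target_rd == 0.0]
    if len(null_frame):
        t1_band = mc_significance_bounds(0.05, n_reps)
        counts["type1_pearson_outside_band"] = int(
            (~null_frame.type1_pearson.apply(t1_band.contains)).sum()
        )
        counts["type1_mcnemar_outside_band"] = int(
            (~null_frame.type1_mcnemar.apply(t1_band.contains)).sum()
        )
    bands = pd.DataFrame([counts])

    return {
        "scenarios": frame,
        "type1": type1,
        "detail": detail,
        "summary": summary,
        "band_counts": bands,
    }


def write_tables(
    summary: Mapping[str, pd.DataFrame],
    path: str | Path,
    manifest: Mapping | None = None,
) -> list[Path]:
    """Write each summary table as CSV plus a JSON run manifest."""
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in summary.items():
        target = outdir / f"{name}.csv"
        frame.to_csv(target, index=False)
        written.append(target)
    manifest = dict(manifest or {})
    manifest.setdefault("package_version", _pkg_version)
    target = outdir / "manifest.json"
    with open(target, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    written.append(target)
    return written


def coefficients_table(
    coeff_map: Mapping[tuple, CoefficientSet]
) -> pd.DataFrame:
    """Serialize calibrated coefficient sets to a human-readable table."""
    rows = []
    for (scenario, strength, prob, rd), c in sorted(coeff_map.items()):
        rows.append(
            {
                "covariate_scenario": scenario,
                "selection_strength": strength,
                "baseline_outcome_prob": prob,
                "target_rd": rd,
                "alpha0_treat": c.alpha0_treat,
                "alpha0_outcome": c.alpha0_outcome,
                "beta": c.beta,
                "allocation": "".join(
                    {"L": "L", "M": "M", "H": "H", "VH": "V"}[a]
                    for a in c.allocation
                ),
            }
        )
    return pd.DataFrame(rows)


def load_config(path: str | Path) -> dict:
    """Read a YAML run configuration.

    Recognised keys: ``preset``, ``master_seed``, ``n_replicates``,
    ``weak_n_initial``, ``calib_m``, ``caliper_multiplier``,
    ``allocation`` (list of 10 level labels), and ``scenarios`` (explicit
    list of cell mappings overriding the preset grid).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "scenarios" in cfg:
        cells = []
        for i, entry in enumerate(cfg["scenarios"]):
            index = entry.pop("scenario_index", i)
            cells.append((index, ScenarioSpec(**entry)))
        cfg["cells"] = cells
    return cfg
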