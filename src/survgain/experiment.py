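"""Monte Carlo study driver.

One *scenario* fixes a heterogeneity level, cohort size, treated proportion,
censoring rate, matching method and its k (or number of bootstrap resamples
b). One *iteration* simulates a fresh cohort, fits the PS model on X3..X10,
builds matched sets, estimates per-treated-unit survival gain and variance,
and reduces them to scalar metrics:

* mean STE  — mean estimated survival gain over labelable treated units;
* mean STE variance — mean estimated variance V_i over units where defined;
* var(V^s)  — variance of the V_i across treated units within the iteration;
* proportion of labels censored — fraction of treated units whose response
  label is undetermined;
* delta_var / V — relative difference between the true variance of the
  simulated survival gain and the mean estimated STE variance.

Scenario metrics are averaged over iterations (default test profile: 200
iterations of n = 1000 patients; the full study profile is 1000 iterations).
Seeds derive from (base_seed, scenario key, iteration) via SeedSequence, so
adding scenarios to a grid never perturbs existing ones.

The three factor sweeps vary (1) the proportion treated with no censoring,
(2) the censoring rate at 20% treated, and (3) k at 20% treated and 20%
censored; k = 15 is held where k is not the swept factor.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .dgp import (
    LEVELS,
    Cohort,
    make_scenario,
    calibrate_intercept,
    simulate_cohort,
    truth_summary,
)
from .errors import ConfigError, PSFitError, MatchingError
from .estimation import Label, SubjectEstimate, estimate_all
from .matching import bootstrap_match, exp_weights, nn_match
from .propensity import DEFAULT_PS_COVARIATES, fit_ps

__all__ = [
    "METHODS",
    "ScenarioConfig",
    "IterationResult",
    "run_iteration",
    "iteration_metrics",
    "summarize",
    "run_scenario",
    "run_sweep",
    "run_grid",
    "default_grids",
]

METHODS = ("one_by_one", "knn", "weighted_knn", "bootstrap")

_MAX_REDRAWS = 10


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the Monte Carlo design."""

    heterogeneity: str = "medium"
    n_patients: int = 1000
    prop_treated: float = 0.2
    p_censor: float = 0.2
    method: str = "knn"
    k_or_b: int = 15
    alpha: float = 5.0
    threshold_months: float = 3.0
    n_iterations: int = 1000
    base_seed: int = 0
    n_calib: int = 100_000
    covariate_dist: str = "normal"

    def __post_init__(self):
        if self.heterogeneity not in LEVELS:
            raise ConfigError(f"unknown heterogeneity {self.heterogeneity!r}")
        if self.method not in METHODS:
            raise ConfigError(f"unknown method {self.method!r}; expected {METHODS}")
        if not (0.0 < self.prop_treated < 1.0):
            raise ConfigError("prop_treated must lie in (0, 1)")
        if not (0.0 <= self.p_censor < 1.0):
            raise ConfigError("p_censor must lie in [0, 1)")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if self.k_or_b < 1:
            raise ConfigError("k_or_b must be >= 1")

    @property
    def key(self) -> str:
        """Stable scenario identifier used for seed derivation."""
        return (
            f"{self.heterogeneity}|{self.method}|n={self.n_patients}"
            f"|pt={self.prop_treated}|pc={self.p_censor}|k={self.k_or_b}"
            f"|a={self.alpha}|thr={self.threshold_months}"
        )


@dataclass(frozen=True)
class IterationResult:
    """Scalar metrics of one Monte Carlo iteration."""

    mean_ste: float | None  # months
    mean_ste_var: float | None  # months^2
    var_of_ste_var: float | None  # months^4, across treated units
    prop_labels_censored: float
    true_ate: float  # months
    true_variance: float  # months^2
    delta_var_rel: float | None  # (V - mean V^s) / V
    n_treated: int
    n_labelable: int
    n_var_defined: int
    n_redraws: int = 0


@lru_cache(maxsize=None)
def _calibrated_intercept(
    level: str, target: float, n_calib: int, calib_seed: int, dist: str
) -> float:
    scenario = make_scenario(level)
    return calibrate_intercept(
        scenario, target, n_calib=n_calib, seed=calib_seed, dist=dist
    )


def _calib_seed(config: ScenarioConfig) -> int:
    # one calibration sample per (base_seed, level, target); < 2**31
    key = f"calib|{config.heterogeneity}|{config.prop_treated}|{config.base_seed}"
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def _build_matched_sets(config: ScenarioConfig, cohort: Cohort, ps_fit, rng):
    t_idx, c_idx = cohort.treated_idx, cohort.control_idx
    if config.method == "bootstrap":
        return bootstrap_match(cohort, config.k_or_b, rng)
    k = 1 if config.method == "one_by_one" else config.k_or_b
    sets = nn_match(
        ps_fit.ps_hat[t_idx],
        ps_fit.ps_hat[c_idx],
        k,
        treated_ids=t_idx,
        control_ids=c_idx,
    )
    if config.method == "weighted_knn":
        for s in sets:
            s.weights = exp_weights(s.distances, config.alpha)
    return sets


def iteration_metrics(
    estimates: list[SubjectEstimate], true_ate: float, true_variance: float
) -> IterationResult:
    """Reduce per-treated-unit estimates to the iteration's scalar metrics."""
    sg = np.array([e.sg_hat for e in estimates if e.sg_hat is not None], float)
    v = np.array([e.v_hat for e in estimates if e.v_hat is not None], float)
    n_undet = sum(1 for e in estimates if e.label is Label.UNDETERMINED)
    mean_ste = float(sg.mean()) if sg.size else None
    mean_v = float(v.mean()) if v.size else None
    var_v = float(np.var(v, ddof=1)) if v.size >= 2 else None
    delta = (
        (true_variance - mean_v) / true_variance
        if (mean_v is not None and true_variance > 0)
        else None
    )
    return IterationResult(
        mean_ste=mean_ste,
        mean_ste_var=mean_v,
        var_of_ste_var=var_v,
        prop_labels_censored=n_undet / len(estimates) if estimates else 0.0,
        true_ate=true_ate,
        true_variance=true_variance,
        delta_var_rel=delta,
        n_treated=len(estimates),
        n_labelable=int(sg.size),
        n_var_defined=int(v.size),
    )


def run_iteration(config: ScenarioConfig, iteration_seed) -> IterationResult:
    """One Monte Carlo iteration: simulate, fit PS, match, estimate, reduce.

    Degenerate draws (too few treated/controls, PS non-convergence) are
    redrawn from spawned seeds, at most 10 times, and counted in
    ``n_redraws``.
    """
    ss = (
        iteration_seed
        if isinstance(iteration_seed, np.random.SeedSequence)
        else np.random.SeedSequence(iteration_seed)
    )
    scenario = make_scenario(config.heterogeneity).with_intercept(
        _calibrated_intercept(
            config.heterogeneity,
            config.prop_treated,
            config.n_calib,
            _calib_seed(config),
            config.covariate_dist,
        )
    )
    k_needed = 1 if config.method in ("one_by_one", "bootstrap") else config.k_or_b
    last_err: Exception | None = None
    children = ss.spawn(_MAX_REDRAWS + 1)
    for redraw, child in enumerate(children):
        s_cohort, s_match = child.spawn(2)
        cohort = simulate_cohort(
            scenario,
            n=config.n_patients,
            p_censor=config.p_censor,
            seed=s_cohort,
            dist=config.covariate_dist,
        )
        if cohort.treated_idx.size < 2 or cohort.control_idx.size < max(2, k_needed):
            last_err = MatchingError("degenerate treatment split")
            continue
        try:
            ps_fit = fit_ps(cohort, DEFAULT_PS_COVARIATES)
            sets = _build_matched_sets(
                config, cohort, ps_fit, np.random.default_rng(s_match)
            )
        except (PSFitError, MatchingError) as exc:
            last_err = exc
            continue
        truth = truth_summary(cohort)
        variance_mode = "one_by_one_crude" if config.method == "one_by_one" else "knn"
        estimates = estimate_all(
            cohort, sets, threshold=config.threshold_months, variance_mode=variance_mode
        )
        result = iteration_metrics(estimates, truth.true_ate, truth.true_variance)
        return replace(result, n_redraws=redraw)
    raise MatchingError(
        f"iteration failed after {_MAX_REDRAWS} redraws: {last_err}"
    )


_METRIC_FIELDS = (
    "mean_ste",
    "mean_ste_var",
    "var_of_ste_var",
    "prop_labels_censored",
    "true_ate",
    "true_variance",
    "delta_var_rel",
)


def summarize(results: list[IterationResult]) -> dict:
    """Across-iteration means and Monte Carlo standard errors.

    Undefined per-iteration values are ignored, with the number of
    contributing iterations reported per metric; an all-undefined metric is
    reported as missing (NaN), never as zero. Also reports the
    across-iteration variance of the per-iteration mean STE variance as
    ``between_iter_var_of_mean_v`` (the alternative reading of var(V^s)).
    """
    if not results:
        raise ConfigError("cannot summarize an empty result list")
    out: dict = {"n_iterations": len(results)}
    for name in _METRIC_FIELDS:
        vals = np.array(
            [getattr(r, name) for r in results if getattr(r, name) is not None], float
        )
        if vals.size == 0:
            out[name] = np.nan
            out[f"{name}_se"] = np.nan
            out[f"{name}_n"] = 0
            continue
        out[name] = float(vals.mean())
        out[f"{name}_se"] = (
            float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        )
        out[f"{name}_n"] = int(vals.size)
    mv = np.array(
        [r.mean_ste_var for r in results if r.mean_ste_var is not None], float
    )
    out["between_iter_var_of_mean_v"] = (
        float(np.var(mv, ddof=1)) if mv.size >= 2 else np.nan
    )
    out["total_redraws"] = int(sum(r.n_redraws for r in results))
    return out


def iteration_seed(config: ScenarioConfig, i: int) -> np.random.SeedSequence:
    """Counter-based seed stream: (base_seed, crc32(scenario key), iteration)."""
    stream = zlib.crc32(config.key.encode()) & 0x7FFFFFFF
    return np.random.SeedSequence([config.base_seed, stream, i])


def run_scenario(config: ScenarioConfig) -> tuple[dict, list[IterationResult]]:
    """All iterations of one scenario, reduced to a summary row."""
    results = [
        run_iteration(config, iteration_seed(config, i))
        for i in range(config.n_iterations)
    ]
    return summarize(results), results


def default_grids() -> dict:
    """Default factor grids for the three sweeps (overridable via config)."""
    return {
        "prop_treated": [0.05, 0.10, 0.20, 0.30, 0.40, 0.50],
        "p_censor": [0.0, 0.10, 0.20, 0.30, 0.40, 0.50],
        "k": [1, 2, 5, 10, 15, 25, 50],
    }


_SWEEP_FIXED = {
    # swept factor -> fixed settings for the other two factors
    "prop_treated": {"p_censor": 0.0, "k_or_b": 15},
    "p_censor": {"prop_treated": 0.2, "k_or_b": 15},
    "k": {"prop_treated": 0.2, "p_censor": 0.2},
}


def run_sweep(
    sweep: str,
    values,
    levels=LEVELS,
    methods=METHODS,
    base_config: ScenarioConfig | None = None,
) -> pd.DataFrame:
    """One factor sweep: every value x heterogeneity level x method.

    ``sweep`` is 'prop_treated', 'p_censor' or 'k'; the other two factors are
    held at the study's design point (20% treated, 20% censored, k = 15).
    Returns one tidy row per cell with metric means and MC standard errors.
    """
    if sweep not in _SWEEP_FIXED:
        raise ConfigError(f"unknown sweep {sweep!r}; expected {tuple(_SWEEP_FIXED)}")
    base = base_config or ScenarioConfig()
    rows = []
    for level in levels:
        for method in methods:
            for value in values:
                overrides = dict(_SWEEP_FIXED[sweep])
                if sweep == "k":
                    overrides["k_or_b"] = int(value)
                else:
                    overrides[sweep] = float(value)
                config = replace(
                    base, heterogeneity=level, method=method, **overrides
                )
                summary, _ = run_scenario(config)
                row = {
                    "sweep": sweep,
                    "swept_value": value,
                    "heterogeneity": level,
                    "method": method,
                    "n_patients": config.n_patients,
                    "prop_treated": config.prop_treated,
                    "p_censor": config.p_censor,
                    "k_or_b": config.k_or_b,
                    "alpha": config.alpha,
                    "threshold_months": config.threshold_months,
                    "base_seed": config.base_seed,
                }
                row.update(summary)
                rows.append(row)
    return pd.DataFrame(rows)


def run_grid(
    grids: dict | None = None,
    levels=LEVELS,
    methods=METHODS,
    base_config: ScenarioConfig | None = None,
) -> pd.DataFrame:
    """All three factor sweeps concatenated into one tidy table."""
    grids = grids or default_grids()
    if not grids:
        raise ConfigError("empty sweep grid")
    frames = [
        run_sweep(sweep, values, levels=levels, methods=methods, base_config=base_config)
        for sweep, values in grids.items()
    ]
    return pd.concat(frames, ignore_index=True)
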