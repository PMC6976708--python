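"""Synthetic oncology cohort generation.

Implements the data-generating process of the Monte Carlo study: 1000
patients with ten standard-normal baseline covariates X1..X10, of which
X1..X7 drive treatment selection through a logistic model and X4..X10 drive
overall survival (OS) through a Weibull proportional-hazards model. Three
coefficient patterns encode low/medium/high patient heterogeneity, built
from five effect sizes (odds / hazard ratios 1.25, 1.5, 2, 4, 8). Treatment
is Bernoulli on the true propensity; OS is drawn by inverse-probability
transform

    OS = ( -log(u) / (lambda * exp(LP)) )^(1/2),   lambda = 2e-5,

with a single uniform draw ``u`` shared between the two treatment arms, so
each subject carries a pair of potential outcomes (OS1, OS0) and a true
subject-specific survival gain SG = OS1 - OS0. The conditional hazard ratio
of treatment is fixed at 0.8, hence OS1/OS0 = 0.8^(-1/2) exactly for every
subject. Censoring is an independent Bernoulli(p*) status flag: the recorded
OS is then a lower bound on true survival, never a truncated time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import CalibrationError, ConfigError, DataError

__all__ = [
    "WEIBULL_SCALE",
    "LOG_HR_TREAT",
    "LEVELS",
    "HeterogeneityScenario",
    "Cohort",
    "TruthSummary",
    "make_scenario",
    "generate_covariates",
    "calibrate_intercept",
    "assign_treatment",
    "weibull_os",
    "generate_survival",
    "apply_censoring",
    "truth_summary",
    "simulate_cohort",
]

#: Weibull scale parameter of the survival model (per month^2 hazard scale).
WEIBULL_SCALE = 2.0e-5

#: Log conditional hazard ratio of treatment, exp(beta) = 0.8 in all scenarios.
LOG_HR_TREAT = math.log(0.8)

LEVELS = ("low", "medium", "high")

# Effect-size ladder: very weak .. very strong (log odds / log hazard ratios).
_VW = math.log(1.25)
_W = math.log(1.5)
_M = math.log(2.0)
_S = math.log(4.0)
_VS = math.log(8.0)

# Treatment-selection coefficients on X1..X7 per heterogeneity level.
_TREAT_COEFFS = {
    "low": (_VW, _W, _VW, _W, _VW, _W, _M),
    "medium": (_W, _M, _S, _W, _M, _S, _VS),
    "high": (_M, _S, _M, _S, _M, _S, _VS),
}

# Survival linear-predictor coefficients on X4..X10 per heterogeneity level.
_OUTCOME_COEFFS = {
    "low": (_W, _VW, _W, _M, _VW, _W, _VW),
    "medium": (_W, _M, _S, _VS, _W, _M, _S),
    "high": (_S, _M, _S, _VS, _M, _S, _M),
}

_COHORT_COLUMNS = ["id", "z", "os_months", "censored"]
_TRUTH_COLUMNS = ["os1", "os0", "sg_true", "ps_true"]
_X_COLUMNS = [f"x{i}" for i in range(1, 11)]


def _as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class HeterogeneityScenario:
    """Coefficient pattern for one heterogeneity level.

    ``treat_coeffs`` are the 7 log-odds coefficients on X1..X7 in the
    treatment-selection logit; ``outcome_coeffs`` are the 7 log-hazard
    coefficients on X4..X10 in the survival linear predictor.
    """

    level: str
    treat_coeffs: tuple[float, ...]
    outcome_coeffs: tuple[float, ...]
    treat_intercept: float = 0.0
    beta_treat: float = LOG_HR_TREAT

    def with_intercept(self, intercept: float) -> "HeterogeneityScenario":
        return replace(self, treat_intercept=float(intercept))


@dataclass
class Cohort:
    """A (simulated or real) patient cohort.

    ``X`` is the n x 10 covariate matrix; ``Z`` the treatment flag; ``OS_obs``
    the recorded overall survival in months; ``censored`` the censoring status
    (1 = censored, i.e. OS_obs is a lower bound on true survival). Simulated
    cohorts additionally carry the true propensity and both potential
    outcomes; real cohorts leave those as None.
    """

    X: np.ndarray
    Z: np.ndarray
    OS_obs: np.ndarray
    censored: np.ndarray
    p_true: np.ndarray | None = None
    OS1: np.ndarray | None = None
    OS0: np.ndarray | None = None
    SG_true: np.ndarray | None = None
    ids: np.ndarray | None = None
    weibull_scale: float = WEIBULL_SCALE

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DataError("covariate matrix X must be 2-dimensional")
        n = self.X.shape[0]
        self.Z = np.asarray(self.Z, dtype=int)
        self.OS_obs = np.asarray(self.OS_obs, dtype=float)
        self.censored = np.asarray(self.censored, dtype=int)
        for name in ("Z", "OS_obs", "censored"):
            if getattr(self, name).shape != (n,):
                raise DataError(f"cohort field {name} has wrong length")
        if self.ids is None:
            self.ids = np.arange(n)
        else:
            self.ids = np.asarray(self.ids)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def treated_idx(self) -> np.ndarray:
        return np.flatnonzero(self.Z == 1)

    @property
    def control_idx(self) -> np.ndarray:
        return np.flatnonzero(self.Z == 0)

    def covariate_matrix(self, names: list[str]) -> np.ndarray:
        """Columns of X selected by name ('x1'..'x10')."""
        cols = []
        for name in names:
            if name not in _X_COLUMNS:
                raise DataError(f"unknown covariate name: {name!r}")
            cols.append(int(name[1:]) - 1)
        return self.X[:, cols]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "z": self.Z,
                "os_months": self.OS_obs,
                "censored": self.censored,
            }
        )
        if self.OS1 is not None:
            df["os1"] = self.OS1
            df["os0"] = self.OS0
            df["sg_true"] = self.SG_true
        if self.p_true is not None:
            df["ps_true"] = self.p_true
        for j, name in enumerate(_X_COLUMNS):
            df[name] = self.X[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        missing = [c for c in _COHORT_COLUMNS + _X_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"cohort table missing required columns: {missing}")
        X = df[_X_COLUMNS].to_numpy(dtype=float)
        kwargs = {}
        if all(c in df.columns for c in ("os1", "os0", "sg_true")):
            kwargs.update(
                OS1=df["os1"].to_numpy(float),
                OS0=df["os0"].to_numpy(float),
                SG_true=df["sg_true"].to_numpy(float),
            )
        if "ps_true" in df.columns:
            kwargs["p_true"] = df["ps_true"].to_numpy(float)
        return cls(
            X=X,
            Z=df["z"].to_numpy(int),
            OS_obs=df["os_months"].to_numpy(float),
            censored=df["censored"].to_numpy(int),
            ids=df["id"].to_numpy(),
            **kwargs,
        )

    def to_csv(self, path) -> None:
        # %.17g round-trips IEEE doubles exactly
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


@dataclass(frozen=True)
class TruthSummary:
    """Mean and sample variance of the true survival gain over treated subjects."""

    true_ate: float  # months
    true_variance: float  # months^2
    n_treated: int


def make_scenario(level: str) -> HeterogeneityScenario:
    """Return the coefficient pattern for a heterogeneity level.

    The treatment intercept defaults to 0 and is set separately (see
    :func:`calibrate_intercept`); the log conditional hazard ratio of
    treatment is log(0.8) in every scenario.
    """
    if level not in LEVELS:
        raise ConfigError(
            f"unknown heterogeneity level {level!r}; expected one of {LEVELS}"
        )
    return HeterogeneityScenario(
        level=level,
        treat_coeffs=_TREAT_COEFFS[level],
        outcome_coeffs=_OUTCOME_COEFFS[level],
    )


def generate_covariates(n: int, seed, dist: str = "normal") -> np.ndarray:
    """Draw the n x 10 baseline covariate matrix.

    Columns are independent standard normal by default; ``dist='bernoulli'``
    switches to Bernoulli(0.5) covariates.
    """
    if n <= 0:
        raise DataError(f"need n >= 1 patients, got {n}")
    rng = _as_rng(seed)
    if dist == "normal":
        return rng.standard_normal((n, 10))
    if dist == "bernoulli":
        return rng.integers(0, 2, size=(n, 10)).astype(float)
    raise ConfigError(f"unknown covariate distribution {dist!r}")


def _treat_lp(X: np.ndarray, scenario: HeterogeneityScenario) -> np.ndarray:
    return X[:, :7] @ np.asarray(scenario.treat_coeffs)


def calibrate_intercept(
    scenario: HeterogeneityScenario,
    target_treated_prop: float,
    n_calib: int = 100_000,
    seed=0,
    tol: float = 0.002,
    bracket: tuple[float, float] = (-30.0, 30.0),
    dist: str = "normal",
) -> float:
    """Find the treatment-model intercept hitting a target treated proportion.

    Bisection on the intercept of the selection logit, using one fixed
    calibration sample of ``n_calib`` covariate draws reused across bisection
    steps; stops when the Monte Carlo mean propensity is within ``tol`` of the
    target.
    """
    if not (0.0 < target_treated_prop < 1.0):
        raise ConfigError(
            "target treated proportion must lie in the open interval (0, 1), "
            f"got {target_treated_prop}"
        )
    X = generate_covariates(n_calib, seed, dist=dist)
    lp = _treat_lp(X, scenario)

    def mean_prop(a: float) -> float:
        return float(np.mean(expit(a + lp)))

    lo, hi = bracket
    f_lo = mean_prop(lo) - target_treated_prop
    f_hi = mean_prop(hi) - target_treated_prop
    if not (f_lo < 0.0 < f_hi):
        raise CalibrationError(
            f"target proportion {target_treated_prop} not bracketed on {bracket}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = mean_prop(mid) - target_treated_prop
        if abs(f_mid) <= tol or (hi - lo) < 1e-12:
            return mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def assign_treatment(
    X: np.ndarray, scenario: HeterogeneityScenario, seed
) -> tuple[np.ndarray, np.ndarray]:
    """True propensity p_i = expit(intercept + X[:, :7] @ coeffs) and Z ~ Bernoulli(p_i)."""
    rng = _as_rng(seed)
    p_true = expit(scenario.treat_intercept + _treat_lp(X, scenario))
    Z = (rng.random(X.shape[0]) < p_true).astype(int)
    return p_true, Z


def weibull_os(u, lp, scale: float = WEIBULL_SCALE):
    """Inverse-probability transform OS = sqrt(-log(u) / (scale * exp(lp))).

    Monotone decreasing in both ``u`` (at fixed ``lp``) and ``lp`` (at fixed
    ``u``); shape-2 Weibull, so proportional hazards hold exactly.
    """
    return np.sqrt(-np.log(u) / (scale * np.exp(lp)))


def generate_survival(
    X: np.ndarray,
    Z: np.ndarray,
    scenario: HeterogeneityScenario,
    seed,
    scale: float = WEIBULL_SCALE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Potential outcomes (OS1, OS0), the factual OS, and the true survival gain.

    One uniform draw per subject is shared between both arms (common random
    numbers), which makes the per-subject counterfactual contrast exact:
    OS1/OS0 = exp(-beta_treat / 2) for every subject.
    """
    rng = _as_rng(seed)
    n = X.shape[0]
    u = rng.random(n)
    while np.any(u == 0.0):  # open-interval sampler: u = 0 would give OS = inf
        bad = u == 0.0
        u[bad] = rng.random(int(bad.sum()))
    lp_base = X[:, 3:10] @ np.asarray(scenario.outcome_coeffs)
    OS1 = weibull_os(u, scenario.beta_treat + lp_base, scale)
    OS0 = weibull_os(u, lp_base, scale)
    OS_obs = np.where(Z == 1, OS1, OS0)
    SG_true = OS1 - OS0
    return OS1, OS0, OS_obs, SG_true


def apply_censoring(n: int, p_star: float, seed) -> np.ndarray:
    """Independent Bernoulli(p*) censoring status flags (1 = censored)."""
    if not (0.0 <= p_star <= 1.0):
        raise DataError(f"censoring probability must lie in [0, 1], got {p_star}")
    rng = _as_rng(seed)
    return (rng.random(n) < p_star).astype(int)


def truth_summary(cohort: Cohort) -> TruthSummary:
    """True ATE (mean SG over treated) and true variance (sample variance of SG over treated)."""
    if cohort.SG_true is None:
        raise DataError("cohort has no true survival gain (real cohort?)")
    sg = cohort.SG_true[cohort.treated_idx]
    if sg.size < 2:
        raise DataError(f"need at least 2 treated subjects, got {sg.size}")
    return TruthSummary(
        true_ate=float(np.mean(sg)),
        true_variance=float(np.var(sg, ddof=1)),
        n_treated=int(sg.size),
    )


def simulate_cohort(
    scenario: HeterogeneityScenario,
    n: int = 1000,
    p_censor: float = 0.0,
    seed=0,
    dist: str = "normal",
) -> Cohort:
    """Generate one full cohort (covariates, treatment, survival, censoring).

    The seed is split into independent streams for each generation step, so
    identical seeds yield bit-identical cohorts.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_cov, s_treat, s_surv, s_cens = ss.spawn(4)
    X = generate_covariates(n, np.random.default_rng(s_cov), dist=dist)
    p_true, Z = assign_treatment(X, scenario, np.random.default_rng(s_treat))
    OS1, OS0, OS_obs, SG_true = generate_survival(
        X, Z, scenario, np.random.default_rng(s_surv)
    )
    censored = apply_censoring(n, p_censor, np.random.default_rng(s_cens))
    return Cohort(
        X=X,
        Z=Z,
        OS_obs=OS_obs,
        censored=censored,
        p_true=p_true,
        OS1=OS1,
        OS0=OS0,
        SG_true=SG_true,
    )
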