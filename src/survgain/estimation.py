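"""Subject-specific survival gain, its variance, and the response label.

For a treated unit i with matched control multiset C(i) and weights w_ij,

    SG_i = OS_i^T - sum_{j in C(i)} w_ij OS_j^C

is the estimated subject-specific survival gain (STE), in months. A unit is
labelled ``response`` when SG_i >= lambda, a clinical threshold in months
(default 3.0), and ``non_response`` otherwise.

Censoring makes both quantities only partially identified: a censored OS is
a lower bound on true survival. The label logic treats censored values
accordingly:

(a) treated and every matched control censored — nothing can be said:
    ``undetermined``;
(b) some (not all) controls censored — the censored controls are dropped and
    the weights renormalized over the observed ones;
(c) every control censored but the treated observed — the control mean can
    only grow, so SG computed from the censored values is an upper bound on
    the true SG; it is conclusive only when small: SG >= lambda is
    ``undetermined``, SG < lambda is a safe ``non_response``;
(d) treated censored but SG (over observed controls) already >= lambda — the
    true SG is even larger: ``response``; with SG < lambda nothing can be
    concluded: ``undetermined``;
(e) no relevant censoring — plain threshold comparison.

The STE variance is

    V_i = sum_{j retained} w_ij^2 * s^2_{C(i)}          (k-NN mode)

with s^2 the sample variance of the retained matched controls' OS, or, for
one-by-one matching where a within-set variance is not available, the crude
estimate s^2 over the whole control group (``one_by_one_crude`` mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .dgp import Cohort
from .errors import DataError
from .matching import MatchedSet

__all__ = [
    "Label",
    "LabelRuleInput",
    "LabelDecision",
    "SubjectEstimate",
    "estimate_sg",
    "classify_label",
    "estimate_variance",
    "estimate_all",
    "estimates_to_frame",
]

DEFAULT_THRESHOLD_MONTHS = 3.0


class Label(str, Enum):
    RESPONSE = "response"
    NON_RESPONSE = "non_response"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class LabelRuleInput:
    """Inputs to the censoring-aware labelling rule for one treated unit."""

    treated_os: float
    treated_censored: bool
    control_os: np.ndarray
    control_censored: np.ndarray
    weights: np.ndarray
    threshold: float = DEFAULT_THRESHOLD_MONTHS

    def __post_init__(self):
        object.__setattr__(self, "control_os", np.asarray(self.control_os, float))
        object.__setattr__(
            self, "control_censored", np.asarray(self.control_censored, bool)
        )
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        k = self.control_os.size
        if k == 0:
            raise DataError("matched control set is empty")
        if self.control_censored.size != k or self.weights.size != k:
            raise DataError("control vectors must have equal length")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise DataError("match weights must sum to 1")


@dataclass(frozen=True)
class LabelDecision:
    """Outcome of the labelling rule.

    ``sg_hat`` is None exactly when the label is undetermined. ``used_mask``
    marks the controls contributing to the SG estimate. ``kappa_defined`` is
    False in the two cases where the control contribution itself is
    unusable (all-censored set with treated censored, or with SG >= lambda),
    in which case no variance can be computed either.
    """

    label: Label
    sg_hat: float | None
    used_mask: np.ndarray
    kappa_defined: bool


def estimate_sg(matched: MatchedSet, os: np.ndarray) -> float:
    """Weighted survival-gain estimate OS_T - sum_j w_j OS_j over the matched set."""
    os = np.asarray(os, dtype=float)
    if matched.weights.size != matched.control_ids.size:
        raise DataError("weight / control length mismatch")
    return float(os[matched.treated_id] - matched.weights @ os[matched.control_ids])


def _weighted_sg(t_os: float, c_os: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    return float(t_os - w @ c_os)


def classify_label(inp: LabelRuleInput) -> LabelDecision:
    """Censoring-aware binary response label for one treated unit.

    Implements rules (a)-(e) of the module docstring. Ties at exactly the
    threshold count as response. Zero-weight controls cannot contribute to
    the weighted mean, so they are transparent to the rule: dropping one
    changes neither the label nor any estimate.
    """
    zeros = np.zeros(inp.control_os.size, dtype=bool)
    pos = np.flatnonzero(inp.weights > 0)
    if pos.size == 0:
        raise DataError("matched set has no positive-weight control")
    c_os = inp.control_os[pos]
    c_cens = inp.control_censored[pos]
    w = inp.weights[pos]
    obs = ~c_cens

    def mask_of(sub: np.ndarray) -> np.ndarray:
        m = zeros.copy()
        m[pos[sub]] = True
        return m

    if inp.treated_censored and not obs.any():  # (a)
        return LabelDecision(Label.UNDETERMINED, None, zeros, kappa_defined=False)

    if not inp.treated_censored:
        if obs.any():  # (b) then (e): drop censored controls, renormalize
            sg = _weighted_sg(inp.treated_os, c_os[obs], w[obs])
            label = Label.RESPONSE if sg >= inp.threshold else Label.NON_RESPONSE
            return LabelDecision(label, sg, mask_of(obs), kappa_defined=True)
        # (c): all controls censored, treated observed; the censored values
        # understate control survival, so only a small SG is conclusive
        sg = _weighted_sg(inp.treated_os, c_os, w)
        if sg >= inp.threshold:
            return LabelDecision(Label.UNDETERMINED, None, zeros, kappa_defined=False)
        return LabelDecision(
            Label.NON_RESPONSE, sg, mask_of(np.ones(pos.size, bool)), kappa_defined=True
        )

    # (d): treated censored, some controls observed; the treated OS
    # understates true survival, so only a large SG is conclusive
    sg = _weighted_sg(inp.treated_os, c_os[obs], w[obs])
    if sg >= inp.threshold:
        return LabelDecision(Label.RESPONSE, sg, mask_of(obs), kappa_defined=True)
    return LabelDecision(Label.UNDETERMINED, None, mask_of(obs), kappa_defined=True)


def estimate_variance(
    matched: MatchedSet,
    os: np.ndarray,
    used_mask: np.ndarray,
    mode: str = "knn",
    full_control_os: np.ndarray | None = None,
) -> float | None:
    """STE variance estimate, or None when it is undefined.

    ``knn`` mode: sum over retained controls of w^2 times the within-set
    sample variance of the retained controls' OS (weights renormalized over
    the retained controls); undefined with fewer than 2 retained controls.
    ``one_by_one_crude`` mode: sample variance of the full control group's OS.
    """
    if mode == "one_by_one_crude":
        if full_control_os is None:
            raise DataError("crude variance mode needs the full control OS vector")
        full_control_os = np.asarray(full_control_os, float)
        if full_control_os.size < 2:
            return None
        return float(np.var(full_control_os, ddof=1))
    if mode != "knn":
        raise DataError(f"unknown variance mode {mode!r}")
    used_mask = np.asarray(used_mask, bool)
    if used_mask.sum() < 2:
        return None
    os = np.asarray(os, float)
    w = matched.weights[used_mask]
    w = w / w.sum()
    vals = os[matched.control_ids[used_mask]]
    s2 = float(np.var(vals, ddof=1))
    return float(np.sum(w**2) * s2)


@dataclass(frozen=True)
class SubjectEstimate:
    """Per-treated-unit estimate: survival gain, its variance, and the label."""

    treated_id: int
    sg_hat: float | None
    v_hat: float | None
    label: Label
    n_controls_used: int


def estimate_all(
    cohort: Cohort,
    matched_sets: list[MatchedSet],
    threshold: float = DEFAULT_THRESHOLD_MONTHS,
    variance_mode: str = "knn",
) -> list[SubjectEstimate]:
    """Apply SG estimation, labelling, and variance estimation per treated unit.

    The controls retained by the labelling rule feed the variance estimate;
    when the control contribution is unusable (kappa undefined) the variance
    is undefined as well.
    """
    os = cohort.OS_obs
    cens = cohort.censored.astype(bool)
    full_control_os = os[cohort.control_idx]
    out = []
    for ms in matched_sets:
        inp = LabelRuleInput(
            treated_os=float(os[ms.treated_id]),
            treated_censored=bool(cens[ms.treated_id]),
            control_os=os[ms.control_ids],
            control_censored=cens[ms.control_ids],
            weights=ms.weights,
            threshold=threshold,
        )
        dec = classify_label(inp)
        if dec.kappa_defined:
            v = estimate_variance(
                ms, os, dec.used_mask, mode=variance_mode, full_control_os=full_control_os
            )
        else:
            v = None
        out.append(
            SubjectEstimate(
                treated_id=ms.treated_id,
                sg_hat=dec.sg_hat,
                v_hat=v,
                label=dec.label,
                n_controls_used=int(np.asarray(dec.used_mask).sum()),
            )
        )
    return out


def estimates_to_frame(estimates: list[SubjectEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "treated_id": [e.treated_id for e in estimates],
            "sg_hat": [np.nan if e.sg_hat is None else e.sg_hat for e in estimates],
            "v_hat": [np.nan if e.v_hat is None else e.v_hat for e in estimates],
            "label": [e.label.value for e in estimates],
            "n_controls_used": [e.n_controls_used for e in estimates],
        }
    )
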