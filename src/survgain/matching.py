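"""Nearest-neighbour matched-set construction on the propensity score.

Three schemes, all matching WITH replacement (a control may serve several
treated units):

* greedy k-NN: each treated unit independently takes the k controls with the
  smallest absolute PS difference, uniform weights 1/k;
* exponentially weighted k-NN: same neighbours, weights proportional to
  exp(-alpha * distance), alpha = 5 by default;
* complex bootstrap: b resamples of the control group (size N^C, with
  replacement), PS model refit within each resample, 1:1 NN matching per
  resample, and the b matched controls pooled per treated unit with uniform
  weights 1/b. Only in bootstrap mode may a matched multiset contain repeats.

Distance ties are broken towards the smaller control identifier, which makes
every scheme deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dgp import Cohort
from .errors import MatchingError
from .propensity import DEFAULT_PS_COVARIATES, fit_logit

__all__ = [
    "MatchedSet",
    "nn_match",
    "exp_weights",
    "bootstrap_match",
    "matched_sets_to_frame",
]


@dataclass
class MatchedSet:
    """One treated unit and its multiset of matched controls.

    ``control_ids`` may contain repeats only when built by the bootstrap;
    ``weights`` always sum to one. ``replicates`` records the bootstrap
    replicate index per match (all zero for plain k-NN).
    """

    treated_id: int
    control_ids: np.ndarray
    distances: np.ndarray
    weights: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self):
        self.control_ids = np.asarray(self.control_ids)
        self.distances = np.asarray(self.distances, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.replicates is None:
            self.replicates = np.zeros(self.control_ids.size, dtype=int)

    @property
    def n_controls(self) -> int:
        return self.control_ids.size


def nn_match(
    ps_treated: np.ndarray,
    ps_control: np.ndarray,
    k: int,
    treated_ids: np.ndarray | None = None,
    control_ids: np.ndarray | None = None,
) -> list[MatchedSet]:
    """Greedy k-NN matching with replacement on |PS_i - PS_j|.

    Each treated unit independently receives the k controls with smallest
    absolute PS distance, with uniform weights 1/k. k = 1 is one-by-one
    matching. Ties in distance go to the smaller control identifier.
    """
    ps_treated = np.atleast_1d(np.asarray(ps_treated, dtype=float))
    ps_control = np.atleast_1d(np.asarray(ps_control, dtype=float))
    n_t, n_c = ps_treated.size, ps_control.size
    if k < 1:
        raise MatchingError(f"k must be >= 1, got {k}")
    if k > n_c:
        raise MatchingError(f"k = {k} exceeds the number of controls ({n_c})")
    treated_ids = np.arange(n_t) if treated_ids is None else np.asarray(treated_ids)
    control_ids = np.arange(n_c) if control_ids is None else np.asarray(control_ids)

    # sort controls by identifier so a stable distance sort breaks ties by id
    id_order = np.argsort(control_ids, kind="stable")
    ps_c = ps_control[id_order]
    ids_c = control_ids[id_order]

    dist = np.abs(ps_treated[:, None] - ps_c[None, :])
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]

    out = []
    w = np.full(k, 1.0 / k)
    for row, tid in enumerate(treated_ids):
        sel = nearest[row]
        out.append(
            MatchedSet(
                treated_id=int(tid),
                control_ids=ids_c[sel],
                distances=dist[row, sel],
                weights=w.copy(),
            )
        )
    return out


def exp_weights(distances: np.ndarray, alpha: float = 5.0) -> np.ndarray:
    """Exponential distance weights w_j = exp(-alpha d_j) / sum_j exp(-alpha d_j).

    alpha = 0 recovers uniform weights; alpha = 5 (the default) pushes the
    weight of a maximally distant match (d = 1) close to zero while leaving
    meaningful contrast at small distances.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise MatchingError("cannot weight an empty matched set")
    if alpha < 0:
        raise MatchingError(f"alpha must be >= 0, got {alpha}")
    if np.any((d < 0) | (d > 1)):
        raise MatchingError("PS distances must lie in [0, 1]")
    w = np.exp(-alpha * d)
    return w / w.sum()


def bootstrap_match(
    cohort: Cohort,
    b: int,
    seed,
    covariates=DEFAULT_PS_COVARIATES,
    max_retries: int = 10,
) -> list[MatchedSet]:
    """Complex bootstrap matching.

    Draw ``b`` bootstrap samples of the control group (each of size N^C, with
    replacement). Within each sample, refit the PS model on the treated units
    together with the resampled controls, then 1:1 NN-match every treated
    unit to its nearest resampled control. The pooled matched set of a
    treated unit is the multiset of its b matched original control
    identities, with uniform weights 1/b.

    A resample whose PS refit fails is redrawn, at most ``max_retries`` times,
    before the whole matching errors out.
    """
    if b < 1:
        raise MatchingError(f"b must be >= 1, got {b}")
    t_idx = cohort.treated_idx
    c_idx = cohort.control_idx
    if t_idx.size < 1 or c_idx.size < 1:
        raise MatchingError(
            "bootstrap matching needs at least 1 treated and 1 control subject"
        )
    if c_idx.size == 1:
        # forced match: with one control every resample and every pairing is
        # identical, so no PS model is needed; distances recorded as 0
        cid = int(c_idx[0])
        w = np.full(b, 1.0 / b)
        return [
            MatchedSet(
                treated_id=int(tid),
                control_ids=np.full(b, cid),
                distances=np.zeros(b),
                weights=w.copy(),
                replicates=np.arange(b),
            )
            for tid in t_idx
        ]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    X_all = cohort.covariate_matrix(list(covariates))
    n_t, n_c = t_idx.size, c_idx.size
    z_stack = np.concatenate([np.ones(n_t, dtype=int), np.zeros(n_c, dtype=int)])

    matched_ids = np.empty((n_t, b), dtype=int)
    matched_dist = np.empty((n_t, b), dtype=float)
    for rep in range(b):
        last_err = None
        for _ in range(max_retries + 1):
            sample = rng.choice(c_idx, size=n_c, replace=True)
            X_stack = np.vstack([X_all[t_idx], X_all[sample]])
            try:
                _, ps = fit_logit(X_stack, z_stack)
            except Exception as exc:  # refit failure: redraw this resample
                last_err = exc
                continue
            break
        else:
            raise MatchingError(
                f"PS refit failed in bootstrap replicate {rep} after "
                f"{max_retries} retries: {last_err}"
            )
        ps_t, ps_c = ps[:n_t], ps[n_t:]
        # stable sort by original control id within the resample → ties to
        # the smaller identifier
        order = np.argsort(sample, kind="stable")
        ps_c, ids_c = ps_c[order], sample[order]
        dist = np.abs(ps_t[:, None] - ps_c[None, :])
        best = np.argmin(dist, axis=1)  # argmin takes the first → smallest id
        matched_ids[:, rep] = ids_c[best]
        matched_dist[:, rep] = dist[np.arange(n_t), best]

    w = np.full(b, 1.0 / b)
    reps = np.arange(b)
    return [
        MatchedSet(
            treated_id=int(t_idx[i]),
            control_ids=matched_ids[i].copy(),
            distances=matched_dist[i].copy(),
            weights=w.copy(),
            replicates=reps.copy(),
        )
        for i in range(n_t)
    ]


def matched_sets_to_frame(sets: list[MatchedSet]) -> pd.DataFrame:
    """Long-format table: one row per (treated, match) pair."""
    rows = {
        "treated_id": np.concatenate([np.full(s.n_controls, s.treated_id) for s in sets]),
        "control_id": np.concatenate([s.control_ids for s in sets]),
        "distance": np.concatenate([s.distances for s in sets]),
        "weight": np.concatenate([s.weights for s in sets]),
        "replicate": np.concatenate([s.replicates for s in sets]),
    }
    return pd.DataFrame(rows)
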