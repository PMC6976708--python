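"""Independent oracles used by the test suite.

These are deliberately written as direct, slow translations of the decision
rules and of brute-force enumeration, sharing no code with the package
implementation they check.
"""

from __future__ import annotations


def label_oracle(t_os, t_cens, c_os, c_cens, w, thr):
    """Literal kappa/delta/rho translation of the censoring rule.

    delta_j = 1 when j is observed or when every control is censored, else 0.
    kappa = NA when treated and every control are censored; 1 when some
    control is observed, or when every control is censored but the weighted
    SG over delta-retained controls is below the threshold.
    rho = 1 when the treated unit is observed, or when it is censored but the
    SG is at least the threshold; NA otherwise.
    The label is undetermined when kappa or rho is NA; otherwise response
    exactly when SG >= threshold.
    """
    all_cens = all(c_cens)
    delta = [1 if (not cj) or all_cens else 0 for cj in c_cens]
    wr = [wi * di for wi, di in zip(w, delta)]
    tot = sum(wr)
    sg = t_os - sum(wi * ci for wi, ci in zip(wr, c_os)) / tot

    if all_cens and t_cens:
        kappa = None
    elif not all_cens:
        kappa = 1
    else:  # every control censored, treated observed
        kappa = 1 if sg < thr else None
    if kappa is None:
        return "undetermined"

    if not t_cens:
        rho = 1
    else:
        rho = 1 if sg >= thr else None
    if rho is None:
        return "undetermined"

    return "response" if sg >= thr else "non_response"


def brute_force_knn(ps_treated, ps_control, k):
    """Exhaustive k-NN: full sort of every |PS_i - PS_j|, ties to smaller id.

    Returns, per treated unit, the list of selected control indices.
    """
    out = []
    for pt in ps_treated:
        ranked = sorted(range(len(ps_control)), key=lambda j: (abs(pt - ps_control[j]), j))
        out.append(ranked[:k])
    return out
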