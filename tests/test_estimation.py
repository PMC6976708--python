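"""Survival-gain estimation, censoring-aware labelling, variance."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import survgain as sg
from survgain.errors import DataError
from survgain.estimation import Label, estimates_to_frame

from _oracles import label_oracle


def make_set(treated_id, control_ids, weights=None, distances=None):
    k = len(control_ids)
    return sg.MatchedSet(
        treated_id=treated_id,
        control_ids=np.asarray(control_ids),
        distances=np.zeros(k) if distances is None else np.asarray(distances),
        weights=np.full(k, 1.0 / k) if weights is None else np.asarray(weights),
    )


def rule_input(t_os, t_cens, c_os, c_cens, weights=None, thr=3.0):
    k = len(c_os)
    return sg.LabelRuleInput(
        treated_os=t_os,
        treated_censored=t_cens,
        control_os=np.asarray(c_os, float),
        control_censored=np.asarray(c_cens, bool),
        weights=np.full(k, 1.0 / max(k, 1)) if weights is None else np.asarray(weights, float),
        threshold=thr,
    )


class TestEstimateSG:
    def test_uniform_weights(self):
        ms = make_set(0, [1, 2])
        assert sg.estimate_sg(ms, np.array([20.0, 10.0, 14.0])) == pytest.approx(8.0)

    def test_nonuniform_weights(self):
        ms = make_set(0, [1, 2], weights=[0.75, 0.25])
        assert sg.estimate_sg(ms, np.array([20.0, 10.0, 20.0])) == pytest.approx(7.5)

    def test_self_valued_control_gives_zero(self):
        ms = make_set(0, [1])
        assert sg.estimate_sg(ms, np.array([20.0, 20.0])) == pytest.approx(0.0)


class TestClassifyLabel:
    def test_censored_control_large_gain_is_undetermined(self):
        dec = sg.classify_label(rule_input(30.0, False, [10.0], [True]))
        assert dec.label is Label.UNDETERMINED
        assert dec.sg_hat is None

    def test_censored_treated_large_gain_is_response(self):
        dec = sg.classify_label(rule_input(30.0, True, [10.0], [False]))
        assert dec.label is Label.RESPONSE
        assert dec.sg_hat == pytest.approx(20.0)

    def test_both_censored_is_undetermined(self):
        dec = sg.classify_label(rule_input(30.0, True, [10.0], [True]))
        assert dec.label is Label.UNDETERMINED

    def test_censored_control_dropped_and_renormalized(self):
        # treated observed 12; censored control 10 dropped; observed 11 remains
        dec = sg.classify_label(rule_input(12.0, False, [10.0, 11.0], [True, False]))
        assert dec.label is Label.NON_RESPONSE
        assert dec.sg_hat == pytest.approx(1.0)
        assert list(dec.used_mask) == [False, True]

    def test_tie_at_threshold_is_response(self):
        dec = sg.classify_label(rule_input(13.0, False, [10.0], [False], thr=3.0))
        assert dec.label is Label.RESPONSE

    def test_all_controls_censored_small_gain_is_non_response(self):
        dec = sg.classify_label(rule_input(11.0, False, [10.0, 10.0], [True, True]))
        assert dec.label is Label.NON_RESPONSE
        assert dec.sg_hat == pytest.approx(1.0)

    def test_exhaustive_truth_table_against_oracle(self):
        thr = 3.0
        c_base = 10.0
        for k in (1, 2, 3):
            for c_cens in itertools.product([False, True], repeat=k):
                for t_cens in (False, True):
                    for t_os in (c_base + thr + 2.0, c_base + thr - 2.0, c_base + thr):
                        # equal control OS values keep the SG regime invariant
                        # under any censoring-driven subsetting
                        c_os = [c_base] * k
                        w = [1.0 / k] * k
                        dec = sg.classify_label(
                            rule_input(t_os, t_cens, c_os, list(c_cens), w, thr)
                        )
                        expected = label_oracle(t_os, t_cens, c_os, c_cens, w, thr)
                        assert dec.label.value == expected, (
                            k, c_cens, t_cens, t_os)
                        assert (dec.sg_hat is None) == (
                            dec.label is Label.UNDETERMINED
                        )

    def test_empty_control_set_rejected(self):
        with pytest.raises(DataError):
            rule_input(10.0, False, [], [])

    @given(
        t_os=st.floats(0.1, 100),
        bump=st.floats(0.0, 50),
        c_os=st.lists(st.floats(0.1, 100), min_size=1, max_size=4),
        data=st.data(),
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_monotone_in_observed_treated_os(self, t_os, bump, c_os, data):
        c_cens = data.draw(
            st.lists(st.booleans(), min_size=len(c_os), max_size=len(c_os))
        )
        lo = sg.classify_label(rule_input(t_os, False, c_os, c_cens))
        hi = sg.classify_label(rule_input(t_os + bump, False, c_os, c_cens))
        if lo.label is Label.RESPONSE:
            assert hi.label is not Label.NON_RESPONSE


class TestEstimateVariance:
    def test_within_set_variance(self):
        ms = make_set(0, [1, 2])
        os = np.array([20.0, 10.0, 14.0])
        v = sg.estimate_variance(ms, os, np.array([True, True]), mode="knn")
        # s^2 = 8, sum w^2 = 1/2
        assert v == pytest.approx(4.0)

    def test_crude_mode_uses_full_control_pool(self):
        ms = make_set(0, [1])
        v = sg.estimate_variance(
            ms,
            np.array([20.0, 10.0]),
            np.array([True]),
            mode="one_by_one_crude",
            full_control_os=np.array([10.0, 14.0]),
        )
        assert v == pytest.approx(8.0)

    def test_identical_controls_give_zero(self):
        ms = make_set(0, [1, 2, 3])
        os = np.array([20.0, 12.0, 12.0, 12.0])
        assert sg.estimate_variance(ms, os, np.ones(3, bool), mode="knn") == 0.0

    def test_single_retained_control_undefined(self):
        ms = make_set(0, [1, 2])
        os = np.array([20.0, 10.0, 14.0])
        assert sg.estimate_variance(ms, os, np.array([True, False]), mode="knn") is None


class TestEstimateAll:
    def test_no_censoring_means_no_undetermined(self):
        cohort = sg.simulate_cohort(sg.make_scenario("low"), n=400, p_censor=0.0, seed=51)
        fit = sg.fit_ps(cohort)
        t, c = cohort.treated_idx, cohort.control_idx
        sets = sg.nn_match(fit.ps_hat[t], fit.ps_hat[c], 5, treated_ids=t, control_ids=c)
        ests = sg.estimate_all(cohort, sets)
        assert all(e.label is not Label.UNDETERMINED for e in ests)
        assert len(ests) == t.size

    def test_everyone_censored_means_all_undetermined(self):
        cohort = sg.simulate_cohort(sg.make_scenario("low"), n=200, p_censor=1.0, seed=52)
        fit = sg.fit_ps(cohort)
        t, c = cohort.treated_idx, cohort.control_idx
        sets = sg.nn_match(fit.ps_hat[t], fit.ps_hat[c], 3, treated_ids=t, control_ids=c)
        ests = sg.estimate_all(cohort, sets)
        # every treated is censored, so only rules (a)/(d) can fire and the
        # (d) response branch needs SG >= threshold over observed controls,
        # which cannot happen with every control censored too
        assert all(e.label is Label.UNDETERMINED for e in ests)

    def test_zero_weight_control_is_transparent(self):
        os = np.array([20.0, 10.0, 14.0, 999.0])
        cens = np.array([0, 0, 0, 1])
        cohort = _tiny_cohort(os, cens, z=[1, 0, 0, 0])
        with_zero = make_set(0, [1, 2, 3], weights=[0.5, 0.5, 0.0])
        without = make_set(0, [1, 2], weights=[0.5, 0.5])
        [a] = sg.estimate_all(cohort, [with_zero])
        [b] = sg.estimate_all(cohort, [without])
        assert a.label == b.label
        assert a.sg_hat == pytest.approx(b.sg_hat)
        assert a.v_hat == pytest.approx(b.v_hat)

    def test_threshold_zero_no_censoring_response_iff_nonnegative_gain(self):
        cohort = sg.simulate_cohort(sg.make_scenario("low"), n=300, p_censor=0.0, seed=53)
        fit = sg.fit_ps(cohort)
        t, c = cohort.treated_idx, cohort.control_idx
        sets = sg.nn_match(fit.ps_hat[t], fit.ps_hat[c], 5, treated_ids=t, control_ids=c)
        for e in sg.estimate_all(cohort, sets, threshold=1e-12):
            assert (e.label is Label.RESPONSE) == (e.sg_hat >= 1e-12)

    def test_estimates_frame_layout(self, low_cohort, low_cohort_ps):
        t, c = low_cohort.treated_idx, low_cohort.control_idx
        sets = sg.nn_match(
            low_cohort_ps.ps_hat[t], low_cohort_ps.ps_hat[c], 5, treated_ids=t, control_ids=c
        )
        df = estimates_to_frame(sg.estimate_all(low_cohort, sets))
        assert list(df.columns) == ["treated_id", "sg_hat", "v_hat", "label", "n_controls_used"]
        assert df["label"].isin(["response", "non_response", "undetermined"]).all()


def _tiny_cohort(os, cens, z):
    n = len(os)
    return sg.Cohort(
        X=np.zeros((n, 10)),
        Z=np.asarray(z),
        OS_obs=np.asarray(os, float),
        censored=np.asarray(cens),
    )
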