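"""Kaplan-Meier, log-rank, Cox PH and added-value metrics."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import ddrcna
from ddrcna import survival as sv
from ddrcna.errors import DataError


def _records(times, events, **cols):
    df = pd.DataFrame({"time": times, "event": events})
    df.insert(0, "patient_id", np.arange(len(df)))
    for k, v in cols.items():
        df[k] = v
    return df


# ---- censoring -----------------------------------------------------------


def test_censoring_truncates_late_events():
    rec = _records([7.9, 3.2], [True, True])
    out = sv.censor_at_horizon(rec, 5.0)
    assert (out["time"].tolist(), out["event"].tolist()) == ([5.0, 3.2],
                                                             [False, True])


def test_censoring_never_adds_events():
    rng = np.random.default_rng(0)
    rec = _records(rng.exponential(4, 200), rng.random(200) < 0.6)
    out = sv.censor_at_horizon(rec, 5.0)
    assert out["event"].sum() <= rec["event"].sum()


def test_negative_time_rejected():
    with pytest.raises(DataError):
        sv.censor_at_horizon(_records([-1.0], [True]), 5.0)


# ---- Kaplan-Meier --------------------------------------------------------


def test_km_hand_product_limit():
    """times {2 event, 4 censor, 5 event, 6 censor}: S(2)=3/4, S(5)=3/8."""
    rec = _records([2, 4, 5, 6], [True, False, True, False])
    curve = sv.km_estimate(rec)["all"]
    assert curve.survival_at(2) == pytest.approx(0.75)
    assert curve.survival_at(5) == pytest.approx(0.375)
    assert curve.survival_at(1) == 1.0


def test_km_without_events_stays_at_one():
    rec = _records([1, 2, 3], [False, False, False])
    curve = sv.km_estimate(rec)["all"]
    assert curve.survival_at(10) == 1.0


def test_km_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(1)
    t = rng.exponential(3, 150)
    rec = _records(t, np.ones(150, bool))
    curve = sv.km_estimate(rec)["all"]
    for q in (0.5, 1.0, 2.0, 4.0):
        assert curve.survival_at(q) == pytest.approx((t > q).mean())


def test_km_empty_stratum_rejected():
    rec = _records([1.0], [True], grp=["a"])
    with pytest.raises(DataError):
        sv.km_estimate(rec.iloc[:0])


def test_km_survival_is_monotone_nonincreasing(called_cohort):
    b, _, _ = called_cohort
    rec = sv.censor_at_horizon(b.clinical, 5.0)
    curve = sv.km_estimate(rec)["all"]
    assert (np.diff(curve.survival) <= 1e-12).all()
    assert curve.survival[0] <= 1.0


# ---- log-rank ------------------------------------------------------------


def _logrank_oracle(rec, group):
    """Hypergeometric mean/variance terms summed over event times."""
    labels = sorted(rec[group].unique())
    o_minus_e, var = 0.0, 0.0
    for t in sorted(rec.loc[rec["event"], "time"].unique()):
        at_risk = rec["time"] >= t
        n = at_risk.sum()
        n1 = (at_risk & (rec[group] == labels[0])).sum()
        d = (rec["event"] & (rec["time"] == t)).sum()
        d1 = (rec["event"] & (rec["time"] == t) & (rec[group] == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def test_logrank_matches_hand_worked_fixture():
    rec = _records(
        [1, 2, 3, 4, 5, 6],
        [True, True, False, True, True, False],
        grp=["a", "b", "a", "b", "a", "b"],
    )
    chi2, p = sv.logrank_test(rec, "grp")
    assert chi2 == pytest.approx(_logrank_oracle(rec, "grp"), rel=1e-6)


def test_logrank_identical_groups_is_null():
    base = _records([1, 2, 3, 4], [True, True, False, True])
    rec = pd.concat([base.assign(grp="a"), base.assign(grp="b")],
                    ignore_index=True)
    chi2, p = sv.logrank_test(rec, "grp")
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_invariant_to_label_swap():
    rng = np.random.default_rng(3)
    rec = _records(
        rng.exponential(3, 80), rng.random(80) < 0.7,
        grp=rng.choice(["a", "b"], 80),
    )
    _, p1 = sv.logrank_test(rec, "grp")
    rec["grp"] = rec["grp"].map({"a": "b", "b": "a"})
    _, p2 = sv.logrank_test(rec, "grp")
    assert p1 == pytest.approx(p2)


def test_logrank_needs_two_groups():
    with pytest.raises(DataError):
        sv.logrank_test(_records([1, 2], [True, True], grp=["a", "a"]), "grp")


# ---- Cox -----------------------------------------------------------------


def test_cox_symmetric_data_gives_null_coefficient():
    base = _records([1, 2, 3, 5, 7, 9], [1, 1, 0, 1, 1, 0])
    rec = pd.concat([base.assign(x=0), base.assign(x=1)], ignore_index=True)
    fit = sv.cox_fit(rec, ["x"])
    assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)
    assert fit.hazard_ratios["x"] == pytest.approx(1.0, abs=1e-8)


def _efron_loglik_direct(time, event, x, beta):
    """O(n^2) direct evaluation of the Efron partial log-likelihood."""
    ll = 0.0
    for t in np.unique(time[event]):
        members = np.flatnonzero(event & (time == t))
        risk = np.flatnonzero(time >= t)
        m = len(members)
        theta = np.exp(beta * x)
        s0 = theta[risk].sum()
        d0 = theta[members].sum()
        ll += beta * x[members].sum()
        for l in range(m):
            ll -= np.log(s0 - (l / m) * d0)
    return ll


def test_cox_coefficient_matches_partial_likelihood_grid_search():
    time = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
    event = np.array([1, 1, 1, 0, 1, 1, 0, 1], bool)
    x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 0.0])
    rec = _records(time, event, x=x)
    fit = sv.cox_fit(rec, ["x"], ties="efron")
    grid = np.arange(-3, 3, 1e-4)
    lls = [_efron_loglik_direct(time, event, x - x.mean(), b) for b in grid]
    beta_star = grid[int(np.argmax(lls))]
    assert abs(fit.coef[0] - beta_star) < 1e-4


def test_cox_agrees_with_lifelines_cross_check(called_cohort):
    b, _, matrix = called_cohort
    rec = sv.censor_at_horizon(b.clinical, 5.0)
    rec = sv.gain_vs_neutral(rec, matrix, "NBN")
    covs = ["NBN_gain"] + sv.CLINICAL_COVARIATES
    fit = sv.cox_fit(rec, covs, ties="efron")
    cph = CoxPHFitter()
    cph.fit(rec[["time", "event"] + covs], "time", "event")
    assert np.allclose(fit.coef, cph.params_[covs].to_numpy(), atol=1e-5)
    assert np.allclose(fit.se, cph.standard_errors_[covs].to_numpy(), atol=1e-5)


def test_breslow_and_efron_agree_without_ties():
    rng = np.random.default_rng(4)
    rec = _records(rng.exponential(3, 60), np.ones(60, bool),
                   x=rng.integers(0, 2, 60).astype(float))
    fe = sv.cox_fit(rec, ["x"], ties="efron")
    fb = sv.cox_fit(rec, ["x"], ties="breslow")
    assert fe.coef[0] == pytest.approx(fb.coef[0], abs=1e-9)


def test_cox_constant_covariate_rejected():
    rec = _records([1, 2, 3], [True, True, False], x=[1.0, 1.0, 1.0])
    with pytest.raises(DataError, match="constant"):
        sv.cox_fit(rec, ["x"])


def test_cox_separation_is_flagged_not_fatal():
    # events only in the x=0 group, perfectly separated
    rec = _records([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0],
                   x=[0.0, 0, 0, 1, 1, 1])
    with pytest.warns(UserWarning, match="monotone"):
        fit = sv.cox_fit(rec, ["x"])
    assert fit.monotone_likelihood


def test_wald_ci_brackets_hazard_ratio(called_cohort):
    b, _, matrix = called_cohort
    rec = sv.gain_vs_neutral(sv.censor_at_horizon(b.clinical, 5.0), matrix, "NBN")
    s = sv.cox_fit(rec, ["NBN_gain"]).summary()
    assert (s["hr_lo95"] <= s["hr"]).all() and (s["hr"] <= s["hr_hi95"]).all()
    assert (s["hr"] > 0).all()


def test_schoenfeld_seldom_flags_proportional_hazards():
    flags, total = 0, 0
    for seed in range(12):
        b = ddrcna.simulate_cohort("cox_calibrated", seed=seed, n_patients=600)
        rec = sv.gain_vs_neutral(
            sv.censor_at_horizon(b.clinical, 5.0), b.gene_status, "NBN"
        )
        fit = sv.cox_fit(rec, ["NBN_gain"] + sv.CLINICAL_COVARIATES)
        for p in fit.schoenfeld_p.values():
            total += 1
            flags += p < 0.05
    assert flags / total < 0.25


# ---- discrimination metrics ----------------------------------------------


def test_c_statistic_limits():
    rec = _records([1, 2, 6, 7], [True, True, False, False])
    perfect = sv.c_statistic([0.9, 0.8, 0.1, 0.2], rec, horizon=5)
    constant = sv.c_statistic([0.5] * 4, rec, horizon=5)
    assert perfect.c_statistic == 1.0
    assert constant.c_statistic == 0.5


def test_c_statistic_matches_pair_enumeration():
    rec = _records([1, 2, 3, 6, 7, 8],
                   [True, True, True, False, False, False])
    scores = np.array([0.9, 0.4, 0.6, 0.6, 0.2, 0.8])
    ev, fr = scores[:3], scores[3:]
    pairs = [(1.0 if a > b else 0.5 if a == b else 0.0) for a in ev for b in fr]
    want = np.mean(pairs)
    got = sv.c_statistic(scores, rec, horizon=5).c_statistic
    assert got == pytest.approx(want)


def test_c_statistic_invariant_under_monotone_transform():
    rng = np.random.default_rng(5)
    rec = _records(rng.exponential(4, 60), rng.random(60) < 0.5)
    scores = rng.random(60)
    a = sv.c_statistic(scores, rec).c_statistic
    b = sv.c_statistic(np.exp(5 * scores), rec).c_statistic
    assert a == pytest.approx(b)


def test_censored_before_horizon_excluded_from_c_statistic():
    rec = _records([1, 2, 3, 6], [True, False, False, False])
    m = sv.c_statistic([0.4, 0.9, 0.9, 0.1], rec, horizon=5)
    assert (m.n_events, m.n_event_free) == (1, 1)
    assert m.c_statistic == 1.0


def test_nri_idi_zero_for_identical_models():
    rec = _records([1, 2, 6, 7], [True, True, False, False])
    risks = np.array([0.7, 0.6, 0.2, 0.3])
    m = sv.nri_idi(risks, risks.copy(), rec, horizon=5)
    assert m.nri == 0.0 and m.idi == 0.0


def test_nri_attains_upper_bound():
    rec = _records([1, 2, 6, 7], [True, True, False, False])
    old = np.array([0.5, 0.5, 0.5, 0.5])
    new = np.array([0.8, 0.9, 0.2, 0.1])
    assert sv.nri_idi(old, new, rec, horizon=5).nri == 2.0


def test_nri_idi_match_hand_computation():
    rec = _records([1, 2, 3, 6, 7, 8],
                   [True, True, True, False, False, False])
    old = np.array([0.5, 0.4, 0.6, 0.3, 0.2, 0.4])
    new = np.array([0.7, 0.3, 0.9, 0.2, 0.5, 0.4])
    m = sv.nri_idi(old, new, rec, horizon=5)
    # events: up, down, up -> 2/3 - 1/3; event-free: down, up, same -> 1/3 - 1/3
    assert m.nri == pytest.approx((2 / 3 - 1 / 3) + (1 / 3 - 1 / 3))
    d = new - old
    assert m.idi == pytest.approx(d[:3].mean() - d[3:].mean())


def test_nri_mismatched_patient_sets_rejected():
    rec = _records([1, 2, 6], [True, True, False])
    with pytest.raises(DataError):
        sv.nri_idi([0.1, 0.2], [0.3, 0.4], rec, horizon=5)


def test_predicted_risks_are_probabilities(called_cohort):
    b, _, matrix = called_cohort
    rec = sv.gain_vs_neutral(sv.censor_at_horizon(b.clinical, 5.0), matrix, "NBN")
    fit = sv.cox_fit(rec, ["NBN_gain"] + sv.CLINICAL_COVARIATES)
    risks = fit.predicted_risk(rec[["NBN_gain"] + sv.CLINICAL_COVARIATES], 5.0)
    assert ((risks >= 0) & (risks <= 1)).all()
    # gain carriers are higher-risk on average under the planted hazards
    assert risks[rec["NBN_gain"] == 1].mean() > risks[rec["NBN_gain"] == 0].mean()
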