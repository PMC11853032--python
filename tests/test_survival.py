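"""Dichotomization, Cox partial likelihood, Kaplan-Meier, grade logistic."""

import numpy as np
import pandas as pd
import pytest

from telocascade.cohort import DeltaMatrix
from telocascade.survival import (
    INCREASED,
    NOT_INCREASED,
    GroupAssignment,
    cox_fit,
    dichotomize,
    grade_logistic,
    km_curve,
)


def make_deltas(gene_values: dict, delta_tel=None):
    frame = pd.DataFrame(gene_values).T
    frame.columns = [f"P{i}" for i in range(frame.shape[1])]
    tel = pd.Series(delta_tel, index=frame.columns) if delta_tel is not None else None
    return DeltaMatrix(
        values=frame,
        mpnst_log=frame + 5,
        delta_telomere=tel,
        mpnst_telomere=tel,
    )


def groups_from(labels):
    return GroupAssignment(
        factor="G",
        groups=pd.Series(labels, index=[f"P{i}" for i in range(len(labels))], name="group"),
    )


def clinical_frame(times, events, evaluable=None):
    n = len(times)
    return pd.DataFrame(
        {
            "os_time": times,
            "os_event": events,
            "mfs_time": times,
            "mfs_event": events,
            "mfs_evaluable": evaluable if evaluable is not None else np.ones(n, dtype=int),
        },
        index=[f"P{i}" for i in range(n)],
    )


# ---------------------------------------------------------------------------
# dichotomization
# ---------------------------------------------------------------------------

def test_zero_delta_is_not_increased():
    groups = dichotomize(make_deltas({"G": [0.0, 0.001, -0.5]}), "G")
    assert groups.groups.tolist() == [NOT_INCREASED, INCREASED, NOT_INCREASED]


def test_single_group_flagged_non_comparable():
    groups = dichotomize(make_deltas({"G": [-1.0, -2.0, -0.5]}), "G")
    assert not groups.comparable
    clin = clinical_frame([1, 2, 3], [1, 1, 0])
    with pytest.raises(ValueError, match="single group"):
        cox_fit(clin, groups, "OS")


def test_dichotomize_on_telomere_uses_content_change():
    deltas = make_deltas({"G": [0.0, 0.0, 0.0]}, delta_tel=[5.0, -3.0, 0.0])
    groups = dichotomize(deltas, "telomere")
    assert groups.groups.tolist() == [INCREASED, NOT_INCREASED, NOT_INCREASED]


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

def breslow_loglik(beta, times, events, x):
    """Breslow partial log-likelihood for a single covariate."""
    ll = 0.0
    for t, d, xi in zip(times, events, x):
        if d:
            at_risk = [j for j in range(len(times)) if times[j] >= t]
            ll += beta * xi - np.log(sum(np.exp(beta * x[j]) for j in at_risk))
    return ll


def test_cox_matches_grid_maximized_breslow_likelihood():
    times = [1.0, 2.0, 3.0, 4.0]
    events = [1, 1, 1, 0]
    # alternating groups keep the partial likelihood maximum interior
    x = [1.0, 0.0, 1.0, 0.0]
    labels = [INCREASED, NOT_INCREASED, INCREASED, NOT_INCREASED]
    res = cox_fit(clinical_frame(times, events), groups_from(labels), "OS", ties="breslow")
    grid = np.linspace(-5, 5, 20001)
    ll = [breslow_loglik(b, times, events, x) for b in grid]
    beta_star = grid[int(np.argmax(ll))]
    assert np.log(res.hazard_ratio) == pytest.approx(beta_star, abs=1e-3)


def test_cox_invariant_to_time_rescaling(rng):
    n = 40
    times = rng.exponential(30, n)
    events = (rng.random(n) < 0.7).astype(int)
    labels = [INCREASED if i % 2 else NOT_INCREASED for i in range(n)]
    months = cox_fit(clinical_frame(times, events), groups_from(labels), "OS")
    days = cox_fit(clinical_frame(times * 30.44, events), groups_from(labels), "OS")
    assert months.hazard_ratio == pytest.approx(days.hazard_ratio, rel=1e-8)
    assert months.wald_p == pytest.approx(days.wald_p, rel=1e-8)


def test_swapping_groups_inverts_hazard_ratio(rng):
    n = 30
    times = rng.exponential(20, n)
    events = (rng.random(n) < 0.8).astype(int)
    labels = [INCREASED if i < 12 else NOT_INCREASED for i in range(n)]
    flipped = [NOT_INCREASED if lab == INCREASED else INCREASED for lab in labels]
    a = cox_fit(clinical_frame(times, events), groups_from(labels), "OS")
    b = cox_fit(clinical_frame(times, events), groups_from(flipped), "OS")
    assert a.hazard_ratio == pytest.approx(1 / b.hazard_ratio, rel=1e-8)
    assert a.wald_p == pytest.approx(b.wald_p, rel=1e-6)


def test_cox_null_covers_unity_at_large_n(rng):
    n = 400
    times = rng.exponential(30, n)
    events = (rng.random(n) < 0.75).astype(int)
    labels = [INCREASED if v else NOT_INCREASED for v in rng.random(n) < 0.5]
    res = cox_fit(clinical_frame(times, events), groups_from(labels), "OS")
    assert res.ci_low < 1.0 < res.ci_high


def test_cox_requires_events():
    clin = clinical_frame([1, 2, 3, 4], [0, 0, 0, 0])
    labels = [INCREASED, INCREASED, NOT_INCREASED, NOT_INCREASED]
    with pytest.raises(ValueError, match="no events"):
        cox_fit(clin, groups_from(labels), "OS")


def test_cox_flags_monotone_likelihood():
    clin = clinical_frame([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0])
    labels = [INCREASED] * 3 + [NOT_INCREASED] * 3
    res = cox_fit(clin, groups_from(labels), "OS")
    assert res.flag == "monotone_likelihood"
    assert res.ci_high == np.inf


def test_mfs_restricted_to_evaluable_patients():
    clin = clinical_frame([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 0, 0], [1, 1, 1, 1, 0, 0])
    labels = [INCREASED, NOT_INCREASED] * 3
    res = cox_fit(clin, groups_from(labels), "MFS")
    assert res.n_increased + res.n_not_increased == 4


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

def hand_product_limit(times, events):
    """Hand product-limit over distinct event times."""
    order = np.argsort(times)
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=int)[order]
    surv = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1 - d / n_risk
        surv[t] = s
    return surv


def km_values(curve):
    return dict(zip(curve.times, curve.survival))


def test_km_steps_without_censoring():
    clin = clinical_frame([1.0, 2.0, 3.0], [1, 1, 1])
    groups = groups_from([INCREASED] * 3)
    (curve,) = km_curve(clin, groups, "OS").values()
    vals = km_values(curve)
    assert vals[1.0] == pytest.approx(2 / 3)
    assert vals[2.0] == pytest.approx(1 / 3)
    assert vals[3.0] == pytest.approx(0.0)


def test_km_all_censored_stays_flat():
    clin = clinical_frame([5.0, 8.0, 9.0], [0, 0, 0])
    (curve,) = km_curve(clin, groups_from([INCREASED] * 3), "OS").values()
    assert (curve.survival == 1.0).all()
    assert len(curve.censor_times) == 3


def test_km_matches_hand_computation_on_mixed_records():
    times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    events = [1, 0, 1, 1, 0, 1]
    clin = clinical_frame(times, events)
    (curve,) = km_curve(clin, groups_from([NOT_INCREASED] * 6), "OS").values()
    vals = km_values(curve)
    for t, s in hand_product_limit(times, events).items():
        assert vals[t] == pytest.approx(s, abs=1e-12)
    assert vals[1.0] == pytest.approx(5 / 6)
    assert vals[6.0] == pytest.approx(0.0)


def test_km_is_non_increasing_and_starts_at_one(rng):
    times = rng.exponential(10, 25)
    events = (rng.random(25) < 0.6).astype(int)
    labels = [INCREASED if i % 2 else NOT_INCREASED for i in range(25)]
    for curve in km_curve(clinical_frame(times, events), groups_from(labels), "OS").values():
        assert curve.survival[0] == 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()


# ---------------------------------------------------------------------------
# grade logistic
# ---------------------------------------------------------------------------

def grade_clinical(grades):
    return pd.DataFrame({"fnclcc_grade": grades}, index=[f"P{i}" for i in range(len(grades))])


def test_grade_logistic_matches_cross_product_ratio():
    # 2x2 table (a,b,c,d) = (6,2,2,6): OR = ad/bc = 9
    grades = [3] * 6 + [1] * 2 + [3] * 2 + [2] * 6
    labels = [INCREASED] * 8 + [NOT_INCREASED] * 8
    res = grade_logistic(groups_from(labels), grade_clinical(grades))
    assert res.odds_ratio == pytest.approx(9.0, rel=1e-6)
    assert res.flag is None


def test_grade_logistic_null_covers_unity(rng):
    n = 400
    labels = [INCREASED if v else NOT_INCREASED for v in rng.random(n) < 0.5]
    grades = rng.choice([1, 2, 3], size=n)
    res = grade_logistic(groups_from(labels), grade_clinical(grades))
    assert res.ci_low < 1.0 < res.ci_high


def test_grade_logistic_flags_separation():
    grades = [3] * 5 + [1] * 5
    labels = [INCREASED] * 5 + [NOT_INCREASED] * 5
    res = grade_logistic(groups_from(labels), grade_clinical(grades))
    assert res.flag == "separation"
    assert np.isnan(res.p_value)
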