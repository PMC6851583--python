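"""Kinetics estimators: closed-form cases, identities, statistical protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from picovir import kinetics as kin


# -- log2 fold change and growth rate ---------------------------------------

@pytest.mark.parametrize("value,expected", [
    (2e6, 1.0),          # one doubling
    (1e6, 0.0),
    (5e6, np.log2(5.0)),
])
def test_log2_fold_change_closed_form(value, expected):
    out = kin.log2_fold_change([1e6, value], times=[0.0, 1.0], reference_time=0.0)
    assert out[1] == pytest.approx(expected)
    assert out[0] == 0.0


def test_log2_fold_change_flags_nonpositive_counts():
    with pytest.warns(UserWarning):
        out = kin.log2_fold_change([1e6, 0.0], times=[0, 1], reference_time=0)
    assert np.isnan(out[1])


def test_growth_rate_doubling_in_a_day():
    mu = kin.growth_rate([0.0, 24.0], [1e6, 2e6], 0.0, 24.0)
    assert mu == pytest.approx(np.log(2.0))


def test_growth_rate_constant_and_mortality():
    assert kin.growth_rate([0, 24], [5e5, 5e5], 0, 24) == 0.0
    assert kin.growth_rate([0, 24], [5e5, 2.5e5], 0, 24) == pytest.approx(-np.log(2))


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(1e2, 1e9), min_size=2, max_size=12))
def test_vp_equals_two_to_the_log2fc(values):
    """VP = 2**n_t exactly, per observation."""
    times = np.arange(len(values), dtype=float)
    n = kin.log2_fold_change(values, times=times, reference_time=0.0)
    vp = kin.viral_production(values, times=times, reference_time=0.0)
    np.testing.assert_allclose(vp, 2.0 ** n, rtol=1e-12)


# -- latent period ----------------------------------------------------------

def test_latent_period_interval_from_first_significant_timepoint():
    times = [4.5, 6.5, 8.5]
    reps = np.array([[0.0, 0.01, -0.01], [0.0, 0.0, 0.01], [1.0, 1.1, 0.9]])
    interval = kin.latent_period(reps, times)
    assert (interval.t_low, interval.t_high) == (6.5, 8.5)
    assert interval.detected


def test_latent_period_undetected_when_flat():
    with pytest.warns(UserWarning):
        interval = kin.latent_period(np.zeros((3, 3)), [4.5, 6.5, 8.5])
    assert not interval.detected
    assert np.isinf(interval.t_high)


def test_latent_period_requires_positive_mean():
    """A significant *decrease* (adsorption) must not trigger detection."""
    reps = np.array([[-1.0, -1.1, -0.9], [2.0, 2.1, 1.9]])
    interval = kin.latent_period(reps, [2.5, 4.5])
    assert (interval.t_low, interval.t_high) == (2.5, 4.5)


def test_latent_period_never_precedes_first_positive_mean(rng):
    for _ in range(20):
        times = np.array([2.5, 4.5, 6.5, 8.5, 10.5])
        reps = rng.normal(0, 0.2, size=(5, 3))
        reps[3:] += 2.0
        est = kin.LatentPeriodEstimator().fit(reps, times=times)
        if est.interval_.detected:
            means = reps.mean(axis=1)
            first_pos = times[np.flatnonzero(means > 0)[0]]
            assert est.interval_.t_high >= first_pos


# -- burst size -------------------------------------------------------------

def burst_reps(dv, dh, h0=1e6, v0=1e6):
    times = np.array([18.5, 24.5])
    return [(times, np.array([v0, v0 + dv]), np.array([h0, h0 - dh]))]


def test_burst_size_arithmetic():
    mean, sd = kin.burst_size(burst_reps(dv=1e5, dh=1e3))
    assert mean == pytest.approx(100.0)
    assert sd == 0.0


def test_burst_size_zero_release():
    mean, _ = kin.burst_size(burst_reps(dv=0.0, dh=1e3))
    assert mean == 0.0


def test_burst_size_excludes_host_gain_with_warning():
    reps = burst_reps(1e5, 1e3) + burst_reps(1e5, -1e3)
    with pytest.warns(UserWarning):
        est = kin.BurstSizeEstimator().fit(reps)
    assert est.n_used_ == 1 and est.n_excluded_ == 1
    assert est.burst_mean_ == pytest.approx(100.0)


def test_burst_size_unit_invariance():
    per_ml = burst_reps(1e5, 1e3)
    per_l = [(t, v * 1e3, h * 1e3) for t, v, h in per_ml]
    assert kin.burst_size(per_ml)[0] == pytest.approx(kin.burst_size(per_l)[0])


# -- production ratio -------------------------------------------------------

def test_sensitivity_ratio_identical_series_is_one():
    vp = np.array([[10.0, 11.0, 9.0], [20.0, 21.0, 19.0]])
    out = kin.sensitivity_ratio(vp, vp, times=[10.5, 24.5])
    np.testing.assert_allclose(out["ratio"], 1.0)


def test_sensitivity_ratio_reported_fold_changes():
    """LL 16.6x vs SL 48.6x production gives a ratio of 0.342."""
    ll = np.array([[16.6 - 1.2, 16.6, 16.6 + 1.2]])
    sl = np.array([[48.6 - 14.2, 48.6, 48.6 + 14.2]])
    out = kin.sensitivity_ratio(ll, sl, times=[24.5])
    assert out["ratio"].iloc[0] == pytest.approx(16.6 / 48.6, rel=1e-6)
    assert out["ratio"].iloc[0] == pytest.approx(0.342, abs=5e-4)


def test_sensitivity_ratio_guards_zero_denominator():
    ll = np.array([[1.0, 1.1, 0.9]])
    sl = np.zeros((1, 3))
    with pytest.warns(UserWarning):
        out = kin.sensitivity_ratio(ll, sl, times=[24.5])
    assert np.isnan(out["ratio"].iloc[0])


def test_sensitivity_ratio_excludes_pre_release_times():
    vp = np.ones((3, 3))
    out = kin.sensitivity_ratio(vp, vp, times=[4.5, 8.5, 24.5], after_h=8.5)
    assert list(out["time_h"]) == [8.5, 24.5]


# -- statistical protocol ---------------------------------------------------

def make_table(groups: dict, time_h: float = 8.5) -> pd.DataFrame:
    rows = [
        {"time_h": time_h, "group": g, "value": v}
        for g, values in groups.items()
        for v in values
    ]
    return pd.DataFrame(rows)


def test_protocol_separates_distinct_groups():
    table = make_table({"none": [0, 0.05, -0.05], "v1": [5, 5.1, 4.9],
                        "v2": [5, 5.0, 5.2]})
    out = kin.test_protocol(table)
    assert (out["p_anova"] < 1e-6).all()
    sig = out.set_index("contrast")["p_tukey"]
    assert sig["none vs v1"] < 0.01
    assert sig["none vs v2"] < 0.01
    assert sig["v1 vs v2"] > 0.05


def test_protocol_identical_groups_not_significant():
    table = make_table({"a": [1.0, 1.1, 0.9], "b": [1.0, 1.1, 0.9],
                        "c": [1.0, 1.1, 0.9]})
    out = kin.test_protocol(table)
    assert (out["p_anova"] > 0.9).all()
    assert not out["significant"].any()


def test_protocol_degenerate_zero_variance():
    table = make_table({"a": [1.0, 1.0], "b": [1.0, 1.0]})
    out = kin.test_protocol(table)
    assert out["degenerate"].all()
    assert out["p_anova"].isna().all()


def test_protocol_type2_equals_type1_for_balanced_design(rng):
    """In a balanced one-way layout, Type II and Type I sums of squares agree."""
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    table = make_table({g: rng.normal(i, 1, 4) for i, g in enumerate("abc")})
    out = kin.test_protocol(table)
    model = ols("value ~ C(group)", data=table).fit()
    f_type1 = float(anova_lm(model, typ=1).loc["C(group)", "F"])
    assert out["f_anova"].iloc[0] == pytest.approx(f_type1, rel=1e-9)


def test_protocol_welch_contrast_present():
    table = make_table({"a": [0.0, 0.1, -0.1], "b": [3.0, 3.1, 2.9]})
    out = kin.test_protocol(table)
    assert out["p_welch"].iloc[0] < 0.01
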