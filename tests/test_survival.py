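"""Survival analysis against hand-worked product-limit and rank-test oracles."""

import numpy as np
import pandas as pd
import pytest

import panelscreen as ps
from panelscreen.errors import DataError, UsageError
from panelscreen.survival import _rmst_one


def rec(times, events=None, **cols):
    df = pd.DataFrame({"time": times,
                       "event": events if events is not None else [1] * len(times)})
    for k, v in cols.items():
        df[k] = v
    return df


def test_km_no_censoring_steps_and_median():
    curve = ps.km_fit(rec([1.0, 2.0, 3.0, 4.0]))
    assert np.allclose(curve.survival, [0.75, 0.50, 0.25, 0.0])
    assert ps.survival_quantile(curve, 0.5) == 2.0
    assert ps.survival_quantile(curve, 0.9) == 4.0


def test_km_with_censoring_matches_hand_product_limit():
    # times 1, 2+, 3, 4: S(1)=3/4, S(3)=3/4*1/2=3/8, S(4)=0
    curve = ps.km_fit(rec([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 1]))
    tab = dict(zip(curve.times, curve.survival))
    assert tab[1.0] == pytest.approx(0.75)
    assert tab[3.0] == pytest.approx(0.375)
    assert tab[4.0] == pytest.approx(0.0)


def test_km_all_censored_median_missing():
    curve = ps.km_fit(rec([1.0, 2.0, 3.0], [0, 0, 0]))
    assert np.isnan(ps.survival_quantile(curve, 0.5))


def test_km_no_censoring_equals_empirical_survival():
    rng = np.random.default_rng(0)
    t = rng.exponential(10, 50)
    curve = ps.km_fit(rec(t))
    for ti, si in zip(curve.times, curve.survival):
        assert si == pytest.approx((t > ti).mean(), abs=1e-12)


def test_km_empty_raises():
    with pytest.raises(DataError):
        ps.km_fit(rec([]))
    with pytest.raises(DataError):
        ps.km_fit(rec([0.0, 1.0]))


def test_logrank_identical_groups_is_null():
    base = rec([1.0, 2.0, 3.0, 4.0])
    df = pd.concat([base.assign(g="a"), base.assign(g="b")], ignore_index=True)
    out = ps.logrank(df, "g")
    assert out["statistic"][0] == pytest.approx(0.0, abs=1e-10)
    assert out["p"][0] == pytest.approx(1.0)


def test_logrank_two_group_matches_hypergeometric_oracle():
    df = pd.concat([rec([1.0, 3.0, 5.0, 7.0], g="a"),
                    rec([2.0, 4.0, 6.0, 8.0], g="b")], ignore_index=True)
    # hand computation of sum(O-E) and hypergeometric variance for group a
    t = df["time"].to_numpy()
    ga = (df["g"] == "a").to_numpy()
    O_E, V = 0.0, 0.0
    for ut in np.sort(np.unique(t)):
        at = t >= ut
        n = at.sum()
        n_a = (at & ga).sum()
        d = (t == ut).sum()
        d_a = ((t == ut) & ga).sum()
        O_E += d_a - d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    stat_oracle = O_E ** 2 / V
    out = ps.logrank(df, "g")
    assert out["statistic"][0] == pytest.approx(stat_oracle, rel=1e-10)


def test_logrank_invariant_to_monotone_time_transform():
    rng = np.random.default_rng(1)
    df = rec(rng.exponential(5, 40) + 0.1, g=np.repeat(["a", "b"], 20))
    s1 = ps.logrank(df, "g")["statistic"][0]
    df2 = df.assign(time=df["time"] ** 2)
    s2 = ps.logrank(df2, "g")["statistic"][0]
    assert s1 == pytest.approx(s2, rel=1e-12)


def test_pairwise_logrank_has_bh_column_and_all_pairs():
    rng = np.random.default_rng(2)
    df = rec(rng.exponential(5, 60) + 0.1,
             g=np.repeat(["a", "b", "c"], 20))
    out = ps.logrank(df, "g", pairwise=True)
    assert len(out) == 3
    assert (out["q"] >= out["p"] - 1e-12).all()


def test_cox_tiny_data_matches_newton_oracle():
    df = rec([1.0, 2.0, 3.0, 4.0], x=[1.0, 0.0, 1.0, 0.0])
    fit = ps.cox_fit(df, covariates="x", strata=None)
    # independent Newton on the exact partial-likelihood score
    xs = df.sort_values("time")["x"].to_numpy()
    b = 0.0
    for _ in range(60):
        s = h = 0.0
        for i in range(len(xs)):
            r = xs[i:]
            w = np.exp(b * r)
            e = (r * w).sum() / w.sum()
            s += xs[i] - e
            h -= (r ** 2 * w).sum() / w.sum() - e ** 2
        step = s / h
        b -= step
        if abs(s) < 1e-14:
            break
    assert float(fit.summary["coef"]["x"]) == pytest.approx(b, abs=1e-8)


def test_cox_efron_equals_breslow_without_ties():
    df = rec([1.0, 2.5, 3.0, 4.5, 1.5, 2.0, 3.5, 5.0],
             x=[1.0, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 1.0],
             g=list("aaaabbbb"))
    ef = ps.cox_fit(df, covariates="x", strata="g")
    br = ps.cox_fit(df, covariates="x", strata="g", ties="breslow")
    assert float(ef.summary["coef"]["x"]) == pytest.approx(
        float(br.summary["coef"]["x"]), abs=1e-8)


def test_cox_single_stratum_equals_unstratified():
    rng = np.random.default_rng(4)
    df = rec(rng.exponential(8, 40) + 0.1, x=rng.integers(0, 2, 40).astype(float),
             g="only")
    f1 = ps.cox_fit(df, covariates="x", strata="g")
    f2 = ps.cox_fit(df, covariates="x", strata=None)
    assert float(f1.summary["coef"]["x"]) == pytest.approx(
        float(f2.summary["coef"]["x"]), abs=1e-8)


def test_cox_permutation_calibration():
    rng = np.random.default_rng(5)
    t = rng.exponential(10, 60) + 0.1
    x = rng.integers(0, 2, 60).astype(float)
    big_p = 0
    for _ in range(100):
        xp = rng.permutation(x)
        fit = ps.cox_fit(rec(t, x=xp), covariates="x", strata=None)
        big_p += float(fit.summary["p"]["x"]) > 0.05
    assert big_p >= 90  # permuted covariate is null; ~95% of p should exceed .05


def test_rmst_identity_and_no_censoring_mean():
    base = rec([2.0, 4.0, 6.0, 8.0])
    df = pd.concat([base.assign(diet="AL"), base.assign(diet="IF")],
                   ignore_index=True)
    r = ps.rmst_diff(df, group="diet")
    assert r.difference == pytest.approx(0.0, abs=1e-12)
    assert r.ci[0] <= 0 <= r.ci[1]
    # no censoring: RMST(tau) = mean(min(T, tau))
    tau = 5.0
    r2 = ps.rmst_diff(df, group="diet", tau=tau)
    expect = np.minimum(base["time"], tau).mean()
    assert r2.rmst["AL"] == pytest.approx(expect, abs=1e-12)


def test_rmst_equals_hand_step_quadrature():
    # 4-point curve, hand sum of S(t_i) * (t_{i+1} - t_i)
    one = rec([1.0, 2.0, 3.0, 4.0])
    rmst, _ = _rmst_one(one, 4.0)
    hand = 1.0 * 1 + 0.75 * 1 + 0.5 * 1 + 0.25 * 1
    assert rmst == pytest.approx(hand, abs=1e-12)


def test_rmst_tau_max_equals_sample_mean():
    rng = np.random.default_rng(6)
    t = rng.exponential(10, 30) + 0.5
    rmst, _ = _rmst_one(rec(t), float(t.max()))
    assert rmst == pytest.approx(t.mean(), abs=1e-10)


def test_rmst_tau_beyond_followup_raises():
    df = pd.concat([rec([1.0, 2.0], diet="AL"), rec([1.5, 2.5], diet="IF")],
                   ignore_index=True)
    with pytest.raises(DataError):
        ps.rmst_diff(df, group="diet", tau=10.0)


def test_cv_hand_value_scale_invariance_and_identity():
    df = pd.concat([
        rec([2.0, 4.0, 6.0], strain="s1", diet="AL"),
        rec([2.0, 4.0, 6.0], strain="s1", diet="IF"),
        rec([3.0, 5.0, 7.0], strain="s2", diet="AL"),
        rec([3.0, 5.0, 7.0], strain="s2", diet="IF"),
    ], ignore_index=True)
    out = ps.cv_compare(df)
    tab = out["table"].set_index(["strain", "diet"])["cv"]
    assert tab[("s1", "AL")] == pytest.approx(0.5)  # sd=2, mean=4
    assert out["p"] == 1.0  # identical groups -> all paired diffs 0
    df10 = df.assign(time=df["time"] * 10)
    out10 = ps.cv_compare(df10)
    assert np.allclose(out10["table"]["cv"], out["table"]["cv"])


def test_cv_small_cells_dropped_with_warning():
    df = pd.concat([
        rec([2.0, 4.0, 6.0], strain="s1", diet="AL"),
        rec([3.0], strain="s1", diet="IF"),
        rec([2.5, 4.5], strain="s2", diet="AL"),
        rec([3.0, 6.0], strain="s2", diet="IF"),
    ], ignore_index=True)
    with pytest.warns(UserWarning):
        out = ps.cv_compare(df)
    assert ("s1", "IF") not in out["table"].set_index(["strain", "diet"]).index


def test_lifespan_summary_columns(small_cohort):
    _, b = small_cohort
    from panelscreen.pipeline import surv_records
    tab = ps.lifespan_summary(surv_records(b.animals), by=["sex", "diet"])
    assert set(tab.columns) >= {"n", "events", "median", "q90", "rmst"}
    assert tab["n"].sum() == len(b.animals)
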