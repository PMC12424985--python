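"""Mixed-model engine: closed-form, dense-covariance, and invariance checks."""

import numpy as np
import pandas as pd
import pytest
from patsy import dmatrix

import panelscreen as ps
from panelscreen.errors import (
    DegenerateFitError, RankDeficiencyError, UsageError,
)
from panelscreen.lmm import parse_random

from conftest import anova_components


def dense_reml_loglik(df, fixed, blocks, theta_map, sigma2):
    """Independent REML evaluation through the full n x n covariance V."""
    X = np.asarray(dmatrix(fixed, df), dtype=float)
    n, p = X.shape
    V = sigma2 * np.eye(n)
    for Z, G in blocks:
        V += sigma2 * Z @ G @ Z.T
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ df["y"])
    r = df["y"].to_numpy() - X @ b
    return -0.5 * ((n - p) * np.log(2 * np.pi)
                   + np.linalg.slogdet(V)[1]
                   + np.linalg.slogdet(X.T @ Vi @ X)[1]
                   + r @ Vi @ r)


def z_intercept(df, col):
    levels = sorted(df[col].astype(str).unique())
    codes = pd.Categorical(df[col].astype(str), categories=levels).codes
    Z = np.zeros((len(df), len(levels)))
    Z[np.arange(len(df)), codes] = 1.0
    return Z


def test_no_random_terms_reduces_to_ols():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"x": rng.normal(size=30), "g": np.repeat(list("ab"), 15)})
    df["y"] = 1 + 2 * df["x"] + rng.normal(size=30)
    fit = ps.fit_lmm(ps.ModelSpec("y", "x + g"), df)
    X = np.asarray(dmatrix("x + g", df))
    bols = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
    assert np.allclose(fit.beta.to_numpy(), bols, atol=1e-10)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_balanced_oneway_matches_anova_closed_form(seed):
    """sigma_u^2 = max(0, (MSB-MSW)/n) always; at an interior optimum the
    residual also equals MSW (at the boundary REML pools the variance)."""
    rng = np.random.default_rng(seed)
    g, nrep = 6, 5
    sd_u = [1.2, 0.6, 0.0, 0.05][seed]
    y = np.repeat(rng.normal(0, sd_u, g), nrep) + rng.normal(0, 0.8, g * nrep)
    df = pd.DataFrame({"y": y, "grp": np.repeat(list("abcdef"), nrep)})
    fit = ps.fit_lmm(ps.ModelSpec("y", "1", ["(1|grp)"]), df)
    s2u, s2e, _, _ = anova_components(df, group="grp")
    assert fit.vc["(1|grp)"]["var"] == pytest.approx(s2u, abs=1e-8)
    if s2u > 0:
        assert fit.vc["residual"] == pytest.approx(s2e, abs=1e-8)
    else:
        pooled = df["y"].var(ddof=1)
        assert fit.vc["residual"] == pytest.approx(pooled, abs=1e-8)


def test_blup_shrinkage_closed_form_and_bound(oneway_data):
    fit = ps.fit_lmm(ps.ModelSpec("y", "1", ["(1|grp)"]), oneway_data)
    s2u, s2e, ybar, gm = anova_components(oneway_data)
    nrep = 6
    lam = nrep * s2u / (nrep * s2u + s2e)
    modes = fit.blups["(1|grp)"]["mode"].to_numpy()
    expected = lam * (ybar.to_numpy() - gm)
    assert np.allclose(modes, expected, atol=1e-8)
    # shrinkage: conditional modes never exceed the raw deviations
    assert (np.abs(modes) <= np.abs(ybar.to_numpy() - gm) + 1e-12).all()


def test_blups_zero_at_zero_variance():
    # group means exactly equal -> MSB = 0 -> boundary estimate, BLUPs 0
    df = pd.DataFrame({
        "y": [-1.0, 1.0, -1.0, 1.0, -2.0, 2.0],
        "grp": ["a", "a", "b", "b", "c", "c"],
    })
    fit = ps.fit_lmm(ps.ModelSpec("y", "1", ["(1|grp)"]), df)
    assert fit.vc["(1|grp)"]["var"] == 0.0
    assert (fit.blups["(1|grp)"]["mode"] == 0.0).all()


def test_mirrored_groups_give_opposite_blups():
    df = pd.DataFrame({
        "y": [1.0, 2.0, 3.0, -1.0, -2.0, -3.0],
        "grp": ["a", "a", "a", "b", "b", "b"],
    })
    fit = ps.fit_lmm(ps.ModelSpec("y", "1", ["(1|grp)"]), df)
    m = fit.blups["(1|grp)"]["mode"]
    assert m["a"] == pytest.approx(-m["b"], abs=1e-10)


@pytest.mark.parametrize("seed", range(6))
def test_reml_matches_dense_covariance(seed):
    """Profiled Woodbury REML equals the dense-V evaluation on random toys."""
    rng = np.random.default_rng(100 + seed)
    n_strain = 5 + seed % 3
    nper = 8
    n = n_strain * nper
    df = pd.DataFrame({
        "strain": np.repeat([f"s{i}" for i in range(n_strain)], nper),
        "diet": np.tile(["AL"] * (nper // 2) + ["IF"] * (nper // 2), n_strain),
    })
    df["y"] = (np.repeat(rng.normal(0, 1, n_strain), nper)
               + np.repeat(rng.normal(0, 0.8, n_strain), nper)
               * (df["diet"] == "IF")
               + rng.normal(0, 1, n))
    fit = ps.fit_lmm(ps.ModelSpec("y", "diet", ["(1+diet|strain)"]), df)
    l11, l21, l22 = fit.theta
    L2 = np.array([[l11, 0.0], [l21, l22]])
    G = np.kron(np.eye(n_strain), L2 @ L2.T)
    d = (df["diet"] == "IF").to_numpy(dtype=float)
    codes = pd.Categorical(df["strain"]).codes
    Z = np.zeros((n, 2 * n_strain))
    Z[np.arange(n), 2 * codes] = 1.0
    Z[np.arange(n), 2 * codes + 1] = d
    ll = dense_reml_loglik(df, "diet", [(Z, G)], None, fit.sigma2)
    assert fit.reml_loglik == pytest.approx(ll, abs=1e-6)


def test_kinship_term_matches_dense_covariance():
    rng = np.random.default_rng(7)
    K = ps.generate_kinship(6, seed=11)
    nper = 6
    n = 6 * nper
    df = pd.DataFrame({"strain": np.repeat(K.index, nper)})
    C = np.linalg.cholesky(K.to_numpy())
    df["y"] = np.repeat(C @ rng.normal(0, 1, 6), nper) + rng.normal(0, 1, n)
    term = ps.RandomTerm(grouping="strain", covariance="scaled_by_A", A=K,
                         name="kin")
    fit = ps.fit_lmm(ps.ModelSpec("y", "1", [term]), df)
    th = fit.theta[0]
    Z = z_intercept(df, "strain")
    ll = dense_reml_loglik(df, "1", [(Z, th ** 2 * K.to_numpy())], None,
                           fit.sigma2)
    assert fit.reml_loglik == pytest.approx(ll, abs=1e-6)


def test_lrt_identity_and_power(small_cohort):
    cfg, b = small_cohort
    ph = b.phenotypes[b.phenotypes["phenotype"] == "rdw"]
    df = ph.merge(b.animals, on="mouse_id")
    df["y"] = ps.rank_normal(df["value"])
    spec = ps.ModelSpec("y", "diet * sex", ["(1|strain)"])
    fit = ps.fit_lmm(spec, df)
    same = ps.lrt_random(fit, fit)
    assert same.estimate == 0.0 and same.p == 1.0
    # strong planted slope -> decisive rejection on one seeded dataset
    rng = np.random.default_rng(5)
    n_strain, nper = 10, 20
    d2 = pd.DataFrame({
        "strain": np.repeat([f"s{i}" for i in range(n_strain)], nper),
        "diet": np.tile(["AL"] * 10 + ["IF"] * 10, n_strain),
    })
    d2["y"] = (np.repeat(rng.normal(0, 1, n_strain), nper)
               + np.repeat(rng.normal(0, 2.0, n_strain), nper)
               * (d2["diet"] == "IF") + rng.normal(0, 1, len(d2)))
    full = ps.fit_lmm(ps.ModelSpec("y", "diet", ["(1+diet|strain)"]), d2)
    red = ps.fit_lmm(ps.ModelSpec("y", "diet", ["(1|strain)"]), d2)
    lrt = ps.lrt_random(full, red)
    assert lrt.df == 2
    assert lrt.p < 1e-3


def test_lrt_non_nested_raises(oneway_data):
    fit = ps.fit_lmm(ps.ModelSpec("y", "1", ["(1|grp)"]), oneway_data)
    other = ps.fit_lmm(ps.ModelSpec("y", "grp"), oneway_data)
    with pytest.raises(UsageError):
        ps.lrt_random(fit, other)


def test_contrast_balanced_two_group_equals_raw_difference():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({"g": np.repeat(["A", "B"], 20),
                       "y": rng.normal(size=40)})
    fit = ps.fit_lmm(ps.ModelSpec("y", "g"), df)
    c = ps.contrast_means(fit, "g")[0]
    raw = df[df["g"] == "B"]["y"].mean() - df[df["g"] == "A"]["y"].mean()
    assert c.estimate == pytest.approx(raw, abs=1e-10)


def test_contrast_matches_gls_closed_form():
    rng = np.random.default_rng(4)
    n_strain, nper = 6, 8
    df = pd.DataFrame({
        "strain": np.repeat([f"s{i}" for i in range(n_strain)], nper),
        "diet": np.tile(["AL", "IF"] * (nper // 2), n_strain),
    })
    df["y"] = np.repeat(rng.normal(0, 1, n_strain), nper) + rng.normal(
        0, 1, len(df)) + 0.7 * (df["diet"] == "IF")
    fit = ps.fit_lmm(ps.ModelSpec("y", "diet", ["(1|strain)"]), df)
    # dense GLS at fitted components
    X = np.asarray(dmatrix("diet", df))
    Z = z_intercept(df, "strain")
    th = fit.theta[0]
    V = fit.sigma2 * (th ** 2 * Z @ Z.T + np.eye(len(df)))
    Vi = np.linalg.inv(V)
    covb = np.linalg.inv(X.T @ Vi @ X)
    b = covb @ X.T @ Vi @ df["y"]
    c = np.array([0.0, 1.0])
    res = ps.contrast_means(fit, "diet")[0]
    assert res.estimate == pytest.approx(float(c @ b), abs=1e-8)
    assert res.se == pytest.approx(float(np.sqrt(c @ covb @ c)), abs=1e-8)


def test_contrast_zero_under_diet_symmetry():
    df = pd.DataFrame({
        "diet": ["AL", "IF"] * 10,
        "y": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 0.5, 0.5, 1.5, 1.5] * 2,
    })
    fit = ps.fit_lmm(ps.ModelSpec("y", "diet"), df)
    assert ps.contrast_means(fit, "diet")[0].estimate == pytest.approx(0, abs=1e-12)


def test_row_order_invariance(oneway_data):
    fit1 = ps.fit_lmm(ps.ModelSpec("y", "1", ["(1|grp)"]), oneway_data)
    perm = oneway_data.sample(frac=1.0, random_state=9).reset_index(drop=True)
    fit2 = ps.fit_lmm(ps.ModelSpec("y", "1", ["(1|grp)"]), perm)
    assert fit1.reml_loglik == pytest.approx(fit2.reml_loglik, abs=1e-9)
    assert fit1.vc["(1|grp)"]["var"] == pytest.approx(
        fit2.vc["(1|grp)"]["var"], abs=1e-9)


def test_variance_scale_equivariance(oneway_data):
    fit1 = ps.fit_lmm(ps.ModelSpec("y", "1", ["(1|grp)"]), oneway_data)
    df = oneway_data.copy()
    df["y"] = 3.0 * df["y"]
    fit3 = ps.fit_lmm(ps.ModelSpec("y", "1", ["(1|grp)"]), df)
    assert fit3.vc["(1|grp)"]["var"] == pytest.approx(
        9.0 * fit1.vc["(1|grp)"]["var"], rel=1e-6)
    assert fit3.vc["residual"] == pytest.approx(
        9.0 * fit1.vc["residual"], rel=1e-6)


def test_rank_deficiency_names_aliased_columns():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"x": rng.normal(size=20)})
    df["x2"] = 2 * df["x"]
    df["y"] = df["x"] + rng.normal(size=20)
    with pytest.raises(RankDeficiencyError) as exc:
        ps.fit_lmm(ps.ModelSpec("y", "x + x2"), df)
    assert "x2" in str(exc.value)
    fit = ps.fit_lmm(ps.ModelSpec("y", "x + x2"), df, drop_aliased=True)
    assert fit.aliased == ["x2"]


def test_degenerate_zero_residual_raises():
    df = pd.DataFrame({"g": list("aabb"), "y": [1.0, 1.0, 2.0, 2.0]})
    with pytest.raises(DegenerateFitError):
        ps.fit_lmm(ps.ModelSpec("y", "1", ["(1|g)"]), df)


def test_parse_random_strings():
    t = parse_random("(1+diet|strain)")
    assert t.grouping == "strain" and t.slope == "diet"
    assert t.covariance == "unstructured2x2"
    t2 = parse_random("(1|mouse_id)")
    assert t2.grouping == "mouse_id" and t2.covariance == "iid"
    with pytest.raises(UsageError):
        parse_random("strain")


def test_satterthwaite_reduces_to_residual_df():
    rng = np.random.default_rng(8)
    df = pd.DataFrame({"x": rng.normal(size=40),
                       "g": np.repeat([f"g{i}" for i in range(8)], 5)})
    # no group structure at all: variance pinned to the boundary
    df["y"] = 2.0 + 0.5 * df["x"] + rng.normal(size=40)
    fit = ps.fit_lmm(ps.ModelSpec("y", "x", ["(1|g)"]), df)
    c = np.array([0.0, 1.0])
    df_s = ps.satterthwaite_df(fit, c)
    if fit.vc["(1|g)"]["var"] == 0.0:
        assert df_s == pytest.approx(fit.residual_df, rel=0.02)
    else:  # small but nonzero variance: df must not exceed the OLS df
        assert 1.0 <= df_s <= fit.residual_df + 1e-9
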