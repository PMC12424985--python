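"""GxT screen: rank-normal transform, BH, model wiring, scores, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import panelscreen as ps
from panelscreen.errors import DataError, DegenerateFitError
from panelscreen.gxt import DietEffectScores


def bh_oracle(p):
    """Independent step-up computation: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


# ---------------------------------------------------------------------------
# rank-normal


def test_rank_normal_blom_n3_oracle():
    out = ps.rank_normal([10.0, -3.0, 4.0])
    # Blom fractional ranks for n=3: (r - 3/8)/(3.25)
    expect = stats.norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
    assert np.allclose(out, expect, atol=1e-12)


def test_rank_normal_antisymmetry_and_missing():
    x = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
    out = ps.rank_normal(x)
    assert np.isnan(out[-1])
    assert np.allclose(out[:4], -out[:4][::-1], atol=1e-12)


def test_rank_normal_errors():
    with pytest.raises(DataError):
        ps.rank_normal([1.0, 2.0])
    with pytest.raises(DataError):
        ps.rank_normal([5.0, 5.0, 5.0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40, unique=True))
def test_rank_normal_is_monotone(xs):
    out = ps.rank_normal(np.array(xs))
    order = np.argsort(xs)
    assert (np.diff(out[order]) > 0).all()


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_single_and_hand_example():
    assert ps.adjust_bh([0.037])[0] == pytest.approx(0.037)
    q = ps.adjust_bh([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_rejects_invalid():
    with pytest.raises(DataError):
        ps.adjust_bh([0.5, 1.2])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
def test_bh_matches_stepup_oracle(ps_list):
    q = ps.adjust_bh(ps_list)
    assert np.allclose(q, bh_oracle(ps_list), atol=1e-12)
    order = np.argsort(ps_list)
    assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# the per-phenotype model


def test_run_gxt_degenerate_input_raises(small_cohort):
    _, b = small_cohort
    ph = b.phenotypes[b.phenotypes["phenotype"] == "rdw"].copy()
    # constant within strain x diet x sex with zero noise
    key = ph.merge(b.animals[["mouse_id", "strain", "sex", "diet"]],
                   on="mouse_id")
    ph["value"] = (pd.Categorical(key["strain"]).codes * 4
                   + (key["diet"] == "IF") * 2 + (key["sex"] == "M")).astype(float)
    with pytest.raises((DegenerateFitError, DataError)):
        ps.run_gxt(ph, b.animals, include_mouse=False, include_batch=False)


def test_run_gxt_rank_invariance(small_cohort):
    _, b = small_cohort
    ph = b.phenotypes[b.phenotypes["phenotype"] == "hgb"]
    r1 = ps.run_gxt(ph, b.animals, include_mouse=False)
    ph2 = ph.assign(value=np.exp(ph["value"] / 2.0))  # strictly monotone
    r2 = ps.run_gxt(ph2, b.animals, include_mouse=False)
    assert r1.diet_p == pytest.approx(r2.diet_p, abs=1e-10)
    assert r1.gxt_stat == pytest.approx(r2.gxt_stat, abs=1e-8)
    assert r1.rho == pytest.approx(r2.rho, abs=1e-8)


def test_run_gxt_recovers_negative_rho():
    cfg = ps.SimConfig(n_strains=10, mice_per_cell=8, strain_sd=2.0,
                       diet_slope_sd=1.0, intercept_slope_corr=-0.8,
                       residual_sd=1.0, timepoint_schedule=(45, 97),
                       phenotype_names=("p1",), seed=12)
    b = ps.simulate(cfg)
    r = ps.run_gxt(b.phenotypes[b.phenotypes["phenotype"] == "p1"],
                   b.animals, include_mouse=False)
    assert np.sign(r.rho) == -1.0
    assert abs(r.rho) <= 1.0


def test_run_gxt_screen_adds_bh_columns(small_cohort):
    _, b = small_cohort
    res = ps.run_gxt_screen(b.phenotypes, b.animals, include_mouse=False,
                            phenotype_names=["rdw", "hgb"])
    tab = ps.gxt_table(res)
    assert set(tab.index) == {"rdw", "hgb"}
    assert (tab["diet_q"] >= tab["diet_p"] - 1e-12).all()
    assert (tab["gxt_q"] >= tab["gxt_p"] - 1e-12).all()
    assert (tab["rho"].abs() <= 1.0).all()


# ---------------------------------------------------------------------------
# diet-effect scores


@pytest.fixture(scope="module")
def screen_results():
    cfg = ps.SimConfig(n_strains=8, mice_per_cell=6, strain_sd=1.5,
                       diet_slope_sd=1.0, residual_sd=1.0,
                       timepoint_schedule=(45, 97),
                       phenotype_names=("p1", "p2", "p3"), seed=21)
    b = ps.simulate(cfg)
    return b, ps.run_gxt_screen(b.phenotypes, b.animals, include_mouse=False)


def test_scores_are_blup_plus_stratum_contrast(screen_results):
    b, res = screen_results
    scores = ps.diet_effect_scores(res)
    key = sorted(scores.scores)[0]
    mat = scores.scores[key]
    for ph in mat.index:
        fit = res[ph].fit
        blup = fit.blup_table("(1+diet|strain)")["slope"]
        cs = {c.name.split("|")[-1]: c.estimate
              for c in ps.contrast_means(fit, "diet", by=["sex", "timepoint"])}
        expect = blup + cs[",".join(key)]
        assert np.allclose(mat.loc[ph].to_numpy(), expect.to_numpy(), atol=1e-8)


def test_scaled_scores_are_zscored_within_strain(screen_results):
    _, res = screen_results
    scores = ps.diet_effect_scores(res)
    for mat in scores.scaled.values():
        assert np.allclose(mat.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(mat.std(axis=0, ddof=1), 1.0, atol=1e-10)


def test_shrinkage_limit_scores_equal_population_contrast():
    cfg = ps.SimConfig(n_strains=6, mice_per_cell=6, strain_sd=1.0,
                       diet_slope_sd=0.0, residual_sd=1.0,
                       timepoint_schedule=(45,), phenotype_names=("p1", "p2"),
                       seed=30)
    b = ps.simulate(cfg)
    res = ps.run_gxt_screen(b.phenotypes, b.animals, include_mouse=False)
    scores = ps.diet_effect_scores(res)
    for ph, r in res.items():
        blup = r.fit.blup_table("(1+diet|strain)")["slope"]
        if (blup == 0.0).all():  # slope variance at the boundary
            for key, mat in scores.scores.items():
                assert mat.loc[ph].nunique() == 1


# ---------------------------------------------------------------------------
# clustering and strain selection


def test_cluster_planted_blocks_recovered():
    rng = np.random.default_rng(0)
    base = np.array([[5.0] * 4 + [0.0] * 4 + [0.0] * 4,
                     [0.0] * 4 + [5.0] * 4 + [0.0] * 4,
                     [0.0] * 4 + [0.0] * 4 + [5.0] * 4])
    M = np.repeat(base, 3, axis=0) + rng.normal(0, 0.1, (9, 12))
    mat = pd.DataFrame(M, index=[f"p{i}" for i in range(9)],
                       columns=[f"s{i}" for i in range(12)])
    cr = ps.cluster_scores(mat, k=3)
    labels = cr.row_labels.to_numpy()
    for block in (labels[:3], labels[3:6], labels[6:]):
        assert len(set(block)) == 1
    assert len(set(labels)) == 3
    cols = cr.col_labels.to_numpy()
    for block in (cols[:4], cols[4:8], cols[8:]):
        assert len(set(block)) == 1


def test_cluster_identical_rows_and_determinism():
    mat = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 8.0, 7.0]],
                       index=list("abc"), columns=list("xyz"))
    c1 = ps.cluster_scores(mat, k=2)
    c2 = ps.cluster_scores(mat, k=2)
    assert c1.row_labels["a"] == c1.row_labels["b"]
    assert c1.row_labels.equals(c2.row_labels)
    assert c1.row_order == c2.row_order


def test_cluster_constant_matrix_degenerates_with_warning():
    mat = pd.DataFrame(np.ones((3, 3)))
    with pytest.warns(UserWarning):
        cr = ps.cluster_scores(mat)
    assert set(cr.row_labels) == {1}


def test_cluster_respects_reference_row_order():
    rng = np.random.default_rng(1)
    mat = pd.DataFrame(rng.normal(size=(4, 4)), index=list("abcd"))
    order = ["d", "a", "c", "b"]
    cr = ps.cluster_scores(mat, k=2, row_order=order)
    assert cr.row_order == order


def test_select_model_strains_examples_and_bruteforce():
    sel = ps.select_model_strains({"A": -1.0, "B": 0.0, "C": 2.0})
    assert sel["max_strain"] == "C" and sel["min_strain"] == "A"
    sel_tie = ps.select_model_strains({"B": 1.0, "A": 1.0, "C": 0.0})
    assert sel_tie["max_strain"] == "A"  # lexicographic tie-break
    rng = np.random.default_rng(2)
    for _ in range(20):
        v = pd.Series(rng.normal(size=8), index=[f"s{i}" for i in range(8)])
        sel = ps.select_model_strains(v)
        assert v[sel["max_strain"]] == v.max()
        assert v[sel["min_strain"]] == v.min()
    with pytest.raises(DataError):
        ps.select_model_strains({"A": np.nan})
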