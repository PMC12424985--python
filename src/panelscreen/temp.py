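"""Penalized-spline additive mixed model for body temperature on scaled age.

Temperature is modeled as parametric sex + strain (+ diet) effects plus
cubic P-spline smooths of proportion of life lived and of 6-month body
weight, with a per-mouse random intercept.  Each smooth is a cubic
B-spline basis with a second-difference penalty; the penalty null space
(the linear trend) stays in the fixed effects and the penalized range
space becomes an iid random-coefficient block, so smoothing parameters
are selected by the same REML machinery used for every other mixed model
in the package.  Late-life inflection is localized with a continuous
two-segment (broken-stick) least-squares fit over a candidate-knot grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from .errors import DataError, UsageError
from .lmm import ModelSpec, RandomTerm, fit_lmm, LMMFit


# ---------------------------------------------------------------------------
# basis construction


def _bspline_basis(x: np.ndarray, k: int):
    """Cubic B-spline design with k basis functions, equally spaced knots."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise DataError("covariate has no spread for a smooth term")
    pad = 1e-8 * (hi - lo)
    inner = np.linspace(lo, hi, k - 2)
    t = np.concatenate([[lo - pad] * 3, inner, [hi + pad] * 3])
    B = BSpline.design_matrix(np.clip(x, lo, hi), t, 3).toarray()
    return B, t


def _smooth_blocks(x: np.ndarray, k: int, name: str):
    """Split a penalized B-spline into fixed (null-space) and random
    (wiggle) blocks via the eigendecomposition of the second-difference
    penalty."""
    nuniq = len(np.unique(x))
    if k > nuniq:
        warnings.warn(f"{name}: basis dimension {k} > {nuniq} distinct values; "
                      f"reducing to {max(4, nuniq)}")
        k = max(4, nuniq)
    B, _ = _bspline_basis(x, k)
    D = np.diff(np.eye(k), n=2, axis=0)
    S = D.T @ D
    w, U = np.linalg.eigh(S)
    null = w < 1e-10 * w.max()
    Xf = B @ U[:, null]               # spans constant + linear trend
    Zr = B @ U[:, ~null] / np.sqrt(w[~null])
    return Xf, Zr, k


@dataclass
class GAMMFit:
    """Fitted additive mixed model for temperature."""

    fit: LMMFit
    smooths: dict          # name -> {"edf", "lambda", "k"}
    parametric: pd.Series
    deviance: float        # -2 x (profiled) ML log-likelihood
    reml_loglik: float
    n: int
    include_diet: bool
    n_parametric: int


def _edf_by_block(fit: LMMFit) -> dict:
    """Effective degrees of freedom per random block from the augmented
    (penalized) normal equations at the fitted smoothing parameters."""
    mm = fit._mm
    ths = mm.split(fit.theta)
    A = np.hstack([td.build_A(th) for td, th in zip(mm.terms, ths)]) if mm.q else None
    X = mm.X
    C = np.hstack([X, A]) if A is not None else X
    p = X.shape[1]
    CtC = C.T @ C
    Dpen = np.zeros_like(CtC)
    Dpen[p:, p:] = np.eye(C.shape[1] - p)
    F = np.linalg.solve(CtC + Dpen, CtC)
    d = np.diag(F)
    out = {"_fixed": float(d[:p].sum())}
    for td, sl in zip(mm.terms, mm.slices):
        out[td.term.name] = float(d[p + sl.start: p + sl.stop].sum())
    return out


def fit_temp_gamm(data: pd.DataFrame, include_diet: bool = False,
                  k: int = 10, lambdas: dict | None = None) -> GAMMFit:
    """Fit the temperature GAMM.

    ``data`` needs columns mouse_id, pll, value (temperature), sex,
    strain, bw6mo (and diet when ``include_diet``).  ``lambdas`` pins the
    smoothing parameters {'s(pll)': l1, 's(bw6mo)': l2, '(1|mouse_id)': l3}
    instead of REML selection (theta_k = 1/sqrt(lambda_k)).
    """
    need = {"mouse_id", "pll", "value", "sex", "strain", "bw6mo"}
    if include_diet:
        need.add("diet")
    missing = need - set(data.columns)
    if missing:
        raise DataError(f"missing columns: {sorted(missing)}")
    df = data.dropna(subset=sorted(need)).copy()
    if len(df) < 100:
        raise DataError("temperature GAMM needs n >= 100")

    Xf1, Zr1, k1 = _smooth_blocks(df["pll"].to_numpy(dtype=float), k, "s(pll)")
    Xf2, Zr2, k2 = _smooth_blocks(df["bw6mo"].to_numpy(dtype=float), k, "s(bw6mo)")
    # null spaces contain a constant each; keep the linear part only and let
    # the parametric intercept carry the level
    for j, (Xf, tag) in enumerate(((Xf1, "pll"), (Xf2, "bw6mo"))):
        for c in range(Xf.shape[1]):
            df[f"_{tag}_f{c}"] = Xf[:, c]
    fixed = "sex + strain"
    if include_diet:
        fixed += " + diet"
    fixed += " + " + " + ".join(
        [f"_pll_f{c}" for c in range(Xf1.shape[1])]
        + [f"_bw6mo_f{c}" for c in range(Xf2.shape[1])]
    )
    random = [
        RandomTerm(covariance="iid_matrix", Z=Zr1, name="s(pll)"),
        RandomTerm(covariance="iid_matrix", Z=Zr2, name="s(bw6mo)"),
        RandomTerm(grouping="mouse_id"),
    ]
    fixed_theta = None
    if lambdas is not None:
        order = ["s(pll)", "s(bw6mo)", "(1|mouse_id)"]
        fixed_theta = [1.0 / np.sqrt(float(lambdas[name])) for name in order]
    fit = fit_lmm(ModelSpec("value", fixed, random), df, drop_aliased=True,
                  fixed_theta=fixed_theta)
    edf = _edf_by_block(fit)
    smooths = {}
    for name, kk in (("s(pll)", k1), ("s(bw6mo)", k2)):
        th = fit.theta[["s(pll)", "s(bw6mo)", "(1|mouse_id)"].index(name)]
        lam = float(1.0 / th ** 2) if th > 0 else np.inf
        # +1 for the linear null-space column carried in the fixed effects
        smooths[name] = {"edf": edf[name] + 1.0, "lambda": lam, "k": kk}
    n_parametric = sum(1 for b in fit.beta.index if not b.startswith("_"))
    return GAMMFit(
        fit=fit, smooths=smooths,
        parametric=fit.beta[[b for b in fit.beta.index if not b.startswith("_")]],
        deviance=-2.0 * fit.loglik_ml, reml_loglik=fit.reml_loglik,
        n=fit.n_obs, include_diet=include_diet, n_parametric=n_parametric,
    )


def compare_deviance(fit_with: GAMMFit, fit_without: GAMMFit) -> dict:
    """Analysis-of-deviance chi-square test for added parametric terms."""
    if fit_with.n != fit_without.n:
        raise UsageError("deviance comparison requires identical data")
    with_names = set(fit_with.parametric.index)
    without_names = set(fit_without.parametric.index)
    if not without_names <= with_names:
        raise UsageError("models are not nested in their parametric terms")
    df = len(with_names) - len(without_names)
    stat = max(0.0, fit_without.deviance - fit_with.deviance)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return {"statistic": stat, "df": df, "p": p}


# ---------------------------------------------------------------------------
# broken-stick inflection localization


@dataclass
class InflectionEstimate:
    pll_star: float
    slope_pre: float
    slope_post: float
    rss_single: float
    rss_broken: float
    improvement: float
    found: bool


def locate_inflection(pll, values, grid=None,
                      min_improvement: float = 0.01) -> InflectionEstimate:
    """Continuous two-segment least squares over a candidate-knot grid.

    The knot minimizing the residual sum of squares over a 0.01-step grid
    in [0.5, 0.95] is returned with the segment slopes; when the best
    broken stick improves on the single line by less than
    ``min_improvement`` (relative RSS) the result is flagged as
    'no inflection'.
    """
    pll = np.asarray(pll, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = ~(np.isnan(pll) | np.isnan(y))
    pll, y = pll[ok], y[ok]
    if len(np.unique(np.round(pll, 12))) < 10:
        raise DataError("inflection search needs >= 10 distinct PLL values")
    if grid is None:
        grid = np.round(np.arange(0.50, 0.9501, 0.01), 10)
    X0 = np.column_stack([np.ones_like(pll), pll])
    b0, rss0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss0 = float(np.sum((y - X0 @ b0) ** 2))
    best = (np.inf, np.nan, None)
    for t0 in grid:
        X = np.column_stack([np.ones_like(pll), pll, np.clip(pll - t0, 0.0, None)])
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ b) ** 2))
        if rss < best[0] - 1e-14:
            best = (rss, float(t0), b)
    rss1, t_star, b = best
    tss = float(np.sum((y - y.mean()) ** 2))
    if rss0 <= 1e-12 * max(tss, 1.0):  # single line already interpolates
        improvement = 0.0
    else:
        improvement = 1.0 - rss1 / rss0
    found = improvement >= min_improvement
    return InflectionEstimate(
        pll_star=t_star if found else float("nan"),
        slope_pre=float(b[1]), slope_post=float(b[1] + b[2]),
        rss_single=rss0, rss_broken=rss1,
        improvement=float(improvement), found=found,
    )
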