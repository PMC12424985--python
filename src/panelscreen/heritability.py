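"""Broad- and narrow-sense heritability from strain-replicate designs.

H^2 comes from a strain random-intercept model, h^2 from the same model
with the strain covariance proportional to a kinship matrix K (rescaled to
mean diagonal 1).  Replicates are never collapsed to strain means, which
would bias heritability upward.  Confidence intervals are available by
inverting the REML profile likelihood of the variance ratio or by a strain
bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError, InvalidDesignError
from .lmm import ModelSpec, RandomTerm, fit_lmm, LMMFit, _ModelMatrices

CHI2_1_95 = float(stats.chi2.ppf(0.95, 1))


@dataclass
class HeritabilityEstimate:
    kind: str  # "H2" or "h2"
    estimate: float
    ci: tuple
    ci_method: str | None
    proportions: dict  # fixed / strain (or kinship) / residual shares
    fit: LMMFit
    boundary: bool = False


def rescale_kinship(K: pd.DataFrame, subset=None) -> pd.DataFrame:
    """Subset a kinship matrix and rescale it to mean diagonal exactly 1."""
    if subset is not None:
        unknown = [s for s in subset if s not in K.index]
        if unknown:
            raise DataError(f"strains not in kinship matrix: {unknown}")
        K = K.loc[list(subset), list(subset)]
    M = K.to_numpy(dtype=float)
    M = 0.5 * (M + M.T)
    d = float(np.mean(np.diag(M)))
    if d <= 0:
        raise DataError("kinship matrix has non-positive mean diagonal")
    M = M / d
    w = np.linalg.eigvalsh(M)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise DataError("kinship matrix is not PSD after rescaling")
    return pd.DataFrame(M, index=K.index, columns=K.columns)


def _prepare(data: pd.DataFrame, response: str, covariates: str):
    if data["strain"].nunique() < 2:
        raise InvalidDesignError("heritability needs >= 2 strains")
    if data.groupby("strain").size().min() < 2:
        raise InvalidDesignError("heritability needs >= 2 replicates per strain")
    return data.dropna(subset=[response]).copy()


def _variance_proportions(fit: LMMFit, term_name: str) -> dict:
    """Shares of total variance: var(X beta-hat), strain, residual."""
    mm = fit._mm
    xb = mm.X @ fit.beta.to_numpy()
    v_fixed = float(np.var(xb))
    v_strain = float(fit.vc[term_name]["var"])
    v_resid = float(fit.vc["residual"])
    total = v_fixed + v_strain + v_resid
    return {
        "fixed": v_fixed / total,
        "strain": v_strain / total,
        "residual": v_resid / total,
        "total_variance": total,
    }


def _estimate(data, response, covariates, term: RandomTerm, kind: str,
              ci_method, B, seed) -> HeritabilityEstimate:
    df = _prepare(data, response, covariates)
    spec = ModelSpec(response, covariates, [term])
    fit = fit_lmm(spec, df)
    v_g = float(fit.vc[term.name]["var"])
    v_e = float(fit.vc["residual"])
    est = v_g / (v_g + v_e) if (v_g + v_e) > 0 else 0.0
    props = _variance_proportions(fit, term.name)
    boundary = v_g <= 1e-12 * (v_g + v_e)
    ci = (np.nan, np.nan)
    if ci_method == "profile":
        ci = _profile_ci(fit, est)
    elif ci_method == "bootstrap":
        ci = _bootstrap_ci(df, response, covariates, term, B=B, seed=seed)
    elif ci_method is not None:
        raise DataError(f"unknown ci method {ci_method!r}")
    return HeritabilityEstimate(kind=kind, estimate=float(est), ci=ci,
                                ci_method=ci_method, proportions=props,
                                fit=fit, boundary=boundary)


def estimate_H2(data: pd.DataFrame, response: str = "lifespan_months",
                covariates: str = "sex * diet", ci: str | None = None,
                B: int = 500, seed: int = 0) -> HeritabilityEstimate:
    """Broad-sense heritability: strain intercept variance over strain +
    residual variance, adjusting for the fixed covariates."""
    return _estimate(data, response, covariates, RandomTerm(grouping="strain"),
                     "H2", ci, B, seed)


def estimate_h2(data: pd.DataFrame, K: pd.DataFrame,
                response: str = "lifespan_months",
                covariates: str = "sex * diet", ci: str | None = None,
                B: int = 500, seed: int = 0) -> HeritabilityEstimate:
    """Narrow-sense heritability with strain covariance sigma_g^2 K.

    K is rescaled to mean diagonal 1, so sigma_g^2/(sigma_g^2 + sigma^2)
    is the additive variance share on the same scale as H^2.
    """
    strains = sorted(data["strain"].astype(str).unique())
    Kr = rescale_kinship(K, subset=strains)
    term = RandomTerm(grouping="strain", covariance="scaled_by_A", A=Kr,
                      name="kinship(strain)")
    return _estimate(data, response, covariates, term, "h2", ci, B, seed)


# ---------------------------------------------------------------------------
# confidence intervals


def _profile_ci(fit: LMMFit, est: float, level: float = 0.95) -> tuple:
    """Invert the REML profile likelihood of the variance-ratio parameter.

    The single covariance parameter theta is the relative strain SD;
    heritability is theta^2/(1+theta^2), a monotone map, so profiling
    theta profiles the heritability.
    """
    mm: _ModelMatrices = fit._mm
    cut = stats.chi2.ppf(level, 1)
    th_hat = float(fit.theta[0])
    ll_hat = fit.reml_loglik

    def deficit(th):
        return 2.0 * (ll_hat - mm.loglik(np.array([th]))) - cut

    # lower endpoint
    if th_hat <= 1e-10 or deficit(0.0) <= 0:
        lo_th = 0.0
    else:
        lo_th = optimize.brentq(deficit, 0.0, th_hat, xtol=1e-12, rtol=1e-14)
    # upper endpoint: expand until the deficit is positive
    hi = max(2.0 * th_hat, 1.0)
    for _ in range(60):
        if deficit(hi) > 0:
            break
        hi *= 2.0
    else:
        return (lo_th ** 2 / (1 + lo_th ** 2), 1.0)
    hi_th = optimize.brentq(deficit, max(th_hat, 1e-12), hi, xtol=1e-12, rtol=1e-14)
    return (lo_th ** 2 / (1 + lo_th ** 2), hi_th ** 2 / (1 + hi_th ** 2))


def _bootstrap_ci(df, response, covariates, term: RandomTerm,
                  B: int = 500, seed: int = 0, level: float = 0.95) -> tuple:
    """Percentile CI from resampling strains (the exchangeable unit) with
    replacement; duplicated strains are relabelled as distinct."""
    if B < 50:
        warnings.warn("bootstrap with B < 50 is unreliable")
    rng = np.random.default_rng(seed)
    strains = sorted(df["strain"].astype(str).unique())
    groups = {s: df[df["strain"].astype(str) == s] for s in strains}
    ests = []
    for b in range(B):
        pick = rng.choice(strains, size=len(strains), replace=True)
        parts = []
        for i, s in enumerate(pick):
            g = groups[s].copy()
            g["strain"] = f"bs{i}_{s}"
            parts.append(g)
        bs = pd.concat(parts, ignore_index=True)
        if term.covariance == "scaled_by_A":
            K = term.A
            lbl = [f"bs{i}_{s}" for i, s in enumerate(pick)]
            Kb = pd.DataFrame(K.loc[pick, pick].to_numpy(), index=lbl, columns=lbl)
            t = RandomTerm(grouping="strain", covariance="scaled_by_A",
                           A=rescale_kinship(Kb), name=term.name)
        else:
            t = term
        try:
            f = fit_lmm(ModelSpec(response, covariates, [t]), bs)
            v_g = float(f.vc[t.name]["var"])
            v_e = float(f.vc["residual"])
            ests.append(v_g / (v_g + v_e))
        except Exception:
            continue
    if not ests:
        raise DataError("all bootstrap refits failed")
    a = (1 - level) / 2
    return (float(np.quantile(ests, a)), float(np.quantile(ests, 1 - a)))


def heritability_ci(fit_or_est, method: str = "profile", B: int = 500,
                    seed: int = 0) -> tuple:
    """CI for an existing heritability estimate (profile or bootstrap)."""
    est = fit_or_est
    if method == "profile":
        return _profile_ci(est.fit, est.estimate)
    if method == "bootstrap":
        mm = est.fit._mm
        term = est.fit.spec.random_terms()[0]
        return _bootstrap_ci(mm.data, est.fit.spec.response, est.fit.spec.fixed,
                             term, B=B, seed=seed)
    raise DataError(f"unknown ci method {method!r}")
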