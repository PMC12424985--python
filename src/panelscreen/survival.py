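"""Lifespan analysis: Kaplan-Meier, log-rank, stratified Cox, RMST, CV.

Product-limit estimation, rank tests, and the stratified proportional
hazards model delegate to lifelines; restricted-mean inference (area under
the KM curve with a Greenwood-based variance) and the coefficient-of-
variation comparison are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import KaplanMeierFitter, CoxPHFitter
from lifelines.statistics import multivariate_logrank_test, logrank_test

from .errors import DataError, UsageError
from .gxt import adjust_bh


@dataclass
class KMCurve:
    """Kaplan-Meier estimate: event-time grid with survival and Greenwood SE."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    se: np.ndarray
    n: int

    def quantile(self, q: float) -> float:
        """Smallest t with S(t) <= 1 - q; NaN when never reached."""
        below = self.survival <= (1.0 - q) + 1e-12
        if not below.any():
            return float("nan")
        return float(self.times[np.argmax(below)])


@dataclass
class RMSTResult:
    tau: float
    rmst: dict
    difference: float
    se: float
    ci: tuple
    p: float


def _check_records(records: pd.DataFrame):
    if records is None or not len(records):
        raise DataError("empty survival records")
    if (records["time"] <= 0).any():
        raise DataError("survival times must be positive")


def km_fit(records: pd.DataFrame) -> KMCurve:
    """Product-limit survival estimate from (time, event) records."""
    _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], event_observed=records["event"])
    tab = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    # Greenwood SE recomputed directly (lifelines exposes only log-based CIs)
    at_risk = tab["at_risk"].to_numpy(dtype=float)
    d = tab["observed"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(at_risk * (at_risk - d) > 0, d / (at_risk * (at_risk - d)), 0.0)
    se = surv * np.sqrt(np.cumsum(term))
    return KMCurve(times=times, survival=surv, at_risk=at_risk, events=d,
                   se=se, n=len(records))


def survival_quantile(curve: KMCurve, q: float) -> float:
    """Lifespan quantile (q=0.5 median, q=0.9 maximum-lifespan proxy)."""
    if curve.events.sum() < 1:
        return float("nan")
    return curve.quantile(q)


def logrank(records: pd.DataFrame, group: str, pairwise: bool = False) -> pd.DataFrame:
    """Log-rank test across groups; pairwise mode BH-adjusts all pairs."""
    _check_records(records)
    levels = sorted(records[group].astype(str).unique())
    if len(levels) < 2:
        raise DataError("log-rank needs >= 2 groups")
    if not pairwise:
        res = multivariate_logrank_test(
            records["time"], records[group].astype(str), records["event"]
        )
        return pd.DataFrame({
            "statistic": [res.test_statistic],
            "df": [len(levels) - 1],
            "p": [res.p_value],
        })
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a = records[records[group].astype(str) == levels[i]]
            b = records[records[group].astype(str) == levels[j]]
            r = logrank_test(a["time"], b["time"], a["event"], b["event"])
            rows.append((levels[i], levels[j], r.test_statistic, r.p_value))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p"])
    out["q"] = adjust_bh(out["p"].to_numpy())
    return out


@dataclass
class BreslowCoxFit:
    """Minimal Cox fit with the Breslow ties approximation (own Newton)."""

    summary: pd.DataFrame
    loglik: float


def _breslow_cox(records: pd.DataFrame, covariates: str,
                 strata: str | None) -> BreslowCoxFit:
    from patsy import dmatrix

    dm = dmatrix(covariates + " - 1" if "~" not in covariates else covariates,
                 records, return_type="dataframe")
    # drop the implicit intercept column if patsy kept one
    dm = dm.loc[:, [c for c in dm.columns if c != "Intercept"]]
    X = dm.to_numpy(dtype=float)
    names = list(dm.columns)
    groups = records.groupby(strata) if strata else [(None, records)]
    beta = np.zeros(X.shape[1])
    for _ in range(100):
        grad = np.zeros_like(beta)
        H = np.zeros((len(beta), len(beta)))
        ll = 0.0
        for _, sub in groups:
            idx = sub.index
            Xi = X[records.index.get_indexer(idx)]
            t = sub["time"].to_numpy(dtype=float)
            e = sub["event"].to_numpy(dtype=int)
            order = np.argsort(t, kind="stable")
            Xi, t, e = Xi[order], t[order], e[order]
            eta = Xi @ beta
            w = np.exp(eta)
            for ut in np.unique(t[e == 1]):
                at_risk = t >= ut
                d = (t == ut) & (e == 1)
                sw = w[at_risk].sum()
                sx = (w[at_risk, None] * Xi[at_risk]).sum(axis=0)
                sxx = (w[at_risk, None, None]
                       * Xi[at_risk, :, None] * Xi[at_risk, None, :]).sum(axis=0)
                dcount = int(d.sum())
                ll += eta[d].sum() - dcount * np.log(sw)
                grad += Xi[d].sum(axis=0) - dcount * sx / sw
                H -= dcount * (sxx / sw - np.outer(sx, sx) / sw ** 2)
        step = np.linalg.solve(H, -grad)
        beta = beta + step
        if np.abs(grad).max() < 1e-12:
            break
    se = np.sqrt(np.diag(np.linalg.inv(-H)))
    z = beta / se
    tab = pd.DataFrame({"coef": beta, "se(coef)": se, "z": z,
                        "p": 2 * stats.norm.sf(np.abs(z)),
                        "exp(coef)": np.exp(beta)}, index=pd.Index(names,
                                                                   name="covariate"))
    return BreslowCoxFit(summary=tab, loglik=float(ll))


def cox_fit(records: pd.DataFrame, covariates: str = "diet * sex",
            strata: str | None = "strain", cluster: str | None = None,
            ties: str = "efron"):
    """Stratified Cox proportional-hazards fit (Efron ties by default).

    ``cluster`` switches to a cluster-robust sandwich covariance (the cage
    sensitivity analysis).  ``ties='breslow'`` uses an in-package Newton on
    the Breslow partial likelihood instead.  Returns a fitted model whose
    summary table carries coef, SE, z and p per covariate.
    """
    _check_records(records)
    if ties not in ("efron", "breslow"):
        raise UsageError("ties must be 'efron' or 'breslow'")
    if ties == "breslow":
        if cluster:
            raise UsageError("cluster-robust SEs only with the efron path")
        return _breslow_cox(records.reset_index(drop=True), covariates, strata)
    cols = ["time", "event"]
    import re as _re

    varnames = sorted(set(_re.findall(r"[A-Za-z_]\w*", covariates)))
    varnames = [v for v in varnames if v in records.columns]
    cols += varnames
    if strata:
        if records.groupby(strata)["event"].sum().min() < 1:
            raise DataError("each stratum needs at least one event")
        cols.append(strata)
    if cluster:
        cols.append(cluster)
    df = records[sorted(set(cols))].copy()
    cph = CoxPHFitter(baseline_estimation_method="breslow")
    kwargs = {}
    if strata:
        kwargs["strata"] = [strata]
    if cluster:
        kwargs["cluster_col"] = cluster
        kwargs["robust"] = True
    try:
        cph.fit(df, duration_col="time", event_col="event", formula=covariates,
                fit_options={"precision": 1e-12, "max_steps": 500}, **kwargs)
    except Exception as exc:  # monotone likelihood / separation
        raise DataError(f"Cox fit failed (possible separation): {exc}") from exc
    return cph


def _rmst_one(records: pd.DataFrame, tau: float):
    """RMST on [0, tau] with the Greenwood-based large-sample variance."""
    curve = km_fit(records)
    # step-function grid clipped at tau, starting at S(0)=1
    times = np.concatenate([[0.0], curve.times])
    surv = np.concatenate([[1.0], curve.survival])
    keep = times < tau
    grid_t = np.concatenate([times[keep], [tau]])
    grid_s = surv[keep]
    rmst = float(np.sum(grid_s * np.diff(grid_t)))
    # variance: sum over event times t_i <= tau of A_i^2 d_i / (n_i (n_i - d_i))
    var = 0.0
    for t_i, n_i, d_i in zip(curve.times, curve.at_risk, curve.events):
        if t_i >= tau or d_i == 0:
            continue
        mask = grid_t[:-1] >= t_i
        area_after = float(np.sum(grid_s[mask[: len(grid_s)]] * np.diff(grid_t)[mask]))
        denom = n_i * (n_i - d_i)
        if denom > 0:
            var += area_after ** 2 * d_i / denom
    return rmst, var


def rmst_diff(records: pd.DataFrame, group: str = "diet",
              tau: float | None = None) -> RMSTResult:
    """Restricted-mean survival difference between two groups.

    tau defaults to the minimum over groups of each group's largest
    observed time; a requested tau beyond follow-up raises.
    """
    _check_records(records)
    levels = sorted(records[group].astype(str).unique())
    if len(levels) != 2:
        raise UsageError(f"rmst_diff compares exactly 2 groups, got {levels}")
    max_by_group = records.groupby(records[group].astype(str))["time"].max()
    tau_max = float(max_by_group.min())
    if tau is None:
        tau = tau_max
    elif tau > tau_max + 1e-9:
        raise DataError(f"tau={tau} beyond follow-up (max common time {tau_max})")
    vals, var = {}, {}
    for lv in levels:
        r, v = _rmst_one(records[records[group].astype(str) == lv], tau)
        vals[lv], var[lv] = r, v
    diff = vals[levels[1]] - vals[levels[0]]
    se = float(np.sqrt(var[levels[0]] + var[levels[1]]))
    z = diff / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
    ci = (diff - 1.959963984540054 * se, diff + 1.959963984540054 * se)
    return RMSTResult(tau=float(tau), rmst=vals, difference=float(diff),
                      se=se, ci=ci, p=p)


def cv_compare(records: pd.DataFrame, strata: str = "strain",
               group: str = "diet") -> dict:
    """Coefficient of variation (sd/mean) per stratum x group, with an exact
    Wilcoxon signed-rank test on the paired per-stratum CV differences."""
    import warnings

    _check_records(records)
    rows = []
    for (st, g), sub in records.groupby([strata, group]):
        if len(sub) < 2:
            warnings.warn(f"dropping {strata}={st}, {group}={g}: n<2")
            continue
        rows.append((st, g, float(sub["time"].std(ddof=1) / sub["time"].mean()),
                     len(sub)))
    tab = pd.DataFrame(rows, columns=[strata, group, "cv", "n"])
    wide = tab.pivot(index=strata, columns=group, values="cv").dropna()
    levels = sorted(records[group].astype(str).unique())
    if len(levels) != 2 or len(wide) < 1:
        raise UsageError("cv_compare needs two groups with paired strata")
    d = (wide[levels[1]] - wide[levels[0]]).to_numpy()
    if np.allclose(d, 0.0):
        p = 1.0
    else:
        try:
            p = float(stats.wilcoxon(d, zero_method="wilcox", mode="exact").pvalue)
        except ValueError:
            p = 1.0
    return {"table": tab, "paired_diff": d, "p": p}


def lifespan_summary(records: pd.DataFrame, by: list) -> pd.DataFrame:
    """Per-group n, events, median and 90th-percentile lifespan, RMST."""
    rows = []
    for key, sub in records.groupby(by):
        curve = km_fit(sub)
        key = key if isinstance(key, tuple) else (key,)
        rmst, _ = _rmst_one(sub, float(sub["time"].max()))
        rows.append(key + (len(sub), int(sub["event"].sum()),
                           survival_quantile(curve, 0.5),
                           survival_quantile(curve, 0.9), rmst))
    return pd.DataFrame(rows, columns=list(by) + ["n", "events", "median", "q90", "rmst"])
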