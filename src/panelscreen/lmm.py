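"""Restricted-maximum-likelihood linear mixed models with crossed random terms.

The engine fits Gaussian mixed models

    y = X beta + sum_k Z_k u_k + eps,   u_k ~ N(0, sigma^2 Gamma_k(theta)),
    eps ~ N(0, sigma^2 I),

where each random term contributes either iid intercepts, a correlated
(intercept, slope) pair per group with an unstructured 2x2 covariance, a
group-level effect with covariance proportional to a known relatedness
matrix A (e.g. a strain kinship matrix), or an explicit iid-coefficient
design block (used for penalized splines).

All covariance blocks are parameterized on the relative (residual-free)
scale through Cholesky-type factors F_k with Gamma_k = F_k F_k'.  Writing
A = [Z_1 F_1, ..., Z_K F_K], the marginal correlation matrix is
W = I + A A' and both beta and sigma^2 are profiled out of the REML
criterion.  All solves go through the q x q matrix M = I + A'A
(Woodbury), so the cost scales with the total random-effect dimension
rather than with n.
"""

from __future__ import annotations

import re
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrix, build_design_matrices
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .errors import (
    ConvergenceError,
    DataError,
    DegenerateFitError,
    RankDeficiencyError,
    UsageError,
)

logger = logging.getLogger(__name__)

_RANDOM_RE = re.compile(r"^\(\s*1\s*(?:\+\s*([\w.]+)\s*)?\|\s*([\w.]+)\s*\)$")


# ---------------------------------------------------------------------------
# model specification


@dataclass
class RandomTerm:
    """One random term of a mixed model.

    Parameters
    ----------
    grouping : str
        Grouping column (strain, mouse id, batch, cage, ...).  Ignored for
        ``covariance='iid_matrix'``.
    slope : str, optional
        Column providing a random slope in addition to the intercept; the
        covariance of the (intercept, slope) pair is then unstructured 2x2.
        Non-numeric two-level columns are coded 0/1 with the first sorted
        level as reference.
    covariance : {'iid', 'unstructured2x2', 'scaled_by_A', 'iid_matrix'}
    A : pandas.DataFrame, optional
        Known symmetric PSD relatedness matrix (labels on index/columns)
        for ``covariance='scaled_by_A'``.
    Z : numpy.ndarray, optional
        Explicit n x q design block for ``covariance='iid_matrix'``.
    name : str, optional
        Display name; defaults to a description of the term.
    """

    grouping: str | None = None
    slope: str | None = None
    covariance: str = "iid"
    A: pd.DataFrame | None = None
    Z: np.ndarray | None = None
    name: str | None = None

    def __post_init__(self):
        if self.slope is not None and self.covariance == "iid":
            self.covariance = "unstructured2x2"
        if self.covariance not in ("iid", "unstructured2x2", "scaled_by_A", "iid_matrix"):
            raise UsageError(f"unknown covariance type {self.covariance!r}")
        if self.covariance == "unstructured2x2" and self.slope is None:
            raise UsageError("unstructured2x2 requires a slope column")
        if self.covariance == "scaled_by_A" and self.A is None:
            raise UsageError("scaled_by_A requires the relatedness matrix A")
        if self.covariance == "iid_matrix" and self.Z is None:
            raise UsageError("iid_matrix requires an explicit design block Z")
        if self.name is None:
            if self.covariance == "iid_matrix":
                self.name = "custom"
            elif self.slope is not None:
                self.name = f"(1+{self.slope}|{self.grouping})"
            else:
                self.name = f"(1|{self.grouping})"

    @property
    def n_params(self) -> int:
        return 3 if self.covariance == "unstructured2x2" else 1


def parse_random(term: str) -> RandomTerm:
    """Parse an lme4-style random-term string like ``(1+diet|strain)``."""
    m = _RANDOM_RE.match(term.strip())
    if not m:
        raise UsageError(f"cannot parse random term {term!r}")
    slope, grouping = m.group(1), m.group(2)
    return RandomTerm(grouping=grouping, slope=slope)


@dataclass
class ModelSpec:
    """Mixed-model specification.

    ``fixed`` is a patsy right-hand-side formula (e.g.
    ``"diet * sex * C(timepoint) + bw6mo"``); ``random`` is a list of
    :class:`RandomTerm` or lme4-style strings.
    """

    response: str
    fixed: str = "1"
    random: list = field(default_factory=list)
    reml: bool = True

    def random_terms(self) -> list[RandomTerm]:
        return [t if isinstance(t, RandomTerm) else parse_random(t) for t in self.random]


@dataclass
class ContrastResult:
    """A scalar estimate with its uncertainty: estimate, SE, df, p."""

    name: str
    estimate: float
    se: float
    df: float
    p: float


# ---------------------------------------------------------------------------
# internal design structures


class _TermDesign:
    """Realized design of one random term: Z block plus its factor map."""

    def __init__(self, term: RandomTerm, data: pd.DataFrame):
        self.term = term
        cov = term.covariance
        if cov == "iid_matrix":
            self.Z = np.asarray(term.Z, dtype=float)
            self.levels = [f"{term.name}[{j}]" for j in range(self.Z.shape[1])]
            self.q = self.Z.shape[1]
            return
        g = data[term.grouping]
        self.levels = sorted(pd.unique(g.astype(str)))
        if len(self.levels) < 2:
            raise DataError(
                f"grouping factor {term.grouping!r} needs >= 2 levels"
            )
        idx = pd.Categorical(g.astype(str), categories=self.levels).codes
        n, m = len(data), len(self.levels)
        Zint = np.zeros((n, m))
        Zint[np.arange(n), idx] = 1.0
        if cov == "unstructured2x2":
            d = _code_slope(data[term.slope])
            Zsl = np.zeros((n, m))
            Zsl[np.arange(n), idx] = d
            self.Zint, self.Zsl = Zint, Zsl
            self.q = 2 * m
            Z = np.empty((n, self.q))
            Z[:, 0::2] = Zint
            Z[:, 1::2] = Zsl
            self.Z = Z
        elif cov == "scaled_by_A":
            A = term.A
            missing = [s for s in self.levels if s not in A.index]
            if missing:
                raise DataError(f"relatedness matrix missing levels: {missing}")
            K = A.loc[self.levels, self.levels].to_numpy(dtype=float)
            K = 0.5 * (K + K.T)
            try:
                C = np.linalg.cholesky(K)
            except np.linalg.LinAlgError:
                w = np.linalg.eigvalsh(K)
                if w.min() < -1e-8 * max(1.0, w.max()):
                    raise DataError("relatedness matrix is not PSD")
                C = np.linalg.cholesky(K + (1e-10 - min(0.0, w.min())) * np.eye(len(K)))
            self.Z = Zint
            self.ZC = Zint @ C
            self.C = C
            self.q = m
        else:
            self.Z = Zint
            self.q = m

    def build_A(self, th: np.ndarray) -> np.ndarray:
        """A_k = Z_k F_k, the factor-scaled design block."""
        return self.apply_Ft(th, self.Z.T).T

    def apply_Ft(self, th: np.ndarray, M: np.ndarray) -> np.ndarray:
        """Apply F_k' to the rows of a matrix with q_k rows.

        This is the workhorse of the fast likelihood: all data
        cross-products (Z'Z, Z'X, Z'y) are precomputed once and only these
        O(q^2) factor applications vary with the covariance parameters.
        """
        cov = self.term.covariance
        if cov == "unstructured2x2":
            l11, l21, l22 = th
            out = np.empty_like(M, dtype=float)
            out[0::2] = l11 * M[0::2] + l21 * M[1::2]
            out[1::2] = l22 * M[1::2]
            return out
        if cov == "scaled_by_A":
            return th[0] * (self.C.T @ M)
        return th[0] * np.asarray(M, dtype=float)

    def blups(self, th: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Map A-scale projections s = A_k' W^-1 r to conditional modes."""
        cov = self.term.covariance
        if cov == "unstructured2x2":
            l11, l21, l22 = th
            out = np.empty_like(s)
            out[0::2] = l11 * s[0::2]
            out[1::2] = l21 * s[0::2] + l22 * s[1::2]
            return out
        if cov == "scaled_by_A":
            return th[0] * (self.C @ s)
        return th[0] * s

    def gamma_diag(self, th: np.ndarray) -> np.ndarray:
        cov = self.term.covariance
        if cov == "unstructured2x2":
            l11, l21, l22 = th
            m = self.q // 2
            d = np.empty(self.q)
            d[0::2] = l11 ** 2
            d[1::2] = l21 ** 2 + l22 ** 2
            return d
        if cov == "scaled_by_A":
            return th[0] ** 2 * np.sum(self.C ** 2, axis=1)
        return np.full(self.q, th[0] ** 2)

    def factor_matrix(self, th: np.ndarray) -> np.ndarray:
        """Dense q x q factor F_k with Gamma_k = F F'."""
        cov = self.term.covariance
        if cov == "unstructured2x2":
            l11, l21, l22 = th
            L2 = np.array([[l11, 0.0], [l21, l22]])
            m = self.q // 2
            return np.kron(np.eye(m), L2)
        if cov == "scaled_by_A":
            return th[0] * self.C
        return th[0] * np.eye(self.q)


def _code_slope(col: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    levels = sorted(pd.unique(col.astype(str)))
    if len(levels) != 2:
        raise UsageError(
            f"non-numeric slope column must have exactly 2 levels, got {levels}"
        )
    return (col.astype(str) == levels[1]).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# fitted-model container


@dataclass
class LMMFit:
    """A fitted linear mixed model."""

    spec: ModelSpec
    beta: pd.Series
    cov_beta: pd.DataFrame
    vc: dict
    reml_loglik: float
    loglik_ml: float
    sigma2: float
    theta: np.ndarray
    blups: dict
    fitted: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_obs: int
    n_dropped: int
    optimizer_trace: list
    aliased: list
    # private handles for post-estimation
    _mm: object = None

    @property
    def residual_df(self) -> float:
        return self.n_obs - len(self.beta)

    def blup_table(self, term_name: str) -> pd.DataFrame:
        if term_name not in self.blups:
            raise UsageError(
                f"term {term_name!r} not in fit; have {list(self.blups)}"
            )
        return self.blups[term_name]


class _ModelMatrices:
    """Numeric design + likelihood machinery shared by fit and profiling."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, drop_aliased=False):
        cols = _columns_used(spec, data)
        sub = data[cols].copy()
        n0 = len(sub)
        keep = ~sub.isna().any(axis=1)
        self.data = data.loc[keep].reset_index(drop=True)
        self.n_dropped = int(n0 - keep.sum())
        if self.n_dropped:
            logger.info("dropped %d rows with missing modeled values", self.n_dropped)
        if not len(self.data):
            raise DataError("no complete rows remain after listwise deletion")

        self.y = self.data[spec.response].to_numpy(dtype=float)
        dm = dmatrix(spec.fixed, self.data, return_type="dataframe")
        self.design_info = dm.design_info
        X = dm.to_numpy()
        names = list(dm.columns)
        self.aliased = []
        # rank check via pivoted QR on column-scaled X
        scale = np.linalg.norm(X, axis=0)
        scale[scale == 0] = 1.0
        R = np.linalg.qr(X / scale, mode="r")
        bad = np.abs(np.diag(R)) < 1e-8
        if bad.any():
            # identify aliased columns greedily
            keep_cols, aliased = [], []
            for j in range(X.shape[1]):
                trial = X[:, keep_cols + [j]]
                if np.linalg.matrix_rank(trial, tol=1e-8 * max(1.0, scale.max())) == len(keep_cols) + 1:
                    keep_cols.append(j)
                else:
                    aliased.append(names[j])
            if not drop_aliased:
                raise RankDeficiencyError(aliased)
            self.aliased = aliased
            X = X[:, keep_cols]
            names = [names[j] for j in keep_cols]
        self.X = X
        self.xnames = names
        self.n, self.p = X.shape
        if self.n <= self.p:
            raise DataError("more fixed-effect columns than observations")

        self.terms = [_TermDesign(t, self.data) for t in spec.random_terms()]
        self.slices = []
        off = 0
        for td in self.terms:
            self.slices.append(slice(off, off + td.q))
            off += td.q
        self.q = off
        self.reml = spec.reml

        # constant cross-products: the likelihood then costs one q x q
        # Cholesky per evaluation regardless of n
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        if self.q:
            self.Zfull = np.hstack([td.Z for td in self.terms])
            self.ZtZ = self.Zfull.T @ self.Zfull
            self.ZtX = self.Zfull.T @ self.X
            self.Zty = self.Zfull.T @ self.y

    # -- parameter packing ------------------------------------------------
    def x0(self) -> np.ndarray:
        x = []
        for td in self.terms:
            if td.term.covariance == "unstructured2x2":
                x += [1.0, 0.0, 1.0]
            else:
                x += [1.0]
        return np.array(x)

    def bounds(self):
        b = []
        for td in self.terms:
            if td.term.covariance == "unstructured2x2":
                b += [(0.0, 1e3), (-1e3, 1e3), (0.0, 1e3)]
            else:
                b += [(0.0, 1e3)]
        return b

    def split(self, theta: np.ndarray):
        out, i = [], 0
        for td in self.terms:
            out.append(np.asarray(theta[i : i + td.term.n_params], dtype=float))
            i += td.term.n_params
        return out

    # -- likelihood -------------------------------------------------------
    def _apply_Ft(self, ths, M):
        """Apply blockdiag(F_1', ..., F_K') to the rows of M (q rows)."""
        out = np.empty_like(M, dtype=float)
        for td, th, sl in zip(self.terms, ths, self.slices):
            out[sl] = td.apply_Ft(th, M[sl])
        return out

    def profile(self, theta, reml=None):
        """Profiled criterion pieces at relative-covariance parameters theta."""
        reml = self.reml if reml is None else reml
        if self.q:
            ths = self.split(theta)
            AtX = self._apply_Ft(ths, self.ZtX)
            Aty = self._apply_Ft(ths, self.Zty)
            S = self._apply_Ft(ths, self._apply_Ft(ths, self.ZtZ).T).T
            S = 0.5 * (S + S.T)  # A'A
            M = S + np.eye(self.q)
            cM = cho_factor(M, lower=True, check_finite=False)
            logdetW = 2.0 * np.sum(np.log(np.diag(cM[0])))
            MiAtX = cho_solve(cM, AtX, check_finite=False)
            MiAty = cho_solve(cM, Aty, check_finite=False)
            XtWiX = self.XtX - AtX.T @ MiAtX
            XtWiy = self.Xty - AtX.T @ MiAty
            ytWiy = self.yty - float(Aty @ MiAty)
        else:
            S, cM, AtX, Aty = None, None, None, None
            logdetW = 0.0
            XtWiX, XtWiy, ytWiy = self.XtX, self.Xty, self.yty
        XtWiX = 0.5 * (XtWiX + XtWiX.T)
        try:
            cXX = cho_factor(XtWiX, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            raise RankDeficiencyError(self.xnames)
        beta = cho_solve(cXX, XtWiy, check_finite=False)
        logdet_XtWiX = 2.0 * np.sum(np.log(np.diag(cXX[0])))
        quad = float(ytWiy - 2.0 * beta @ XtWiy + beta @ (XtWiX @ beta))
        quad = max(quad, 0.0)
        dof = self.n - self.p if reml else self.n
        sigma2 = max(quad / dof, 0.0)
        return {
            "beta": beta,
            "sigma2": sigma2,
            "quad": quad,
            "logdetW": logdetW,
            "logdet_XtWiX": logdet_XtWiX,
            "XtWiX": XtWiX,
            "S": S,
            "AtX": AtX,
            "Aty": Aty,
            "cM": cM,
            "reml": reml,
        }

    def loglik(self, theta, reml=None):
        reml = self.reml if reml is None else reml
        pr = self.profile(theta, reml=reml)
        if pr["sigma2"] <= 0:
            return -np.inf
        dof = self.n - self.p if reml else self.n
        val = pr["logdetW"] + dof * (np.log(2 * np.pi * pr["sigma2"]) + 1.0)
        if reml:
            val += pr["logdet_XtWiX"]
        return -0.5 * val

    def loglik_unprofiled(self, theta, sigma2, reml=None):
        """REML/ML log-likelihood as a function of (theta, sigma2)."""
        reml = self.reml if reml is None else reml
        pr = self.profile(theta, reml=reml)
        dof = self.n - self.p if reml else self.n
        val = pr["logdetW"] + dof * np.log(2 * np.pi * sigma2) + pr["quad"] / sigma2
        if reml:
            val += pr["logdet_XtWiX"]
        return -0.5 * val

    def cov_beta(self, theta, sigma2):
        pr = self.profile(theta)
        return sigma2 * np.linalg.inv(pr["XtWiX"])


def _columns_used(spec: ModelSpec, data: pd.DataFrame) -> list:
    cols = {spec.response}
    for name in data.columns:
        if re.search(rf"\b{re.escape(name)}\b", spec.fixed):
            cols.add(name)
    for t in spec.random_terms():
        if t.covariance == "iid_matrix":
            continue
        if t.grouping not in data.columns:
            raise DataError(f"grouping column {t.grouping!r} not in data")
        cols.add(t.grouping)
        if t.slope is not None:
            cols.add(t.slope)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise DataError(f"columns not in data: {missing}")
    return sorted(cols)


# ---------------------------------------------------------------------------
# optimization


def _numgrad(f, x, h=1e-5):
    g = np.zeros_like(x)
    for i in range(len(x)):
        hi = h * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += hi
        xm[i] -= hi
        g[i] = (f(xp) - f(xm)) / (2 * hi)
    return g


def _polish_newton(f, x, bounds, max_iter=8, gtol=1e-9):
    """High-precision Newton polish on a numerical gradient.

    Finite-difference L-BFGS stops with gradient noise around 1e-6; the
    closed-form oracles in the test-suite require parameter accuracy near
    1e-10, which central-difference Newton steps deliver.
    """
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    fx = f(x)
    for _ in range(max_iter):
        g = _numgrad(f, x)
        free = ~((np.isclose(x, lo) & (g > 0)) | (np.isclose(x, hi) & (g < 0)))
        if not free.any() or np.linalg.norm(g[free]) < gtol:
            break
        idx = np.where(free)[0]
        H = np.zeros((len(idx), len(idx)))
        for a, i in enumerate(idx):
            hi_ = 1e-5 * (1.0 + abs(x[i]))
            xp, xm = x.copy(), x.copy()
            xp[i] += hi_
            xm[i] -= hi_
            H[a] = ((_numgrad(f, xp) - _numgrad(f, xm)) / (2 * hi_))[idx]
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(len(idx)), -g[idx])
        except np.linalg.LinAlgError:
            break
        xn = x.copy()
        xn[idx] = np.clip(x[idx] + step, lo[idx], hi[idx])
        fn = f(xn)
        # backtrack if the full Newton step overshoots
        t = 1.0
        while fn > fx + 1e-12 and t > 1e-4:
            t /= 2
            xn = x.copy()
            xn[idx] = np.clip(x[idx] + t * step, lo[idx], hi[idx])
            fn = f(xn)
        if fn > fx + 1e-12:
            break
        if abs(fx - fn) < 1e-15 and np.max(np.abs(xn - x)) < 1e-12:
            x, fx = xn, fn
            break
        x, fx = xn, fn
    return x


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, drop_aliased: bool = False,
            fixed_theta=None) -> LMMFit:
    """Fit a Gaussian linear mixed model by REML (or ML).

    Rows with missing values in any modeled column are dropped (with the
    count recorded on the fit).  ``fixed_theta`` pins the relative
    covariance parameters (no optimization), which is how penalized-spline
    smoothers are evaluated at fixed smoothing parameters.  Raises
    :class:`RankDeficiencyError` on a singular fixed-effect design unless
    ``drop_aliased`` is set, and :class:`DegenerateFitError` when the
    residual variance collapses to 0.
    """
    mm = _ModelMatrices(spec, data, drop_aliased=drop_aliased)
    trace = []

    if mm.q == 0:
        theta = np.array([])
        converged = True
    elif fixed_theta is not None:
        theta = np.asarray(fixed_theta, dtype=float)
        converged = True
    else:
        def neg(x):
            v = mm.loglik(x)
            return np.inf if not np.isfinite(v) else -v

        best = None
        for start_scale in (1.0, 0.3):
            x0 = mm.x0() * start_scale
            res = optimize.minimize(
                neg, x0, method="L-BFGS-B", bounds=mm.bounds(),
                options={"ftol": 1e-14, "gtol": 1e-8, "maxiter": 1000},
            )
            trace.append({"start": x0.tolist(), "fun": float(res.fun),
                          "nit": int(res.nit), "success": bool(res.success)})
            if best is None or res.fun < best.fun - 1e-10:
                best = res
            if res.success and start_scale == 1.0:
                break
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("REML optimization failed", trace)
        theta = _polish_newton(neg, np.asarray(best.x, dtype=float), mm.bounds())
        converged = bool(best.success) or np.isfinite(neg(theta))

    pr = mm.profile(theta)
    sigma2 = pr["sigma2"]
    yscale = float(np.var(mm.y)) if len(mm.y) > 1 else 1.0
    at_upper = mm.q > 0 and any(
        th >= hi - 1e-6 for th, (lo, hi) in zip(theta, mm.bounds()))
    if sigma2 <= max(yscale, 1e-300) * 1e-8 or at_upper:
        raise DegenerateFitError(
            "residual variance is (numerically) zero; the model interpolates the data"
        )

    beta = pd.Series(pr["beta"], index=mm.xnames)
    covb = pd.DataFrame(
        sigma2 * np.linalg.inv(pr["XtWiX"]), index=mm.xnames, columns=mm.xnames
    )

    # BLUPs and conditional SDs
    blups = {}
    vc = {"residual": sigma2}
    if mm.q:
        S, cM = pr["S"], pr["cM"]
        Atr = pr["Aty"] - pr["AtX"] @ pr["beta"]
        s = Atr - S @ cho_solve(cM, Atr, check_finite=False)  # A' W^-1 r
        T = S - S @ cho_solve(cM, S, check_finite=False)      # A' W^-1 A
        ths = mm.split(theta)
        for td, th, sl in zip(mm.terms, ths, mm.slices):
            modes = td.blups(th, s[sl])
            F = td.factor_matrix(th)
            cond_var = sigma2 * (td.gamma_diag(th) - np.diag(F @ T[sl, sl] @ F.T))
            cond_var = np.clip(cond_var, 0.0, None)
            if td.term.covariance == "unstructured2x2":
                tab = pd.DataFrame(
                    {
                        "intercept": modes[0::2],
                        "slope": modes[1::2],
                        "intercept_sd": np.sqrt(cond_var[0::2]),
                        "slope_sd": np.sqrt(cond_var[1::2]),
                    },
                    index=pd.Index([lv for lv in td.levels], name=td.term.grouping),
                )
                l11, l21, l22 = th
                v_int = sigma2 * l11 ** 2
                v_sl = sigma2 * (l21 ** 2 + l22 ** 2)
                denom = np.sqrt(v_int * v_sl)
                rho = float(sigma2 * l11 * l21 / denom) if denom > 0 else 0.0
                vc[td.term.name] = {
                    "var_intercept": v_int,
                    "var_slope": v_sl,
                    "rho": rho,
                }
            else:
                tab = pd.DataFrame(
                    {"mode": modes, "cond_sd": np.sqrt(cond_var)},
                    index=pd.Index(td.levels, name=td.term.grouping or td.term.name),
                )
                vc[td.term.name] = {"var": sigma2 * float(th[0] ** 2)}
            blups[td.term.name] = tab

    fitted = mm.X @ pr["beta"]
    # conditional fitted values include the random-effect contributions
    if mm.q:
        ths = mm.split(theta)
        contrib = np.zeros(mm.n)
        for td, th, sl in zip(mm.terms, ths, mm.slices):
            contrib += td.Z @ td.blups(th, s[sl])
        fitted_cond = fitted + contrib
    else:
        fitted_cond = fitted

    ll_reml = mm.loglik(theta, reml=True)
    ll_ml = mm.loglik(theta, reml=False)

    fit = LMMFit(
        spec=spec,
        beta=beta,
        cov_beta=covb,
        vc=vc,
        reml_loglik=float(ll_reml),
        loglik_ml=float(ll_ml),
        sigma2=float(sigma2),
        theta=np.asarray(theta, dtype=float),
        blups=blups,
        fitted=fitted_cond,
        residuals=mm.y - fitted_cond,
        converged=converged,
        n_obs=mm.n,
        n_dropped=mm.n_dropped,
        optimizer_trace=trace,
        aliased=mm.aliased,
        _mm=mm,
    )
    return fit


def blups(fit: LMMFit, term) -> pd.DataFrame:
    """Per-level conditional modes (empirical-Bayes BLUPs) with SDs."""
    name = term.name if isinstance(term, RandomTerm) else str(term)
    return fit.blup_table(name)


# ---------------------------------------------------------------------------
# likelihood-ratio test for random-effect structure


def lrt_random(full: LMMFit, reduced: LMMFit, mixture: bool = False) -> ContrastResult:
    """REML likelihood-ratio test of nested random-effect structures.

    The statistic 2(l_full - l_reduced), floored at 0, is referred to a
    chi-square with df = number of dropped covariance parameters.  This
    naive reference is conservative when the null pins variances to the
    boundary; ``mixture`` switches to an equal-weights chi-square mixture
    of df and df-1.
    """
    if full.spec.fixed != reduced.spec.fixed or full.spec.response != reduced.spec.response:
        raise UsageError("LRT requires identical fixed effects and response")
    if full.n_obs != reduced.n_obs:
        raise UsageError("LRT requires identical data (row counts differ)")
    df = len(full.theta) - len(reduced.theta)
    if df < 0:
        raise UsageError("reduced model has more covariance parameters than full")
    stat = max(0.0, 2.0 * (full.reml_loglik - reduced.reml_loglik))
    if df == 0:
        p = 1.0
    elif mixture:
        p = 0.5 * stats.chi2.sf(stat, df) + 0.5 * (
            stats.chi2.sf(stat, df - 1) if df > 1 else float(stat <= 0)
        )
    else:
        p = float(stats.chi2.sf(stat, df))
    return ContrastResult(name="lrt_random", estimate=stat, se=np.nan, df=df, p=p)


# ---------------------------------------------------------------------------
# model-based means and contrasts


def _reference_grid(fit: LMMFit) -> pd.DataFrame:
    mm = fit._mm
    di = mm.design_info
    cat_levels, cont = {}, {}
    for f, info in di.factor_infos.items():
        name = f.code
        if info.type == "categorical":
            key = name
            m = re.match(r"^C\((\w+).*\)$", name)
            if m:
                key = m.group(1)
            cat_levels[key] = [lv for lv in info.categories]
        else:
            if name in mm.data.columns:
                cont[name] = float(mm.data[name].mean())
    if not cat_levels:
        raise UsageError("model has no categorical fixed factors")
    keys = sorted(cat_levels)
    grids = [cat_levels[k] for k in keys]
    idx = pd.MultiIndex.from_product(grids, names=keys)
    grid = idx.to_frame(index=False)
    for name, val in cont.items():
        grid[name] = val
    return grid


def contrast_means(fit: LMMFit, factor: str, by: list | None = None,
                   use_satterthwaite: bool = False) -> list:
    """Pairwise model-based-mean contrasts for ``factor``.

    Cell means are computed on an equal-weight reference grid over all
    other fixed factors (continuous covariates held at their mean), and
    pairwise differences between factor levels are returned overall and,
    with ``by``, within each stratum.
    """
    mm = fit._mm
    if factor in mm.data.columns and pd.api.types.is_numeric_dtype(mm.data[factor]) \
            and mm.data[factor].nunique() > 12:
        raise UsageError(f"{factor!r} looks continuous; contrasts need a factor")
    grid = _reference_grid(fit)
    if factor not in grid.columns:
        raise UsageError(f"{factor!r} is not a categorical fixed factor in the model")
    by = list(by or [])
    for b in by:
        if b not in grid.columns:
            raise UsageError(f"stratifier {b!r} is not a fixed factor in the model")
    D = np.asarray(
        build_design_matrices([mm.design_info], grid)[0], dtype=float
    )
    if fit.aliased:
        keep = [j for j, nm in enumerate(mm.design_info.column_names)
                if nm not in fit.aliased]
        D = D[:, keep]
    covb = fit.cov_beta.to_numpy()
    beta = fit.beta.to_numpy()
    levels = sorted(grid[factor].astype(str).unique())
    results = []
    strata = [((), grid)] if not by else [
        (k if isinstance(k, tuple) else (k,), g) for k, g in grid.groupby(by)
    ]
    for key, g in strata:
        rows = {}
        for lv in levels:
            sel = g[factor].astype(str) == lv
            if not sel.any():
                continue
            c = np.zeros(D.shape[0])
            c[g.index[sel]] = 1.0 / sel.sum()
            rows[lv] = c @ D
        labels = sorted(rows)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                c = rows[labels[j]] - rows[labels[i]]
                est = float(c @ beta)
                se = float(np.sqrt(max(c @ covb @ c, 0.0)))
                if use_satterthwaite:
                    df = satterthwaite_df(fit, c)
                else:
                    df = fit.residual_df
                tstat = est / se if se > 0 else np.inf * np.sign(est)
                p = float(2 * stats.t.sf(abs(tstat), df))
                tag = "" if not key else "|" + ",".join(str(k) for k in key)
                results.append(ContrastResult(
                    name=f"{factor}:{labels[j]}-{labels[i]}{tag}",
                    estimate=est, se=se, df=float(df), p=p,
                ))
    return results


# ---------------------------------------------------------------------------
# Satterthwaite denominator degrees of freedom


def satterthwaite_df(fit: LMMFit, c: np.ndarray) -> float:
    """Satterthwaite df for the scalar contrast c'beta.

    df = 2 (c'S c)^2 / Var(c'S c), with the variance obtained from the
    gradient of c'S c with respect to all covariance parameters
    (theta, sigma^2) and their asymptotic covariance (inverse REML
    information, numerically differentiated).
    """
    mm = fit._mm
    c = np.asarray(c, dtype=float)
    phi_hat = np.concatenate([fit.theta, [fit.sigma2]])

    def covc(phi):
        theta, s2 = phi[:-1], phi[-1]
        pr = mm.profile(theta)
        V = s2 * np.linalg.inv(pr["XtWiX"])
        return float(c @ V @ c)

    def negll(phi):
        return -mm.loglik_unprofiled(phi[:-1], phi[-1], reml=True)

    val = covc(phi_hat)
    g = _numgrad(covc, phi_hat, h=1e-5)
    k = len(phi_hat)
    H = np.zeros((k, k))
    for i in range(k):
        hi = 1e-4 * (1.0 + abs(phi_hat[i]))
        xp, xm = phi_hat.copy(), phi_hat.copy()
        xp[i] += hi
        xm[i] -= hi
        H[i] = (_numgrad(negll, xp, h=1e-4) - _numgrad(negll, xm, h=1e-4)) / (2 * hi)
    H = 0.5 * (H + H.T)
    Acov = np.linalg.pinv(H)
    var = float(g @ Acov @ g)
    if var <= 0 or not np.isfinite(var):
        return float(fit.residual_df)
    df = 2.0 * val ** 2 / var
    return float(np.clip(df, 1.0, fit.residual_df))
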