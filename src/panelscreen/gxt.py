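"""Per-phenotype genotype-by-treatment (GxT) screen.

For each phenotype the pipeline rank-normal transforms the outcome, fits a
mixed model with the full diet x sex x timepoint fixed structure, baseline
body weight, a correlated random intercept + diet slope per strain, a
random intercept per mouse, and batch intercepts; tests diet-effect
heterogeneity across strains by dropping the strain diet slope (a
2-df variance-component LRT); extracts the intercept-slope correlation
rho; BH-adjusts p-values across phenotypes; and converts strain slope
BLUPs into interpretable diet-effect scores for mouse-model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .errors import DataError, UsageError
from .lmm import ModelSpec, RandomTerm, fit_lmm, lrt_random, contrast_means, LMMFit


# ---------------------------------------------------------------------------
# rank-based inverse normal transform


def rank_normal(values) -> np.ndarray:
    """Blom rank-normal transform: Phi^-1((r - 3/8) / (n + 1/4)).

    Ties get average ranks; missing values stay missing.  Raises on fewer
    than 3 non-missing values or an all-ties input.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n < 3:
        raise DataError("rank_normal needs >= 3 non-missing values")
    v = x[ok]
    if np.all(v == v[0]):
        raise DataError("rank_normal: all values identical (no ranks)")
    r = stats.rankdata(v, method="average")
    out[ok] = stats.norm.ppf((r - 3.0 / 8.0) / (n + 0.25))
    return out


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def adjust_bh(pvalues) -> np.ndarray:
    """One-step BH step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the per-phenotype model


@dataclass
class GxTResult:
    phenotype: str
    diet_p: float
    diet_estimate: float
    diet_by_sex: dict
    diet_by_timepoint: dict
    gxt_stat: float
    gxt_df: float
    gxt_p: float
    rho: float
    fit: LMMFit
    dropped_terms: list = field(default_factory=list)
    diet_q: float = np.nan
    gxt_q: float = np.nan


def _assemble(pheno: pd.DataFrame, animals: pd.DataFrame) -> pd.DataFrame:
    cols = ["mouse_id", "strain", "sex", "diet", "bw6mo"]
    df = pheno.merge(animals[cols], on="mouse_id", how="inner", validate="m:1")
    if not len(df):
        raise DataError("no phenotype rows match the animals table")
    return df


def run_gxt(pheno: pd.DataFrame, animals: pd.DataFrame,
            include_mouse: bool = True, include_batch: bool = True,
            use_satterthwaite: bool = False) -> GxTResult:
    """Fit the GxT model for one phenotype and test strain-specific diet
    response.

    ``pheno`` holds the long rows of a single phenotype (columns mouse_id,
    timepoint, value, batch); ``animals`` provides strain/sex/diet/bw6mo.
    """
    name = str(pheno["phenotype"].iloc[0]) if "phenotype" in pheno else "phenotype"
    df = _assemble(pheno, animals)
    if df["diet"].nunique() < 2 or df["strain"].nunique() < 2:
        raise DataError("GxT needs >= 2 diets and >= 2 strains")
    df = df.dropna(subset=["value"]).copy()
    df["y"] = rank_normal(df["value"])

    multi_tp = df["timepoint"].nunique() > 1
    fixed = "diet * sex * C(timepoint) + bw6mo" if multi_tp else "diet * sex + bw6mo"

    random_full = [RandomTerm(grouping="strain", slope="diet")]
    random_red = [RandomTerm(grouping="strain")]
    dropped = []
    if include_mouse:
        if df.groupby("mouse_id").size().max() >= 2:
            random_full.append(RandomTerm(grouping="mouse_id"))
            random_red.append(RandomTerm(grouping="mouse_id"))
        else:
            dropped.append("(1|mouse_id)")
            warnings.warn("single observation per mouse: dropping (1|mouse_id)")
    if include_batch and "batch" in df and df["batch"].nunique() >= 2:
        random_full.append(RandomTerm(grouping="batch"))
        random_red.append(RandomTerm(grouping="batch"))

    full = fit_lmm(ModelSpec("y", fixed, random_full), df, drop_aliased=True)
    reduced = fit_lmm(ModelSpec("y", fixed, random_red), df, drop_aliased=True)
    lrt = lrt_random(full, reduced)

    overall = contrast_means(full, "diet", use_satterthwaite=use_satterthwaite)[0]
    by_sex = {c.name.split("|")[-1]: c
              for c in contrast_means(full, "diet", by=["sex"],
                                      use_satterthwaite=use_satterthwaite)}
    by_tp = {}
    if multi_tp:
        by_tp = {c.name.split("|")[-1]: c
                 for c in contrast_means(full, "diet", by=["timepoint"],
                                         use_satterthwaite=use_satterthwaite)}

    rho = full.vc["(1+diet|strain)"]["rho"]
    return GxTResult(
        phenotype=name,
        diet_p=overall.p, diet_estimate=overall.estimate,
        diet_by_sex={k: (v.estimate, v.p) for k, v in by_sex.items()},
        diet_by_timepoint={k: (v.estimate, v.p) for k, v in by_tp.items()},
        gxt_stat=lrt.estimate, gxt_df=lrt.df, gxt_p=lrt.p,
        rho=float(rho), fit=full, dropped_terms=dropped,
    )


def run_gxt_screen(phenotypes: pd.DataFrame, animals: pd.DataFrame,
                   phenotype_names: list | None = None, **kwargs) -> dict:
    """Run the GxT model per phenotype and BH-adjust across phenotypes."""
    names = phenotype_names or sorted(
        p for p in phenotypes["phenotype"].unique()
        if p not in ("bodyweight", "temperature")
    )
    results = {}
    for ph in names:
        results[ph] = run_gxt(phenotypes[phenotypes["phenotype"] == ph],
                              animals, **kwargs)
    qs_diet = adjust_bh([results[ph].diet_p for ph in names])
    qs_gxt = adjust_bh([results[ph].gxt_p for ph in names])
    for ph, qd, qg in zip(names, qs_diet, qs_gxt):
        results[ph].diet_q = float(qd)
        results[ph].gxt_q = float(qg)
    return results


def gxt_table(results: dict) -> pd.DataFrame:
    rows = []
    for ph, r in results.items():
        rows.append((ph, r.diet_estimate, r.diet_p, r.diet_q,
                     r.gxt_stat, r.gxt_p, r.gxt_q, r.rho))
    return pd.DataFrame(rows, columns=[
        "phenotype", "diet_estimate", "diet_p", "diet_q",
        "gxt_stat", "gxt_p", "gxt_q", "rho"]).set_index("phenotype")


# ---------------------------------------------------------------------------
# empirical-Bayes diet-effect scores


@dataclass
class DietEffectScores:
    """Strain diet-effect score matrices, one per sex x timepoint stratum.

    Each matrix has phenotypes as rows and strains as columns; the entry is
    the strain's diet-slope BLUP (zeta_EB) plus the population diet
    contrast for that stratum.  ``scaled`` z-scores each strain's column
    across phenotypes within the stratum.
    """

    scores: dict
    scaled: dict
    strata: tuple


def diet_effect_scores(results: dict, strata=("sex", "timepoint"),
                       scale_within: str = "strain") -> DietEffectScores:
    strata = tuple(strata)
    strata_keys = set()
    per_ph = {}
    for ph, r in results.items():
        blup = r.fit.blup_table("(1+diet|strain)")["slope"]
        contrasts = {}
        by = [s for s in strata
              if s != "timepoint" or r.diet_by_timepoint]
        cs = contrast_means(r.fit, "diet", by=by)
        for c in cs:
            key = c.name.split("|")[-1] if "|" in c.name else ""
            contrasts[tuple(key.split(","))] = c.estimate
            strata_keys.add(tuple(key.split(",")))
        per_ph[ph] = (blup, contrasts)
    scores = {}
    for key in sorted(strata_keys):
        mat = {}
        for ph, (blup, contrasts) in per_ph.items():
            if key not in contrasts:
                warnings.warn(f"missing stratum contrast {key} for {ph}")
                mat[ph] = pd.Series(np.nan, index=blup.index)
            else:
                mat[ph] = blup + contrasts[key]
        scores[key] = pd.DataFrame(mat).T  # rows phenotypes, cols strains
    if scale_within == "strain":
        scaled = {k: (m - m.mean(axis=0)) / m.std(axis=0, ddof=1)
                  for k, m in scores.items()}
    elif scale_within == "phenotype":
        scaled = {k: m.sub(m.mean(axis=1), axis=0).div(m.std(axis=1, ddof=1), axis=0)
                  for k, m in scores.items()}
    else:
        raise UsageError("scale_within must be 'strain' or 'phenotype'")
    return DietEffectScores(scores=scores, scaled=scaled, strata=strata)


# ---------------------------------------------------------------------------
# clustering and model-strain selection


@dataclass
class ClusterResult:
    row_labels: pd.Series
    col_labels: pd.Series
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def cluster_scores(matrix: pd.DataFrame, k: int = 3,
                   row_order: list | None = None) -> ClusterResult:
    """Ward/Euclidean agglomerative clustering of a score matrix.

    Rows (phenotypes) and columns (strains) are clustered separately; a
    ``row_order`` from a designated reference stratum can be imposed so
    the row layout is preserved across strata.  Missing entries are
    mean-imputed with a warning; a constant matrix degenerates to a
    single cluster with a warning.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise DataError("clustering needs >= 2 rows and >= 2 columns")
    M = matrix.copy()
    if M.isna().any().any():
        warnings.warn("mean-imputing missing score entries before clustering")
        M = M.apply(lambda c: c.fillna(c.mean()), axis=0).fillna(0.0)
    X = M.to_numpy(dtype=float)
    if np.allclose(X, X.flat[0]):
        warnings.warn("constant score matrix: degenerate single cluster")
        ones_r = pd.Series(1, index=M.index)
        ones_c = pd.Series(1, index=M.columns)
        return ClusterResult(ones_r, ones_c, list(M.index), list(M.columns),
                             np.empty((0, 4)), np.empty((0, 4)))
    lr = hierarchy.linkage(X, method="ward", metric="euclidean")
    lc = hierarchy.linkage(X.T, method="ward", metric="euclidean")
    kr = min(k, len(M.index))
    kc = min(k, len(M.columns))
    row_labels = pd.Series(hierarchy.fcluster(lr, kr, criterion="maxclust"),
                           index=M.index)
    col_labels = pd.Series(hierarchy.fcluster(lc, kc, criterion="maxclust"),
                           index=M.columns)
    if row_order is None:
        row_order = [M.index[i] for i in hierarchy.leaves_list(lr)]
    else:
        unknown = [r for r in row_order if r not in M.index]
        if unknown:
            raise UsageError(f"row_order entries not in matrix: {unknown}")
    col_order = [M.columns[i] for i in hierarchy.leaves_list(lc)]
    return ClusterResult(row_labels, col_labels, list(row_order), col_order, lr, lc)


def select_model_strains(scores) -> dict:
    """Strains with the maximum and minimum diet-effect score.

    Ties break lexicographically by strain label.  Accepts a mapping or
    pandas Series of strain -> score.
    """
    s = pd.Series(scores, dtype=float).dropna()
    if len(s) < 2:
        raise DataError("need >= 2 strains with non-missing scores")
    vmax, vmin = s.max(), s.min()
    max_strain = sorted(s.index[s == vmax])[0]
    min_strain = sorted(s.index[s == vmin])[0]
    return {"max_strain": max_strain, "max_score": float(vmax),
            "min_strain": min_strain, "min_score": float(vmin)}
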