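"""Longevity-biomarker screen: trait-by-timepoint lifespan association.

For each trait x timepoint, lifespan is regressed on the trait after
adjusting for diet, sex and 6-month body weight, with random intercepts
for strain and collection batch.  Both lifespan and continuous covariates
are rank-normal transformed, so the trait coefficient is a standardized
beta.  The trait term's p-value is an F test (1 numerator df) with a
Satterthwaite denominator df, and a single BH pass pools all trait x
timepoint tests.  Mice must be alive to be measured, so later timepoints
condition on survival; this selection is inherent to the design and is
left as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, RankDeficiencyError
from .gxt import rank_normal, adjust_bh
from .lmm import ModelSpec, RandomTerm, fit_lmm, satterthwaite_df


@dataclass
class BiomarkerResult:
    trait: str
    timepoint: int
    beta: float
    se: float
    F: float
    df_den: float
    p: float
    n: int
    q: float = np.nan


def _fit_one(df: pd.DataFrame, trait: str, timepoint: int,
             random_effects: bool = True) -> BiomarkerResult:
    df = df.dropna(subset=["lifespan_months", "value", "bw6mo"]).copy()
    if len(df) < 20:
        raise DataError(f"{trait} @ t{timepoint}: fewer than 20 complete mice")
    df["y"] = rank_normal(df["lifespan_months"])
    df["trait"] = rank_normal(df["value"])
    df["bw"] = rank_normal(df["bw6mo"])
    if np.corrcoef(df["trait"], df["bw"])[0, 1] ** 2 > 1 - 1e-10:
        raise RankDeficiencyError([f"trait {trait} aliases bw6mo"])
    random = []
    if random_effects:
        if df["strain"].nunique() >= 2:
            random.append(RandomTerm(grouping="strain"))
        if "batch" in df and df["batch"].nunique() >= 2:
            random.append(RandomTerm(grouping="batch"))
    fit = fit_lmm(ModelSpec("y", "trait + diet + sex + bw", random), df)
    j = list(fit.beta.index).index("trait")
    c = np.zeros(len(fit.beta))
    c[j] = 1.0
    beta = float(fit.beta.iloc[j])
    se = float(np.sqrt(fit.cov_beta.iloc[j, j]))
    dfd = satterthwaite_df(fit, c) if random else float(fit.residual_df)
    F = (beta / se) ** 2 if se > 0 else np.inf
    p = float(stats.f.sf(F, 1, dfd))
    return BiomarkerResult(trait=trait, timepoint=int(timepoint), beta=beta,
                           se=se, F=F, df_den=float(dfd), p=p, n=len(df))


def biomarker_screen(phenotypes: pd.DataFrame, animals: pd.DataFrame,
                     traits=None, include_weight_summaries: bool = True,
                     random_effects: bool = True) -> list:
    """Run the lifespan-association screen across traits and timepoints.

    Assay phenotypes enter per timepoint; weekly body weight enters as its
    lifetime summaries MM and +AUC rather than by timepoint.
    """
    meta = animals[["mouse_id", "strain", "sex", "diet", "bw6mo",
                    "lifespan_months"]]
    results = []
    names = traits or sorted(p for p in phenotypes["phenotype"].unique()
                             if p not in ("bodyweight", "temperature"))
    for ph in names:
        sub = phenotypes[phenotypes["phenotype"] == ph]
        for tp, tsub in sub.groupby("timepoint"):
            df = tsub.merge(meta, on="mouse_id", how="inner", validate="m:1")
            try:
                results.append(_fit_one(df, ph, tp, random_effects))
            except DataError:
                continue
    if include_weight_summaries and (phenotypes["phenotype"] == "bodyweight").any():
        from .trajectories import weight_summaries_table

        ws = weight_summaries_table(phenotypes)
        for col, label in (("MM", "bodyweight_MM"), ("plusAUC", "bodyweight_plusAUC")):
            df = ws.rename(columns={col: "value"})[["mouse_id", "value"]]
            df = df.merge(meta, on="mouse_id", how="inner", validate="1:1")
            df["batch"] = "lifetime"
            try:
                results.append(_fit_one(df, label, -1, random_effects))
            except DataError:
                continue
    if not results:
        raise DataError("no trait x timepoint combination was estimable")
    return fdr_across(results)


def fdr_across(results: list) -> list:
    """Single BH pass pooling all trait x timepoint p-values."""
    if not results:
        raise DataError("no results to adjust")
    q = adjust_bh([r.p for r in results])
    for r, qi in zip(results, q):
        r.q = float(qi)
    return results


def biomarker_table(results: list) -> pd.DataFrame:
    rows = [(r.trait, r.timepoint, r.beta, r.se, r.F, r.df_den, r.p, r.q, r.n)
            for r in results]
    tab = pd.DataFrame(rows, columns=["trait", "timepoint", "beta", "se", "F",
                                      "df_den", "p", "q", "n"])
    tab["neg_log10_q"] = -np.log10(np.clip(tab["q"], 1e-300, None))
    return tab
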