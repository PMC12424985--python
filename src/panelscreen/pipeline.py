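"""End-to-end analysis pipeline on a (simulated or loaded) cohort.

Runs every stage — survival, heritability, GxT screen with scores /
clustering / strain selection, trajectory and frailty quantification, the
temperature model, and the biomarker screen — and writes deterministic
text outputs.  Given the same configuration and seed, two runs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import (
    SimConfig, CohortBundle, WEEKS_PER_MONTH,
    simulate as _simulate, write_cohort as _write_cohort,
)
from .survival import (
    km_fit, survival_quantile, logrank, cox_fit, rmst_diff, cv_compare,
    lifespan_summary,
)
from .heritability import estimate_H2, estimate_h2
from .gxt import (
    run_gxt_screen, gxt_table, diet_effect_scores, cluster_scores,
    select_model_strains,
)
from .trajectories import (
    weight_summaries_table, fi_summaries, deficit_incidence, bin_means,
)
from .temp import fit_temp_gamm, compare_deviance, locate_inflection

FLOAT_FMT = "%.10g"


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return v if np.isfinite(v) else None
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def _dump(obj, path: Path):
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")


def surv_records(animals: pd.DataFrame) -> pd.DataFrame:
    out = animals.rename(columns={"lifespan_months": "time",
                                  "event_observed": "event"})
    return out[["time", "event", "strain", "sex", "diet", "cage"]]


def run_pipeline(config: SimConfig, outdir, cohort: CohortBundle | None = None,
                 gxt_mouse_term: bool = True) -> dict:
    """Simulate (unless a cohort is supplied), analyze, and write outputs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = _simulate(config)
    _write_cohort(cohort, out)
    animals, phenos, frailty = cohort.animals, cohort.phenotypes, cohort.frailty
    rec = surv_records(animals)
    summary = {}

    # ---- survival
    surv_tab = lifespan_summary(rec, by=["sex", "diet"]).sort_values(["sex", "diet"])
    surv_tab.to_csv(out / "survival_summary.tsv", sep="\t", index=False,
                    float_format=FLOAT_FMT)
    strain_tab = lifespan_summary(rec, by=["strain", "diet"]).sort_values(
        ["strain", "diet"])
    strain_tab.to_csv(out / "survival_by_strain.tsv", sep="\t", index=False,
                      float_format=FLOAT_FMT)
    lr = logrank(rec, "strain")
    rmst = {}
    for sx in ("F", "M"):
        r = rmst_diff(rec[rec["sex"] == sx], group="diet")
        rmst[sx] = {"tau": r.tau, "difference": r.difference, "se": r.se,
                    "ci": list(r.ci), "p": r.p, "rmst": r.rmst}
    cox = cox_fit(rec, covariates="diet * sex", strata="strain")
    cox_cage = cox_fit(rec, covariates="diet * sex", strata="strain",
                       cluster="cage")
    cv = cv_compare(rec)
    surv_json = {
        "logrank_strain": {"statistic": float(lr["statistic"][0]),
                           "df": int(lr["df"][0]), "p": float(lr["p"][0])},
        "rmst_by_sex": rmst,
        "cox": cox.summary["coef"].to_dict(),
        "cox_p": cox.summary["p"].to_dict(),
        "cox_cage_robust_p": cox_cage.summary["p"].to_dict(),
        "cv_signed_rank_p": cv["p"],
    }
    _dump(surv_json, out / "survival_tests.json")

    # ---- heritability
    H2 = estimate_H2(animals, ci="profile")
    h2 = estimate_h2(animals, cohort.kinship, ci="profile")
    herit = {
        "H2": H2.estimate, "H2_ci": list(H2.ci),
        "h2": h2.estimate, "h2_ci": list(h2.ci),
        "proportions_H2": H2.proportions,
        "proportions_h2": h2.proportions,
    }
    _dump(herit, out / "heritability.json")

    # ---- GxT screen
    results = run_gxt_screen(phenos, animals, include_mouse=gxt_mouse_term)
    gt = gxt_table(results).sort_index()
    gt.to_csv(out / "gxt_results.tsv", sep="\t", float_format=FLOAT_FMT)
    scores = diet_effect_scores(results)
    ref_key = sorted(scores.scaled)[0]
    ref_rows = None
    clusters = {}
    selections = []
    for key in sorted(scores.scaled):
        mat = scores.scaled[key]
        tag = "_".join(key)
        mat.sort_index().to_csv(out / f"scores_{tag}.tsv", sep="\t",
                                float_format=FLOAT_FMT)
        if mat.shape[0] >= 2 and mat.shape[1] >= 2 and not mat.isna().any().any():
            cr = cluster_scores(mat, k=3, row_order=ref_rows)
            if key == ref_key and ref_rows is None:
                ref_rows = cr.row_order
            clusters[tag] = {
                "rows": cr.row_labels.to_dict(),
                "cols": cr.col_labels.to_dict(),
                "row_order": list(cr.row_order),
                "col_order": list(cr.col_order),
            }
    for ph, r in sorted(results.items()):
        sel = select_model_strains(r.fit.blup_table("(1+diet|strain)")["slope"])
        selections.append((ph, sel["max_strain"], sel["max_score"],
                           sel["min_strain"], sel["min_score"]))
    _dump(clusters, out / "clusters.json")
    pd.DataFrame(selections, columns=["phenotype", "max_strain", "max_blup",
                                      "min_strain", "min_blup"]).to_csv(
        out / "selected_strains.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    # ---- trajectories
    ws = weight_summaries_table(phenos).sort_values("mouse_id")
    ws.to_csv(out / "weight_summaries.tsv", sep="\t", index=False,
              float_format=FLOAT_FMT)
    fis = fi_summaries(frailty, animals).sort_values("mouse_id")
    fis.to_csv(out / "fi_summaries.tsv", sep="\t", index=False,
               float_format=FLOAT_FMT)
    inc = deficit_incidence(frailty, animals)
    inc.to_csv(out / "incidence.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    bw = phenos[phenos["phenotype"] == "bodyweight"].merge(
        animals[["mouse_id", "lifespan_months"]], on="mouse_id")
    pll = np.clip(bw["age_weeks"].to_numpy()
                  / (bw["lifespan_months"].to_numpy() * WEEKS_PER_MONTH), 0, 1)
    bins = bin_means(pll, bw["value"].to_numpy())
    bins.to_csv(out / "pll_bins.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    # ---- temperature
    tmp = phenos[phenos["phenotype"] == "temperature"].merge(
        animals[["mouse_id", "sex", "strain", "diet", "bw6mo",
                 "lifespan_months"]], on="mouse_id")
    tmp["pll"] = np.clip(tmp["age_weeks"] / (tmp["lifespan_months"]
                                             * WEEKS_PER_MONTH), 0, 1)
    g0 = fit_temp_gamm(tmp, include_diet=False)
    g1 = fit_temp_gamm(tmp, include_diet=True)
    dev = compare_deviance(g1, g0)
    infl = locate_inflection(tmp["pll"].to_numpy(), tmp["value"].to_numpy())
    temp_json = {
        "edf": {k: v["edf"] for k, v in g0.smooths.items()},
        "lambda": {k: v["lambda"] for k, v in g0.smooths.items()},
        "deviance_no_diet": g0.deviance,
        "diet_deviance_test": dev,
        "inflection": {
            "pll_star": infl.pll_star, "found": infl.found,
            "slope_pre": infl.slope_pre, "slope_post": infl.slope_post,
            "improvement": infl.improvement,
        },
    }
    _dump(temp_json, out / "temp_fit.json")

    # ---- biomarkers
    from .biomarkers import biomarker_screen, biomarker_table

    bm = biomarker_table(biomarker_screen(phenos, animals)).sort_values(
        ["trait", "timepoint"])
    bm.to_csv(out / "biomarkers.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    summary.update({
        "survival": surv_json, "heritability": herit,
        "gxt": gt.to_dict(), "temperature": temp_json,
        "n_biomarker_tests": int(len(bm)),
    })
    _dump(summary, out / "summary.json")
    return summary
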