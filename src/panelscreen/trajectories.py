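"""Per-mouse quantification of longitudinal series.

Weekly body weight is loess-smoothed (degree-2 local regression, tricube
weights over the third of the data nearest each fitted point) and
summarized as mean mass (MM) and the trapezoidal area under the curve
(+AUC).  Ages are rescaled to proportion of life lived (PLL = age /
lifespan) and pooled into 20 equidistant PLL bins.  Frailty assessments
(27 ordinal items in {0, 0.5, 1}) are averaged into a frailty index (FI),
summarized per mouse as an OLS slope on PLL and a final score, and
individual deficits are binarized (severe = 1) into cumulative incidence
per strain and diet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

N_PLL_BINS = 20


# ---------------------------------------------------------------------------
# loess


def smooth_series(ages, values, span: float = 1.0 / 3.0, degree: int = 2):
    """Local polynomial (loess) smoothing with tricube weights.

    For each observed age the fit uses the ``span`` fraction of points
    nearest to it, weighted by the tricube kernel of scaled distance, and
    evaluates a degree-``degree`` weighted least-squares polynomial there.
    Series with fewer than 5 points pass through unchanged (with a
    warning); non-monotone ages are sorted and duplicate ages averaged.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ages) != len(values):
        raise DataError("ages and values differ in length")
    order = np.argsort(ages, kind="stable")
    if not np.all(order == np.arange(len(ages))):
        warnings.warn("ages not sorted; sorting")
    ages, values = ages[order], values[order]
    if len(np.unique(ages)) != len(ages):
        tab = pd.DataFrame({"a": ages, "v": values}).groupby("a")["v"].mean()
        ages, values = tab.index.to_numpy(), tab.to_numpy()
    n = len(ages)
    if n < 5:
        warnings.warn("fewer than 5 points: passthrough (no smoothing)")
        return ages, values.copy()
    k = max(int(np.ceil(span * n)), degree + 1)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(ages - ages[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = values[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        # guard: ensure enough effective weight for the polynomial solve
        if (w > 0).sum() <= degree:
            w = w + 1e-8
        x = ages[idx] - ages[i]
        B = np.vander(x, degree + 1, increasing=True)
        WB = B * w[:, None]
        coef, *_ = np.linalg.lstsq(WB.T @ B, WB.T @ values[idx], rcond=None)
        out[i] = coef[0]
    return ages, out


# ---------------------------------------------------------------------------
# weight summaries


@dataclass
class WeightSummary:
    mouse_id: str
    mm: float
    plus_auc: float
    n_points: int
    x_units: str = "weeks"


def weight_summaries(ages, values, mouse_id: str = "",
                     positive_part: bool = False) -> WeightSummary:
    """Mean mass and trapezoidal AUC of a (smoothed) weight series.

    ``positive_part`` integrates the excess over the first observation
    instead of the absolute curve (alternative reading of "+AUC").
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(ages, kind="stable")
    ages, values = ages[order], values[order]
    if len(ages) < 1:
        raise DataError("empty series")
    mm = float(values.mean())
    if len(ages) < 2:
        return WeightSummary(mouse_id, mm, float("nan"), len(ages))
    base = values - values[0] if positive_part else values
    auc = float(np.trapezoid(base, ages))
    return WeightSummary(mouse_id, mm, auc, len(ages))


def weight_summaries_table(phenotypes: pd.DataFrame, span: float = 1.0 / 3.0,
                           smooth: bool = True) -> pd.DataFrame:
    """MM and +AUC per mouse from the long bodyweight table."""
    bw = phenotypes[phenotypes["phenotype"] == "bodyweight"]
    if not len(bw):
        raise DataError("no bodyweight rows")
    rows = []
    for mid, sub in bw.groupby("mouse_id"):
        a, v = sub["age_weeks"].to_numpy(), sub["value"].to_numpy()
        if smooth:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a, v = smooth_series(a, v, span=span)
        ws = weight_summaries(a, v, mouse_id=mid)
        rows.append((mid, ws.mm, ws.plus_auc, ws.n_points))
    return pd.DataFrame(rows, columns=["mouse_id", "MM", "plusAUC", "n_points"])


# ---------------------------------------------------------------------------
# proportion of life lived


def to_pll(ages, lifespan: float) -> np.ndarray:
    """Rescale ages (same units as lifespan) to proportion of life lived."""
    ages = np.asarray(ages, dtype=float)
    if lifespan <= 0:
        raise DataError("lifespan must be positive")
    if (ages > lifespan * (1 + 1e-9)).any():
        raise DataError("measurement age exceeds lifespan (referential error)")
    return np.clip(ages / lifespan, 0.0, 1.0)


def pll_bin(pll) -> np.ndarray:
    """1-based bin index over 20 equidistant PLL spans; pll=1 stays in bin 20."""
    pll = np.asarray(pll, dtype=float)
    return np.minimum(np.floor(pll * N_PLL_BINS).astype(int) + 1, N_PLL_BINS)


def bin_means(pll, values, bins: int = N_PLL_BINS) -> pd.DataFrame:
    """Mean +/- SEM of values within equidistant PLL bins."""
    pll = np.asarray(pll, dtype=float)
    values = np.asarray(values, dtype=float)
    b = np.minimum(np.floor(pll * bins).astype(int) + 1, bins)
    df = pd.DataFrame({"bin": b, "value": values})
    g = df.groupby("bin")["value"]
    out = pd.DataFrame({
        "n": g.size(),
        "mean": g.mean(),
        "sem": g.std(ddof=1) / np.sqrt(g.size()),
    })
    out.index.name = "pll_bin"
    return out.reset_index()


# ---------------------------------------------------------------------------
# frailty


def frailty_index(items) -> float:
    """FI = mean of non-missing ordinal item scores (each in {0, 0.5, 1})."""
    x = np.asarray(pd.Series(items, dtype=float))
    ok = ~np.isnan(x)
    if not ok.any():
        raise DataError("all frailty items missing at this visit")
    v = x[ok]
    if not np.isin(v, [0.0, 0.5, 1.0]).all():
        raise DataError("frailty items must be scored 0, 0.5 or 1")
    return float(v.mean())


def fi_table(frailty: pd.DataFrame, item_columns=None) -> pd.DataFrame:
    """Per-visit FI scores from the wide frailty table."""
    items = item_columns or [c for c in frailty.columns
                             if c not in ("mouse_id", "age_weeks")]
    rows = []
    for _, r in frailty.iterrows():
        vals = r[items].astype(float)
        if vals.isna().all():
            warnings.warn(f"all items missing for {r['mouse_id']}: visit dropped")
            continue
        rows.append((r["mouse_id"], float(r["age_weeks"]), frailty_index(vals)))
    return pd.DataFrame(rows, columns=["mouse_id", "age_weeks", "fi"])


@dataclass
class FISummary:
    mouse_id: str
    fi_slope: float
    final_fi: float
    n_visits: int


def fi_summaries(frailty: pd.DataFrame, animals: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse FI slope on PLL and final FI (last visit before death)."""
    from .simulate import WEEKS_PER_MONTH

    fi = fi_table(frailty)
    life = animals.set_index("mouse_id")["lifespan_months"] * WEEKS_PER_MONTH
    rows = []
    for mid, sub in fi.groupby("mouse_id"):
        if mid not in life.index:
            raise DataError(f"mouse {mid} missing from animals table")
        sub = sub.sort_values("age_weeks")
        pll = to_pll(sub["age_weeks"].to_numpy(), float(life[mid]))
        y = sub["fi"].to_numpy()
        if len(sub) >= 2 and np.ptp(pll) > 0:
            slope = float(np.polyfit(pll, y, 1)[0])
        else:
            slope = float("nan")
        rows.append((mid, slope, float(y[-1]), len(sub)))
    return pd.DataFrame(rows, columns=["mouse_id", "fi_slope", "final_fi", "n_visits"])


def deficit_incidence(frailty: pd.DataFrame, animals: pd.DataFrame,
                      item_columns=None) -> pd.DataFrame:
    """Cumulative incidence of severe deficits per item x strain x diet.

    A mouse counts as affected for an item if any visit scores it 1
    (severe); 0.5 (mild) counts as non-severe.  The IF - AL difference is
    reported per item and strain.
    """
    items = item_columns or [c for c in frailty.columns
                             if c not in ("mouse_id", "age_weeks")]
    meta = animals[["mouse_id", "strain", "diet"]]
    df = frailty.merge(meta, on="mouse_id", how="inner", validate="m:1")
    ever = df.groupby(["mouse_id", "strain", "diet"])[items].max().reset_index()
    rows = []
    for (st, dt), sub in ever.groupby(["strain", "diet"]):
        n = len(sub)
        for it in items:
            affected = int((sub[it] == 1.0).sum())
            rows.append((it, st, dt, affected, n,
                         affected / n if n else float("nan")))
    tab = pd.DataFrame(rows, columns=["item", "strain", "diet",
                                      "affected", "assessed", "incidence"])
    wide = tab.pivot_table(index=["item", "strain"], columns="diet",
                           values="incidence")
    if {"AL", "IF"} <= set(wide.columns):
        wide["difference"] = wide["IF"] - wide["AL"]
    out = wide.reset_index()
    out.columns.name = None
    return out
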