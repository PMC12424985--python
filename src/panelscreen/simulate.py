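"""Synthetic longitudinal cohorts for a recombinant-inbred panel screen.

The generator emulates the statistical structure of a 10-strain x 2-sex x
2-diet lifespan study: strain-attributable lifespan variance, phenotypes
with correlated strain intercepts and strain-specific diet slopes
(genotype-by-treatment interaction), batch effects, week-dense body-weight
trajectories with a rise/plateau/terminal-drop shape, a two-segment
temperature trajectory with a late-life knee, ordinal frailty items driven
by a shared latent deficit process, and death-driven missingness of later
measurements.  Every quantity is drawn from a single seed so cohorts are
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InvalidDesignError

WEEKS_PER_MONTH = 52.0 / 12.0

#: 27 non-invasive deficit items scored on the 0 / 0.5 / 1 ordinal scale.
FRAILTY_ITEMS = (
    "alopecia", "body_condition", "breathing_rate", "cataracts", "coat_condition",
    "corneal_opacity", "dermatitis", "diarrhea", "distended_abdomen", "eye_discharge",
    "forelimb_grip", "fur_color_loss", "gait_disorder", "genital_prolapse",
    "hearing_loss", "kyphosis", "malocclusion", "menace_reflex", "microphthalmia",
    "nasal_discharge", "piloerection", "rectal_prolapse", "righting_reflex",
    "tail_stiffening", "tremor", "tumor", "vestibular_disturbance",
)

DEFAULT_PHENOTYPES = ("lean_mass", "adiposity", "rdw", "hgb")

#: frailty/temperature visit schedule in weeks of age.
FRAILTY_SCHEDULE = (21, 43, 68, 95, 121, 147)


def _default_lifespan_params() -> dict:
    # Gaussian lifespans: grand mean 23 months; residual SD 5.5 and strain SD
    # 3.18 put the strain-attributable fraction at 3.18^2/(3.18^2+5.5^2)=0.25;
    # sexes differ by ~2 months and the diet benefit is male-specific.
    return {
        "mean": 23.0,
        "sd": 5.5,
        "strain_sd": 3.18,
        "sex_effect": 2.0,
        "diet_effect_male": 2.0,
        "diet_effect_female": 0.3,
    }


@dataclass
class SimConfig:
    """Configuration of a synthetic panel-screen cohort.

    Phenotype-scale parameters (``strain_sd`` etc.) are in units of the
    assay phenotype SD; lifespan parameters are in months; the timepoint
    schedule is in weeks of age.
    """

    n_strains: int = 10
    mice_per_cell: int = 20
    strain_sd: float = 1.0
    diet_slope_sd: float = 0.5
    intercept_slope_corr: float = -0.5
    sex_effect: float = 0.5
    diet_effect: float = -0.5
    sex_by_diet: float = 0.25
    residual_sd: float = 1.0
    batch_sd: float = 0.25
    mouse_sd: float = 0.5
    lifespan_model: str = "gaussian"
    lifespan_params: dict = field(default_factory=_default_lifespan_params)
    censoring_rate: float = 0.0
    timepoint_schedule: tuple = (45, 97, 149)
    phenotype_names: tuple = DEFAULT_PHENOTYPES
    timepoint_trend: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("strain_sd", "diet_slope_sd", "residual_sd", "batch_sd", "mouse_sd"):
            if getattr(self, name) < 0:
                raise InvalidDesignError(f"{name} must be >= 0")
        if abs(self.intercept_slope_corr) > 1:
            raise InvalidDesignError("|intercept_slope_corr| must be <= 1")
        if self.mice_per_cell < 1:
            raise InvalidDesignError("mice_per_cell must be >= 1")
        if self.n_strains < 2:
            raise InvalidDesignError("n_strains must be >= 2")
        if not 0 <= self.censoring_rate < 1:
            raise InvalidDesignError("censoring_rate must be in [0, 1)")
        sched = tuple(self.timepoint_schedule)
        if len(sched) == 0:
            raise InvalidDesignError("timepoint_schedule must be non-empty")
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise InvalidDesignError("timepoint_schedule must be strictly increasing")
        self.timepoint_schedule = sched
        self.phenotype_names = tuple(self.phenotype_names)
        if self.lifespan_model not in ("gaussian", "gompertz"):
            raise InvalidDesignError("lifespan_model must be 'gaussian' or 'gompertz'")
        if self.lifespan_model == "gompertz":
            p = self.lifespan_params
            if p.get("shape", 0) <= 0 or p.get("rate", 0) <= 0:
                raise InvalidDesignError("gompertz shape and rate must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timepoint_schedule"] = list(self.timepoint_schedule)
        d["phenotype_names"] = list(self.phenotype_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class CohortBundle:
    """A simulated cohort: animals, longitudinal tables, kinship, and truth."""

    animals: pd.DataFrame
    kinship: pd.DataFrame
    truth: dict
    phenotypes: pd.DataFrame | None = None
    frailty: pd.DataFrame | None = None

    @property
    def strains(self) -> list:
        return sorted(self.animals["strain"].unique())


# ---------------------------------------------------------------------------
# kinship


def generate_kinship(n_strains: int, seed: int) -> pd.DataFrame:
    """Simulate a strain-level additive relatedness matrix.

    Strains are assigned founder-ancestry proportions (Dirichlet over 8
    founders); relatedness is the correlation-normalized Gram matrix of
    those proportions shrunk toward the identity (inbred strains are
    mostly unrelated, with modest founder sharing), then rescaled so the
    mean diagonal equals 1.  The result is symmetric PSD and deterministic
    given the seed.
    """
    if n_strains < 2:
        raise InvalidDesignError("kinship needs n_strains >= 2")
    rng = np.random.default_rng(seed)
    P = rng.dirichlet(np.full(8, 0.5), size=n_strains)
    S = P @ P.T
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    K = 0.75 * np.eye(n_strains) + 0.25 * R
    K /= np.mean(np.diag(K))
    labels = [f"CC{i+1:03d}" for i in range(n_strains)]
    return pd.DataFrame(K, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# animals and lifespan


def _strain_labels(n: int) -> list:
    return [f"CC{i+1:03d}" for i in range(n)]


def generate_cohort(config: SimConfig) -> CohortBundle:
    """Generate the animals table (design, lifespans, censoring, kinship).

    Lifespans follow the configured generative model with strain random
    effects; mice are conditioned on surviving to the 6-month intervention
    start (draws below 6 months are redrawn), matching a design in which
    analysis is restricted to intervention survivors.
    """
    ss = np.random.SeedSequence(config.seed)
    s_kin, s_life, s_pheno, s_weight, s_frail, s_temp = ss.spawn(6)
    rng = np.random.default_rng(s_life)

    kinship = generate_kinship(
        config.n_strains, int(s_kin.generate_state(1)[0] % (2**31)))
    strains = _strain_labels(config.n_strains)
    cells = [(st, sx, dt) for st in strains for sx in ("F", "M") for dt in ("AL", "IF")]
    rows = []
    mouse_no = 0
    cage_no = 0
    for st, sx, dt in cells:
        for j in range(config.mice_per_cell):
            if j % 4 == 0:
                cage_no += 1
            mouse_no += 1
            rows.append((f"M{mouse_no:04d}", st, sx, dt, f"C{cage_no:04d}"))
    animals = pd.DataFrame(rows, columns=["mouse_id", "strain", "sex", "diet", "cage"])
    n = len(animals)

    lp = config.lifespan_params
    strain_sd = float(lp.get("strain_sd", 0.0))
    if strain_sd > 0:
        z = rng.normal(0.0, 1.0, config.n_strains)
        if lp.get("kinship_effects", True):
            # additive-genetic structure: strain effects follow the kinship,
            # so the iid and kinship heritability models nearly coincide
            C = np.linalg.cholesky(kinship.to_numpy()
                                   + 1e-10 * np.eye(config.n_strains))
            u = strain_sd * (C @ z)
        else:
            u = strain_sd * z
    else:
        u = np.zeros(config.n_strains)
    u_map = dict(zip(strains, u))
    u_mouse = animals["strain"].map(u_map).to_numpy()
    male = (animals["sex"] == "M").to_numpy(dtype=float)
    iffed = (animals["diet"] == "IF").to_numpy(dtype=float)

    if config.lifespan_model == "gaussian":
        mu = (
            lp.get("mean", 23.0)
            + u_mouse
            + lp.get("sex_effect", 0.0) * male
            + iffed * np.where(male > 0, lp.get("diet_effect_male", 0.0),
                               lp.get("diet_effect_female", 0.0))
        )
        sd = float(lp.get("sd", 5.5))
        T = mu + rng.normal(0.0, sd, n)
        # condition on surviving to intervention at 6 months
        for _ in range(200):
            bad = T <= 6.0
            if not bad.any():
                break
            T[bad] = mu[bad] + rng.normal(0.0, sd, int(bad.sum()))
        T = np.maximum(T, 6.01)
    else:
        a, b = float(lp["rate"]), float(lp["shape"])
        frail = np.exp(u_mouse + np.log1p(
            -np.clip(iffed * np.where(male > 0, lp.get("diet_hr_male", 0.0),
                                      lp.get("diet_hr_female", 0.0)), None, 0.99)))
        U = rng.uniform(size=n)
        # inverse-CDF of the Gompertz with proportional frailty
        T = np.log1p(-b * np.log(U) / (a * frail)) / b
        for _ in range(200):
            bad = T <= 6.0
            if not bad.any():
                break
            U = rng.uniform(size=int(bad.sum()))
            T[bad] = np.log1p(-b * np.log(U) / (a * frail[bad])) / b
        T = np.maximum(T, 6.01)

    event = np.ones(n, dtype=int)
    if config.censoring_rate > 0:
        pick = rng.uniform(size=n) < config.censoring_rate
        C = rng.uniform(18.0, 34.0, n)
        cens = pick & (C < T)
        T = np.where(cens, C, T)
        event = np.where(cens, 0, 1)

    animals["lifespan_months"] = T
    animals["event_observed"] = event

    # 6-month baseline body weight: sex + strain + noise (grams)
    bw_strain = rng.normal(0.0, 2.0, config.n_strains)
    bw_map = dict(zip(strains, bw_strain))
    animals["bw6mo"] = (
        25.0 + 5.0 * male + animals["strain"].map(bw_map).to_numpy()
        + rng.normal(0.0, 1.5, n)
    )

    # realized strain-attributable fraction of lifespan variance
    resid = T - (
        lp.get("mean", 23.0) + u_mouse + lp.get("sex_effect", 0.0) * male
        + iffed * np.where(male > 0, lp.get("diet_effect_male", 0.0),
                           lp.get("diet_effect_female", 0.0))
    ) if config.lifespan_model == "gaussian" else T - T.mean()
    v_strain = float(np.var(u_mouse))
    v_resid = float(np.var(resid))
    truth = {
        "config": config.to_dict(),
        "lifespan_strain_effects": {s: float(v) for s, v in u_map.items()},
        "realized_lifespan_strain_varfrac": v_strain / (v_strain + v_resid)
        if (v_strain + v_resid) > 0 else 0.0,
        "phenotype_effects": {},
        "_seeds": {
            "pheno": int(s_pheno.generate_state(1)[0] % (2**31)),
            "weight": int(s_weight.generate_state(1)[0] % (2**31)),
            "frail": int(s_frail.generate_state(1)[0] % (2**31)),
            "temp": int(s_temp.generate_state(1)[0] % (2**31)),
        },
    }
    return CohortBundle(animals=animals, kinship=kinship, truth=truth)


# ---------------------------------------------------------------------------
# longitudinal phenotypes


def _bw_template(pll: np.ndarray) -> np.ndarray:
    """Unit-peak body-weight shape: rise to peak at 40% PLL, gentle decline,
    terminal drop over the last 10% of life."""
    xp = np.array([0.0, 0.4, 0.9, 1.0])
    fp = np.array([0.60, 1.00, 0.88, 0.70])
    return np.interp(pll, xp, fp)


def generate_phenotypes(cohort: CohortBundle, config: SimConfig) -> CohortBundle:
    """Augment a cohort with assay phenotypes, body weight, temperature and
    frailty items.  Rows exist only while the mouse is alive."""
    if "lifespan_months" not in cohort.animals.columns:
        raise InvalidDesignError("cohort has no lifespans; run generate_cohort first")
    if len(config.timepoint_schedule) == 0:
        raise InvalidDesignError("timepoint_schedule is empty")

    seeds = cohort.truth["_seeds"]
    animals = cohort.animals
    strains = cohort.strains
    n_s = len(strains)
    life_wk = animals["lifespan_months"].to_numpy() * WEEKS_PER_MONTH
    male = (animals["sex"] == "M").to_numpy(dtype=float)
    iffed = (animals["diet"] == "IF").to_numpy(dtype=float)
    strain_idx = pd.Categorical(animals["strain"], categories=strains).codes

    frames = []

    # ---- assay phenotypes at the scheduled timepoints
    rng = np.random.default_rng(seeds["pheno"])
    rho = config.intercept_slope_corr
    cov = np.array([
        [config.strain_sd ** 2, rho * config.strain_sd * config.diet_slope_sd],
        [rho * config.strain_sd * config.diet_slope_sd, config.diet_slope_sd ** 2],
    ])
    # cholesky of a possibly singular 2x2
    L = np.zeros((2, 2))
    L[0, 0] = np.sqrt(cov[0, 0])
    if L[0, 0] > 0:
        L[1, 0] = cov[1, 0] / L[0, 0]
    L[1, 1] = np.sqrt(max(cov[1, 1] - L[1, 0] ** 2, 0.0))

    pheno_truth = {}
    n_mice = len(animals)
    sched = np.asarray(config.timepoint_schedule, dtype=float)
    n_batches = max(2, n_mice // 50)
    for ph in config.phenotype_names:
        us = (L @ rng.standard_normal((2, n_s))).T  # (intercept, slope) per strain
        mouse_re = rng.normal(0.0, config.mouse_sd, n_mice)
        batch_eff = rng.normal(0.0, config.batch_sd, (len(sched), n_batches))
        pheno_truth[ph] = {
            "strain_intercepts": {s: float(v) for s, v in zip(strains, us[:, 0])},
            "strain_diet_slopes": {s: float(v) for s, v in zip(strains, us[:, 1])},
        }
        for t_i, wk in enumerate(sched):
            alive = life_wk >= wk
            if not alive.any():
                continue
            idx = np.where(alive)[0]
            batch = rng.integers(0, n_batches, len(idx))
            val = (
                us[strain_idx[idx], 0]
                + us[strain_idx[idx], 1] * iffed[idx]
                + config.sex_effect * male[idx]
                + config.diet_effect * iffed[idx]
                + config.sex_by_diet * male[idx] * iffed[idx]
                + config.timepoint_trend * t_i
                + mouse_re[idx]
                + batch_eff[t_i, batch]
                + rng.normal(0.0, config.residual_sd, len(idx))
            )
            frames.append(pd.DataFrame({
                "mouse_id": animals["mouse_id"].to_numpy()[idx],
                "phenotype": ph,
                "timepoint": t_i,
                "age_weeks": wk,
                "value": val,
                "batch": [f"{ph}_t{t_i}_b{b}" for b in batch],
            }))

    # ---- weekly body weight (week-dense up to death)
    rng_w = np.random.default_rng(seeds["weight"])
    bw_slope_strain = rng_w.normal(-0.05, 0.03, n_s)  # multiplicative IF response
    pheno_truth["bodyweight"] = {
        "strain_diet_factors": {s: float(v) for s, v in zip(strains, bw_slope_strain)}
    }
    bw6 = animals["bw6mo"].to_numpy()
    wrows = {"mouse_id": [], "age_weeks": [], "value": []}
    for i in range(n_mice):
        lw = life_wk[i]
        ages = np.arange(4.0, np.floor(lw) + 1.0)
        pll = ages / lw
        shape = _bw_template(pll)
        peak = bw6[i] / _bw_template(np.array([26.0 / lw]))[0]
        w = peak * shape
        if iffed[i] > 0:
            w = np.where(ages >= 26.0, w * (1.0 + bw_slope_strain[strain_idx[i]]), w)
        w = w + rng_w.normal(0.0, 0.6, len(ages))
        wrows["mouse_id"].append(np.full(len(ages), animals["mouse_id"].iloc[i]))
        wrows["age_weeks"].append(ages)
        wrows["value"].append(w)
    bw = pd.DataFrame({
        "mouse_id": np.concatenate(wrows["mouse_id"]),
        "phenotype": "bodyweight",
        "timepoint": -1,
        "age_weeks": np.concatenate(wrows["age_weeks"]),
        "value": np.concatenate(wrows["value"]),
        "batch": "weekly",
    })
    frames.append(bw)

    # ---- body temperature: two-segment trajectory with knee at 80% PLL
    rng_t = np.random.default_rng(seeds["temp"])
    t_strain = rng_t.normal(0.0, 0.15, n_s)
    t_mouse = rng_t.normal(0.0, 0.10, n_mice)
    trows = []
    for t_i, wk in enumerate(FRAILTY_SCHEDULE):
        alive = life_wk >= wk
        idx = np.where(alive)[0]
        if not len(idx):
            continue
        pll = wk / life_wk[idx]
        val = (
            37.2
            - 0.5 * pll
            - 4.0 * np.clip(pll - 0.8, 0.0, None)
            + 0.15 * male[idx]
            + t_strain[strain_idx[idx]]
            + t_mouse[idx]
            + rng_t.normal(0.0, 0.25, len(idx))
        )
        trows.append(pd.DataFrame({
            "mouse_id": animals["mouse_id"].to_numpy()[idx],
            "phenotype": "temperature",
            "timepoint": t_i,
            "age_weeks": float(wk),
            "value": val,
            "batch": f"temp_t{t_i}",
        }))
    frames.extend(trows)

    phenotypes = pd.concat(frames, ignore_index=True)

    # ---- frailty items: latent deficit process increasing in PLL
    rng_f = np.random.default_rng(seeds["frail"])
    loadings = rng_f.uniform(0.6, 1.4, len(FRAILTY_ITEMS))
    f_strain = rng_f.normal(0.0, 0.2, n_s)
    f_mouse = rng_f.normal(0.0, 0.25, n_mice)
    frows = []
    for wk in FRAILTY_SCHEDULE:
        alive = life_wk >= wk
        idx = np.where(alive)[0]
        if not len(idx):
            continue
        pll = wk / life_wk[idx]
        latent = 1.2 * pll + f_strain[strain_idx[idx]] + f_mouse[idx] \
            + rng_f.normal(0.0, 0.25, len(idx))
        x = loadings[None, :] * latent[:, None] + rng_f.normal(0.0, 0.3, (len(idx), len(FRAILTY_ITEMS)))
        score = np.where(x < 1.1, 0.0, np.where(x < 1.8, 0.5, 1.0))
        tab = pd.DataFrame(score, columns=list(FRAILTY_ITEMS))
        tab.insert(0, "age_weeks", float(wk))
        tab.insert(0, "mouse_id", animals["mouse_id"].to_numpy()[idx])
        frows.append(tab)
    frailty = pd.concat(frows, ignore_index=True)

    truth = dict(cohort.truth)
    truth["phenotype_effects"] = pheno_truth
    return CohortBundle(
        animals=animals, kinship=cohort.kinship, truth=truth,
        phenotypes=phenotypes, frailty=frailty,
    )


def simulate(config: SimConfig) -> CohortBundle:
    """Full simulation: design + lifespans + all longitudinal tables."""
    return generate_phenotypes(generate_cohort(config), config)


# ---------------------------------------------------------------------------
# on-disk round trip


def write_cohort(bundle: CohortBundle, outdir) -> None:
    """Write animals.csv, phenotypes.csv, frailty.csv, kinship.csv, truth.json."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.animals.to_csv(out / "animals.csv", index=False, float_format="%.10g")
    if bundle.phenotypes is not None:
        bundle.phenotypes.to_csv(out / "phenotypes.csv", index=False, float_format="%.10g")
    if bundle.frailty is not None:
        bundle.frailty.to_csv(out / "frailty.csv", index=False, float_format="%.10g")
    bundle.kinship.to_csv(out / "kinship.csv", float_format="%.12g")
    truth = {k: v for k, v in bundle.truth.items() if not k.startswith("_")}
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_cohort(indir) -> CohortBundle:
    from pathlib import Path

    ind = Path(indir)
    animals = pd.read_csv(ind / "animals.csv")
    kinship = pd.read_csv(ind / "kinship.csv", index_col=0)
    phenotypes = pd.read_csv(ind / "phenotypes.csv") if (ind / "phenotypes.csv").exists() else None
    frailty = pd.read_csv(ind / "frailty.csv") if (ind / "frailty.csv").exists() else None
    truth = {}
    if (ind / "truth.json").exists():
        with open(ind / "truth.json") as fh:
            truth = json.load(fh)
    return CohortBundle(animals=animals, kinship=kinship, truth=truth,
                        phenotypes=phenotypes, frailty=frailty)
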