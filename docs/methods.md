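# Methods

`panelscreen` implements the statistical machinery of a recombinant-inbred
panel screen: a longitudinal study in which a fixed panel of inbred strains
(10 by default), both sexes, and two diet arms (ad libitum feeding, AL, and
2-day-per-week intermittent fasting, IF) are followed to natural death with
repeated phenotyping.  This note records the models, the numerical choices,
and what the synthetic data generator does and does not emulate.

## The mixed-model engine

Every model in the package is a Gaussian linear mixed model

y = Xβ + Σₖ Zₖ uₖ + ε,  uₖ ~ N(0, σ² Γₖ(θ)),  ε ~ N(0, σ² I),

fit by restricted maximum likelihood.  Four covariance structures are
supported per random term:

- **iid intercepts** per group level (strain, mouse, batch, cage), one
  relative-SD parameter;
- **unstructured 2×2** correlated (intercept, diet-slope) pair per strain,
  parameterized by the Cholesky factor (ℓ₁₁ ≥ 0, ℓ₂₁, ℓ₂₂ ≥ 0), which keeps
  the block PSD and makes the intercept–slope correlation
  ρ = ℓ₁₁ℓ₂₁ / √(ℓ₁₁²(ℓ₂₁² + ℓ₂₂²)) a derived quantity;
- **scaled-by-K**: strain effects with covariance σ_g² K for a known
  kinship matrix K (rescaled so its mean diagonal is exactly 1);
- **explicit iid coefficient blocks** (used by the penalized-spline
  smoother).

β and σ² are profiled out; all solves go through M = I + A′A with
A = [Z₁F₁, …, Z_K F_K] (Woodbury), so each likelihood evaluation costs one
q×q Cholesky where q is the total random-effect dimension.  The data
cross-products Z′Z, Z′X, Z′y are computed once per fit; only the O(q²)
factor applications vary along the optimization path.  The REML criterion
follows the standard convention, and the test-suite verifies it against a
direct dense-covariance evaluation (V = ΣZGZ′ + σ²I) to 1e−6 on toys of
n ≤ 200.

**Optimization.**  Covariance parameters live on the relative-SD /
Cholesky scale with non-negative diagonal bounds, so boundary estimates
(zero variances) are exact.  L-BFGS-B (ftol 1e−14) is followed by a Newton
polish on a central-difference gradient, which brings parameter accuracy to
~1e−10 — enough for balanced-layout estimates to match ANOVA closed forms
to 1e−8.  A second start at 0.3× the default initial values runs if the
first fails.  At the boundary (between-group mean square below the within
mean square) the REML residual estimate pools the variance rather than
equaling MSW; the implementation follows REML.

**BLUPs** are conditional modes ΓZ′W⁻¹(y − Xβ̂) with conditional SDs from
σ²(Γ − ΓZ′W⁻¹ZΓ) (β̂ uncertainty ignored, as is conventional).  In the
balanced one-way case they reduce to the shrinkage formula
(nσ_u²/(nσ_u² + σ²))(ȳⱼ − ȳ), verified to 1e−8.

**Variance-component LRT.**  Diet-effect heterogeneity across strains is
tested by dropping the strain diet slope and its correlation (2 covariance
parameters) and referring 2Δℓ_REML (floored at 0) to χ²₂.  This reference
is conservative at the boundary — the null calibration test shows rejection
well under the nominal 5% — and an equal-weights χ² mixture option exists
but is off by default.

**Model-based means.**  Contrasts are computed on an equal-weight reference
grid over all categorical fixed factors, continuous covariates at their
mean; SEs from the GLS covariance of β̂; default df = n − p with a
Satterthwaite option.  Satterthwaite denominator df uses the gradient of
c′Cov(β̂)c with respect to (θ, σ²) and the inverse of a numerically
differentiated REML information matrix; with no (or zero-variance) random
effects it reduces to the residual df.

## Synthetic cohorts

The generator emulates the design the analysis assumes, not physiology:

- **Design**: `n_strains` × 2 sexes × 2 diets × `mice_per_cell` (defaults
  10 × 2 × 2 × 20 = 800 mice), 4 mice per cage within cell.
- **Lifespan** (months): Gaussian by default — mean 23, residual SD 5.5,
  strain SD 3.18 (strain-attributable fraction 0.25), sex effect 2,
  diet benefit 2.0 in males and 0.3 in females; draws are conditioned on
  surviving past the 6-month intervention start.  These values put the
  cohort in the regime of a panel lifespan study: within-strain CV near a
  quarter of the mean, sex-specific IF response of roughly two months, and
  a quarter of lifespan variance attributable to strain.  A Gompertz mode
  (shape/rate with log-hazard strain frailty) exists for survival realism;
  euthanasia is treated as death, so the default censoring rate is 0 and
  any requested censoring is administrative-uniform over 18–34 months.
- **Assay phenotypes** at scheduled ages (default weeks 45/97/149):
  grand mean + sex + diet + sex×diet + timepoint trend + strain intercept
  + strain diet slope (jointly normal with correlation
  `intercept_slope_corr`) + mouse intercept + collection batch + noise.
  Rows exist only while the mouse is alive.  Effect sizes are in phenotype
  SD units and are testability choices, not published values.
- **Body weight**: weekly from week 4 to death; a piecewise-linear
  unit-peak template (rise to peak at 40% of life lived, gentle decline,
  terminal drop) anchored to the mouse's 6-month weight, with a
  strain-specific multiplicative IF response.
- **Temperature**: two-segment trajectory in PLL with a knee at 0.8 and a
  4 °C/PLL terminal slope, plus sex/strain/mouse effects.
- **Frailty**: 27 items share a latent deficit process linear in PLL with
  strain and mouse offsets and item-specific loadings, cut at fixed
  thresholds into {0, 0.5, 1}.
- **Kinship**: strains receive Dirichlet founder-ancestry proportions over
  8 founders; K is the Gram matrix of those proportions rescaled to mean
  diagonal 1 (symmetric PSD by construction).

All randomness flows from one seed through named child streams, so any
bundle is byte-reproducible.  What passing tests show is that the
*estimators* recover planted structure under the model's assumptions; the
generator does not emulate assay-specific error structure, informative
missingness beyond death, or real genetic architecture, so numbers from
real cohorts will differ.

## Heritability

Broad-sense H² comes from the strain random-intercept model (covariates
sex × diet): H² = σ_u²/(σ_u² + σ²).  Narrow-sense h² replaces the iid
strain covariance with σ_g² K.  Replicates are never collapsed to strain
means (doing so biases heritability upward).  The share of variance
explained by fixed effects is var(Xβ̂) / (var(Xβ̂) + σ_u² + σ²).
Profile CIs invert the REML profile of the single variance-ratio parameter
at the χ²₁ 0.95 cutoff (brentq to 1e−12; endpoints verified by direct
re-evaluation to 0.01 on the deviance scale); bootstrap CIs resample
strains — the exchangeable unit — with replacement (default B = 500).

## GxT screen and strain selection

Per phenotype: Blom rank-normal transform (Φ⁻¹((r − 3/8)/(n + 1/4)),
average ranks for ties); fixed effects diet × sex × timepoint + 6-month
body weight; random (1 + diet | strain), (1 | mouse), (1 | batch).  Diet is
treatment-coded with AL as reference, so the strain diet slope is the
strain's deviation from the population IF−AL response and ρ is the
correlation between strain baseline and strain response.  Diet contrasts
come from model-based means overall and within sex/timepoint; BH adjusts
p-values across phenotypes (diet and GxT separately).  Strain diet-effect
scores add the slope BLUP to the stratum's population diet contrast; the
scaled variant z-scores each strain across phenotypes within a stratum
(sample SD).  Ward/Euclidean clustering with k = 3 groups phenotypes and
strains; the row order of a designated reference stratum (first stratum by
default) can be imposed on the others.  Model strains are the argmax and
argmin of the slope BLUPs, ties broken lexicographically.

## Survival

KM, log-rank (overall and pairwise with BH), and the strain-stratified Cox
model (Efron ties; convergence tightened to 1e−12 so small-data
coefficients are exact to the partial-likelihood root) are delegated to
lifelines; a Breslow-ties Newton is implemented in-package.  The cage
sensitivity analysis uses a cluster-robust sandwich covariance by cage
rather than a frailty term.  RMST is the area under the KM step function on
[0, τ] with a Greenwood-based variance; τ defaults to the smallest
per-group maximum observed time, and quantiles that the curve never reaches
are missing, never extrapolated.  CV = sd/mean per strain × diet with an
exact Wilcoxon signed-rank test on paired strain differences (zero
differences dropped).

## Trajectories and frailty

Loess is a degree-2 local regression with tricube weights over the third
of the data nearest each fitted point (statsmodels' lowess is degree-1,
hence the in-package smoother).  MM is the mean of the smoothed weekly
series; +AUC is its trapezoidal integral over the observed age range in
gram·weeks (x-axis in weeks, recorded in the output); a positive-part
variant (area above the first observation) is available by flag.
PLL = age/lifespan; 20 equidistant bins with the final bin closed at 1.
FI is the mean of non-missing item scores; its slope is OLS on PLL; the
final FI is the last assessment before death.  Deficit incidence binarizes
severe = 1 exactly (0.5 is non-severe) and counts a mouse as affected if
any visit is severe.

## Longevity biomarkers

Per trait × timepoint: rank-normalized lifespan on rank-normalized trait +
diet + sex + rank-normalized 6-month body weight, random intercepts for
strain and batch (fixed-effects fallback for tiny designs); the trait term
is tested by F(1, df) with Satterthwaite denominator df; one BH pass pools
all trait × timepoint tests.  Weekly body weight enters as MM and +AUC
rather than per timepoint.  Mice must be alive to be measured, so later
timepoints condition on survival; this selection is inherent to the design
and deliberately left in place.

## Temperature model

The additive model uses cubic B-spline bases (dimension 10, equally spaced
knots) with second-difference penalties for s(PLL) and s(6-month weight),
parametric sex and strain (strain fixed, to allow hypothesis tests), and a
per-mouse random intercept.  Each penalty is eigendecomposed; the null
space (linear trend) joins the fixed effects and the range space becomes an
iid coefficient block, so smoothing parameters are REML-selected by the
same engine (λ = 1/θ²).  Effective df per smooth is the trace of the
corresponding block of the penalized hat matrix plus 1 for the linear
term; as λ → ∞ the smooth collapses to a line (edf → 1).  The diet test
compares profiled ML log-likelihoods of nested parametric structures on a
χ² with df = added parameters.  Late-life inflection is localized by
continuous two-segment least squares over a knot grid of step 0.01 on
[0.5, 0.95]; if the best broken stick improves the single-line RSS by less
than 1% (relative), the result is "no inflection" rather than a spurious
knot.

## Problem sizes and determinism

The test-suite runs its simulations at sizes chosen to make each check
sharp but quick: 50 random toys for the dense-REML oracle; 50 cohorts of
800 mice for heritability recovery; 200 null and 2 × 100 alternative
phenotypes (10 strains × 80 mice, two timepoints) for LRT calibration and
power; 100 seeds for ρ/BLUP recovery; 20 seeds for inflection recovery.
The end-to-end pipeline writes all outputs with fixed float formatting and
sorted keys, and two runs from the same configuration and seed are
byte-identical.

## Known limitations

- The variance LRT's χ² reference is conservative at the boundary; no
  simulation-based null is provided.
- The Cox cage sensitivity uses a marginal (sandwich) variance, not a
  shared-frailty hazard model.
- Satterthwaite df relies on numerically differentiated information and is
  validated by calibration, not by digit-matching an external
  implementation.
- The GAMM reports approximate smooth-term inference; conclusions should
  rest on the deviance comparison.
- Heritability CIs treat strains as exchangeable; with 10 strains both
  profile and bootstrap intervals are wide, mirroring the design's real
  uncertainty.
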