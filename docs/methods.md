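# Methods

This note records the statistical model, the numerical choices, and the
limits of what the synthetic-data experiments demonstrate.

## Model and estimands

A binary (or additive-coded) genetic exposure x, clinical covariates c
(with intercept), a two-dimensional functional mediator m(s) on [0, 1] —
the aligned SRVF of a planar contour — and a scalar outcome y are linked
by two regressions:

* mediator model: m_{i,j}(s) = x_i α_j(s) + c_i' ξ_j(s) + η_{i,j}(s) + ε_{i,j}(s),
  with η a zero-mean Gaussian-process subject effect and ε white
  measurement error, independent of (x, c);
* outcome model: y_i = x_i γ + Σ_j ∫ m_{i,j}(s) β_j(s) ds + c_i' κ + δ_i,
  with homoscedastic Gaussian δ independent of the rest.

Plug-in causal estimands for the 0-vs-1 exposure contrast: ADE = γ,
SAIE(s) = Σ_j α_j(s) β_j(s), AIE = ∫ SAIE ds, ATE = ADE + AIE, and
MP = |AIE/ATE|·100%. The absolute value in MP is deliberate: AIE and ATE
can have opposite signs, and MP is reported as a positive proportion.
MP is undefined (NaN, flagged) when ATE = 0.

Causal interpretation rests on the usual sequential-ignorability
assumptions: SUTVA; no unmeasured exposure–outcome, mediator–outcome, or
exposure–mediator confounding given the measured covariates; and no
mediator–outcome confounder affected by the exposure. None of these are
testable from the data; the sensitivity machinery below probes the
mediator–outcome one.

## Shape representation

Contours are treated as open curves with a consistently ordered seed
landmark (seed-point search is out of scope). Normalization removes
translation (centroid) and scale (unit arc length); rotation and
reparameterization are removed by alignment to a Karcher-mean atlas, so
the aligned SRVF depends only on shape up to the registration lattice's
resolution.

Numerical choices:

* **SRVF convention** q = f′/√|f′| — the square-root form, which makes
  the reparameterization action an L² isometry and ties unit arc length
  to unit SRVF norm. Since finite differencing on a curved contour gives
  |f′| = 1 only to O(h²), the cohort pipeline renormalizes each SRVF to
  exact unit L² norm (`srvf_transform(..., unit_norm=True)`).
* **Derivatives**: central differences, one-sided at the endpoints.
  Zero-speed segments (|f′| below 1e−12 of the mean speed) map to q = 0.
* **Rotation**: closed-form Procrustes via SVD of the 2×2 cross-
  covariance ∫ q_ref qᵀ ds, with determinant-sign correction so the
  result is always a proper rotation (det +1); a numerically zero
  cross-covariance returns the identity with a degenerate flag.
* **Warping**: dynamic programming over monotone boundary-preserving
  piecewise-linear warps through grid nodes with local slopes k/l,
  1 ≤ k, l ≤ 3 (the seven coprime steps). The DP is exact on this
  lattice — verified against exhaustive path enumeration — and the edge
  cost integrates the aligned-SRVF mismatch by trapezoid on the fine
  grid. Implemented with numba.
* **Alignment iteration**: two rotation/warping sweeps per subject;
  Karcher mean initialized at the medoid (deterministic), iterating
  align → average → renormalize with tolerance 1e−5 on the mean change
  and at most 20 passes. The total aligned squared distance is
  non-increasing across iterations.
* The aligned SRVFs enter the regression models unchanged (no
  re-scaling after alignment).

## Estimation

* **Mediator model**: pointwise OLS at every grid point and coordinate
  dimension — no smoothing, so fitted + residual reproduces the data at
  machine precision and residual functions retain the full within-curve
  correlation for the bootstrap.
* **Outcome model**: the mediators, centered at their cross-sectional
  mean function (equivalently, the mediator-model fit at sample-mean
  exposure and covariates — identical because OLS residuals with an
  intercept have zero column means), are expanded in the FPCA basis of
  the pooled two-dimensional functions; the two coordinate dimensions
  are concatenated so cross-dimension covariance is respected. Scores
  z_{ik} = Σ_j ∫ m_{i,j} φ_{k,j} ds (trapezoid) enter an OLS of y on
  [x, z, C]; β_j(s) = Σ_k b_k φ_{k,j}(s).
* **Basis dimension**: default is the smallest K explaining 95% of
  variance; a fixed K is available. Under heavy white measurement error
  the 95%-PVE rule admits many small-eigenvalue components: AIE and its
  interval remain well behaved (the integration averages the noise), but
  pointwise SAIE bands become very wide. Band analyses aiming at spatial
  localization should fix a modest K (the band experiments below use
  K = 8); this is an analysis-resolution choice, not a correctness one.
* Degenerate mediators (numerically zero variance) drop to K = 0 and the
  outcome model reduces to OLS of y on (x, C), whose exposure coefficient
  then equals the screening model's.
* **Quadrature**: trapezoid on the uniform grid everywhere, so model
  fitting, score computation, and estimand integration are mutually
  consistent and ∫ SAIE ds = AIE holds to quadrature precision for every
  fit and every bootstrap replicate.

## Inference

Wild bootstrap, B = 1000 by default (experiments below use 250–500).
Per replicate, independent per-subject multipliers v_i, w_i (Rademacher
default; Mammen and Gaussian available) rebuild

    m*_i(s) = fitted_i(s) + v_i · residual_i(s)
    y*_i    = γ̂ x_i + Σ_j ∫ m*_{i,j}(s) β̂_j(s) ds + c_i' κ̂ + w_i · δ̂_i

— one multiplier per subject scales the whole residual function,
preserving the within-curve correlation of η + ε, and the outcome's
mediator-dependent part is rebuilt from the starred mediators so y*
stays coupled to m*. Both models are refit on the starred data (FPCA
basis recomputed per replicate). Residuals are leverage-scaled (HC2,
r_i/√(1−h_ii)) before resampling: the outcome design carries 1 + K + p
parameters, and raw residuals would understate the error scale by a
factor ≈ √(1 − q/n).

Intervals are symmetric, point ± C(ϑ) with C the empirical (1−ϑ)
quantile of |θ* − θ̂|; the SAIE band is constant-width from the sup-norm
deviation quantile, hence simultaneous. Significance calls require
strict zero exclusion. Significant subregions are the contiguous runs of
grid points where the band excludes zero. Multiplicity across candidate
SNPs is handled by the AIE-interval screen only; no further correction
is applied.

## Screening

Per-SNP OLS with covariate adjustment (the model has fixed effects only;
kinship/random-effect correction is out of scope), vectorized by
Frisch–Waugh–Lovell residualization against the shared covariates and
cross-checked against per-SNP statsmodels fits. Monomorphic SNPs yield
NaN with a flag. BH adjustment (via statsmodels) at default q = 0.05
selects the candidate set. Missing dosages are imputed with the per-SNP
modal value at load time. Principal components for population structure
are consumed as supplied covariates, not computed here.

## Synthetic data

The generator draws x ~ Bernoulli(maf) (or Binomial(2, maf)),
covariates (intercept, standard normal, Bernoulli(0.5)), η from a
squared-exponential GP (length-scale 0.2, variance 0.5, independent
across the two dimensions), ε and δ with SD 0.5, and default coefficient
functions α_j = β_j = (sin 2πs, cos 2πs) with γ = 1 — giving true
AIE = 1, ATE = 2, a moderate signal-to-noise regime. True estimands are
returned in closed form by quadrature, so every experiment compares
against an exact truth. Same seed ⇒ byte-identical cohorts.

The hidden-confounder variant adds U ~ N(0,1) to the mediator (constant
in s, both dimensions, strength a) and to the outcome (strength b) while
withholding U from the returned covariates — a controlled violation of
mediator–outcome unconfoundedness. Error metrics follow the standard
simulation conventions: MIAE/MISE for functions, MAE/MSE for scalars.

A separate shape-cohort generator perturbs a smooth bean-like template
contour (synthetic stand-in for a segmented corpus-callosum outline)
with random rotations, translations, scalings, smooth reparameterizations
and jitter, to exercise the alignment pipeline end to end.

What the generator does *not* emulate: linkage disequilibrium between
SNPs, realistic MRI segmentation noise, non-Gaussian or heteroscedastic
outcome errors, and mediator–exposure interactions. Passing tests
therefore certify the estimators and their inference under the stated
model, not robustness to those departures.

## Experiment sizes

Chosen to keep the full validation suite and the acceptance script at a
few minutes each on one CPU:

* estimator recovery: n ∈ {100, 200, 400}, 100 replications per size —
  MISE(α̂), MISE(β̂), MSE(γ̂), MSE(AIE) all decrease monotonically;
* interval coverage: n = 200, B = 500, 120 replications (nominal 95%);
* band size/power: n = 200, B = 300, 120 null and 100 bump replications
  at K = 8; the planted effect is a Gaussian bump at s = 0.7 (SD 0.05)
  with α-amplitude 4 and β-amplitude 3 — a strong, localized signal;
* sensitivity: confounder strengths {0, 0.5, 1, 2}, 100 replications
  each, n = 300 — mean |AIE bias| is non-decreasing in strength;
* screen FDR: global null, n = 200, 200 SNPs, 500 replications.

## Known limitations

* Closed contours are handled as open curves from a fixed seed landmark;
  no seed-point search.
* No roughness penalization in either functional regression; smoothness
  is inherited from the data and, in the outcome model, from the FPCA
  truncation.
* The mediation model excludes exposure–mediator interaction terms, and
  outcomes are analyzed one at a time.
* The bootstrap is residual-based: under strong model misspecification
  of the outcome model its intervals inherit that misspecification.
* The per-SNP screen ignores relatedness and population structure beyond
  the supplied covariates.
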