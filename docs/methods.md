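# Methods

## Model and estimands

For a binary treatment T ∈ {0, 1}, potential outcomes Y(0), Y(1) and
covariates X, the target is the conditional average treatment effect
τ(x) = E[Y(1) − Y(0) | X = x].  The outcome is BMI and lower is better,
so the personalized optimal decision is d(x) = 0 if τ(x) > 0, 1 if
τ(x) < 0, and a tie if τ(x) = 0.  Identification needs the usual
assumptions: no unmeasured confounding given X, overlap
0 < P(T = 1 | X = x) < 1, consistency Y = T·Y(1) + (1 − T)·Y(0), and
E(ε | X = x) = 0 for the outcome noise.

### The five metalearners

All learners accept any regressor/classifier obeying the scikit-learn
fit/predict contract; the default base learner is a random forest with
`n_estimators=100, min_samples_split=7` (regression for outcomes and
imputed effects, classification for the propensity).

* **T**: μ̂₀ on the control arm, μ̂₁ on the treated arm,
  τ̂ = μ̂₁ − μ̂₀.
* **S**: one joint fit μ̂(x, t) on the augmented design [x, t, x·t];
  τ̂(x) = μ̂(x, 1) − μ̂(x, 0).  The interaction block is *enforced*: on
  the design [x, t] a linear joint model gives μ(x,1) − μ(x,0) = β₂,
  constant in x, so the fitted policy could not be personalized.  The
  constructor raises if `interactions=False`.
* **X**: after the T-stage arm fits, imputed individual effects
  D⁰ = μ̂₁(x) − Y(0) (controls) and D¹ = Y(1) − μ̂₀(x) (treated) are
  regressed on x to give τ̂₀ and τ̂₁, combined as
  τ̂(x) = ĝ(x) τ̂₀(x) + (1 − ĝ(x)) τ̂₁(x).
* **SX / SXwint**: the joint model μ̂(x, t) (without / with the x·t
  block) is fit on a *training* split; D⁰, D¹ and hence τ̂₀, τ̂₁ are
  computed on a disjoint *re-training* split; ĝ is fit on the union of
  the two.  Splitting the model-fitting data reduces the overfitting
  that comes from imputing effects with a model evaluated on its own
  training points.

### Propensity convention

ĝ(x) estimates the **control** probability P(T = 0 | X = x) and weights
τ̂₀ — the effect model fit on controls, whose targets were imputed with
the treated-outcome model.  Much of the causal-inference literature
parameterizes the propensity as P(T = 1); this package keeps the control
convention throughout (`PropensityModel.predict_control_probability`).
Estimated propensities are clipped to [δ, 1 − δ] with δ = 0.01; the
clipping guards the blend against degenerate weights and applies only to
*estimated* propensities — a forced override (`propensity_override`,
used to verify the endpoint identities ĝ ≡ 0 ⇒ τ̂ = τ̂₁ and
ĝ ≡ 1 ⇒ τ̂ = τ̂₀) is taken literally.

### Split topology

One run shares a single testing half across all learners so their group
decompositions are comparable.  T, S and X train on the complementary
half; SX and SXwint split that half again into equal training and
re-training parts (1/4 : 1/4 : 1/2 of the cohort), and their propensity
is fit on the union — the same records the other learners train on.
Splits are seeded: indices are shuffled by `numpy.random.default_rng(seed)`
and cut to largest-remainder sizes (earlier parts win remainder ties).
Whether one split is shared across treatments or re-drawn per treatment
is configurable (`resplit_per_treatment`); the default shares it.

## Covariance-test feature screen

BMI is regressed on all 14 lifestyle/demographic features (never Weight,
Height or BMI itself).  Columns are standardized to unit variance and
the outcome centered so path knots are comparable across variables; the
lasso path is computed by LARS.  For the k-th entering variable at knot
λ_k with next event at λ_{k+1} and pre-entry active set A,

    T_k = ( ⟨y, X β̂(λ_{k+1})⟩ − ⟨y, X_A β̂_A(λ_{k+1})⟩ ) / σ²,
    p   = P(Exp(1) > T_k) = exp(−T_k).

σ² defaults to the residual variance of the full least-squares fit
(RSS / (n − p − 1)), appropriate in this n ≫ p regime.  Lasso paths can
drop and re-admit variables; the active set "before entry" is read off
the path at each event rather than accumulated, so re-entries are
handled correctly.  Categorical features enter as one-hot blocks and a
block is summarized by its first entering column.  The Exp(1) null is an
asymptotic-in-p result: simulations of the *closed-form* orthogonal
statistic show visible finite-p deviation up to several hundred
predictors, so the test-suite calibration check runs at p = 1000.

## Evaluation

On the testing half, O = records whose observed treatment equals the
learner's decision, NO = records where it differs, ties excluded from
both and reported separately (|O| + |NO| + |ties| = testing size), and
G = records whose observed treatment equals the one-for-all rule — the
arm with lower mean BMI on the testing data (exact ties break toward
T = 0 with a warning; the criterion is the mean because the general rule
is the "better on average" recommendation).  KS test 1 compares BMI in O
vs NO, KS test 2 in O vs G; D is the maximum ECDF distance and the
p-value uses the asymptotic Kolmogorov distribution with effective size
mn/(m+n) (`exact=True` switches to the exact small-sample law).  The
asymptotic tail underflows for extreme D; p is floored at the smallest
positive double so the (0, 1] contract holds.  Ratio reports
(level-1 : level-0 counts, 3 decimals) are emitted for O, NO, the
testing half and the full filtered cohort, since a verbal "testing data"
attribution can be ambiguous; zero denominators are reported as
undefined, not infinity.

## Synthetic cohorts: the stated world

The generator emulates the obesity-lifestyle schema so synthetic data
exercise the same validation and encoding paths as real data: continuous
covariates uniform on their declared ranges (Age: normal 25.6 ± 6.48
clipped to [15, 56]), categoricals with the overweight-cohort frequency
profile, Height uniform on [1.45, 1.98] m.  Outcomes follow

    Y(0) = μ₀(x) + ε,  Y(1) = μ₀(x) + τ(x) + ε,  ε ~ N(0, σ²),

with BMI = Y and Weight back-computed as Y·Height², so BMI invariants
hold on synthetic records.  Defaults, chosen once as a plausible
overweight-cohort world and not revisited:

* baseline μ₀ = 32 + 1.8·z(Age) + 1.2·z(FCVC) − 0.8·z(FAF) +
  1.5·1[FHWO=Yes] (kg/m²; z-scores under the *design* distribution, so
  closed-form expectations are known — E[τ(X)] is the linear form's
  intercept);
* linear CATE τ = −0.5 + 1.2·z(FCVC) + 0.8·z(FAF) + 0.6·z(CH2O): both
  signs occur, so the optimal decision is genuinely person-specific;
  alternatives: zero, constant c, and a smooth sign-switching
  nonlinear form amplitude·sin(z₁ + z₂);
* noise σ = 1.0 kg/m², moderate relative to CATE magnitudes ~1–2;
* assignment: logistic in z(Age), z(FCVC) (overlap guaranteed by the
  link) or a constant p ∈ (0, 1).

The drawn T is embedded into the treatment schema column (e.g. CALC
"Sometimes"/"No", or CH2O above/below 2 L), and no structural function
may reference the treatment column.  Latent truths live in `truth_*`
columns that are never encoded as covariates.

What the simulator does **not** emulate: the real data's covariate
dependence structure (covariates are drawn independently), measurement
error, the SMOTE-style oversampling of the public obesity dataset, or
confounding beyond the logistic assignment.  A green synthetic test
therefore establishes correctness of the estimators under their stated
assumptions, not real-world effect sizes.

## Numerical conventions and edge cases

* BMI categories by half-open intervals [0,18.5), [18.5,25), [25,30),
  [30,35), [35,40), [40,∞) — the published category descriptions leave
  boundary membership and small gaps (24.9–25.0) unstated; half-open
  intervals give a contiguous partition.  The overweight *filter* is the
  literal "BMI over 24.9" (strict), deliberately kept despite the slight
  mismatch with the 25.0 category edge.
* CALC maps every positive drinking frequency (Sometimes, Frequently,
  Always) to T = 1; the source treats CALC as binary although the raw
  data carry more levels.
* One-hot encoding: drop-first over the lexicographically sorted
  *observed* levels (unobserved declared levels would only add constant
  columns); constant columns are dropped with a logged warning.
* Base-learner seeding: every stochastic component receives
  `sha256(seed ":" stage-label) mod 2³¹`, so runs are reproducible and
  stages are decorrelated.
* Validation rejects rather than imputes: missing values, unknown
  levels, out-of-range continuous values and non-positive Height/Weight
  are errors naming the offending column/records.

## Known limitations

* Two treatment arms only; no dynamic or multi-stage regimes.
* No confidence intervals or asymptotic inference for τ̂.
* The SX learner's joint model class excludes interactions by design,
  so its exact-recovery regime under linear bases is constant-τ data;
  SXwint covers the heterogeneous linear case.  Their equivalence under
  ĝ ≡ 0 is likewise a noiseless-linear statement and is not asserted for
  random-forest bases on noisy data.
* The covariance test is implemented for the n > p regime (σ² from the
  full least-squares fit); no high-dimensional guarantees, and no
  spacing or exact post-selection tests.
* With many-level categoricals, SXwint's interaction design grows as
  2p + 1 columns and random-forest fits slow accordingly.
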