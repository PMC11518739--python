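# Methods

`rrscore` implements a Bayesian reduced-rank regression (RRR) that predicts a
panel of 13 cognitive and motor outcome measures in an aging cohort from a
small number of latent *composite risk scores*, together with the per-outcome
ordinary-least-squares (OLS) baselines it is benchmarked against, a
subject-grouped cross-validation harness, and a synthetic-cohort generator
with known ground truth.

## Outcome panel

Raw clinical columns of a long-format visit table (one row per
subject-visit) are reduced to 13 outcome measures:

- **Gait** (4 dual-task conditions: walking while subtracting serial 7s,
  subtracting while walking, walking while box-checking, box-checking while
  walking): per condition an *overall speed* = dual-task speed + single-task
  speed and a *dual-task cost* = dual-task speed − single-task speed
  (8 measures).  The two walking-dual conditions share the single max-walk
  speed as their single-task reference.
- **Cognition**: CERAD total score, word-list learning, word-list recall,
  and the Trail Making Test composites TMT A + TMT B (overall speed) and
  TMT B − TMT A (cognitive flexibility) (5 measures).  TMT times above the
  administration caps (180 s part A, 300 s part B) are treated as invalid
  cells.

All outcomes are oriented so that **higher = worse**: speeds and
correct-item counts are negated, completion times kept.  Under this
orientation a positive predictor effect reads as a risk factor and a
negative one as protective.

Missing raw inputs propagate to missing composites; outcomes are never
imputed.  Predictors are imputed per subject by forward- then
backward-filling across visits (a predictor is assumed to change only when
re-measured); subjects missing a predictor entirely are excluded and
reported.

## The model

With `X` the `j x m` encoded predictor matrix and `Y` the `j x 13` centered
outcome matrix,

```
theta = X A                     A: m x k   (latent composite scores)
Y     ~ Normal(theta B^T, sigma^2)   B: 13 x k, all entries > 0
```

- Each element of `A` has a `Laplace(0, b)` prior with `b = 1`, promoting
  element-wise sparsity: predictors that do not inform the composite score
  are pulled to zero.
- Each element of `B` has a lognormal prior with median 1 and shape
  `sigma_B = 0.25`, enforcing positivity.  Because `B > 0`, the sign of
  every predictor effect lives entirely in `A`, and ranking visits by the
  composite score equals ranking them by any predicted outcome.
- The observation noise is fixed at `sigma = 0.908` on the standardized
  outcome scale; `rrscore.ols.pooled_training_sd` recomputes this quantity
  as the observation-weighted pooled training RMSE of the 13 OLS fits, and
  `PriorConfig.per_outcome_sd` allows per-outcome overrides.
- Missing outcome cells contribute nothing to the likelihood, so visits
  with partial outcome panels still inform the fit; the posterior
  predictive imputes them for free.
- Variants: `k = 1` (headline), `k = 2`, and `k = 1` with `B` fixed to 1
  (a single shared linear predictor, matching the complexity of one OLS
  model).

### Ordinal predictors

Ordinal predictors (activity and alcohol ratings 0–4, family-history
counts, and genetic dose variables GBA severity / SNCA / ApoE4 / MAPT,
all treated as ordinal) enter through the cumulative monotonic transform

```
cmo(x, zeta) = sum_{i<=x} zeta_i,        zeta in the D-simplex,
```

which is monotone in the category code with freely inferred spacings; the
effect size and sign come from the regression coefficient.  The spacings
carry a symmetric `Dirichlet(alpha = 1)` prior (uniform on the simplex;
prior mean spacing `1/D`, i.e. centered on a linear trend).  For the
genetic 0/1/2 doses the free spacing interpolates dominant, additive and
recessive effect shapes.  Encoded columns are bounded in `[0, 1]` and are
*not* z-standardized, preserving the interpretability of spacing-times-
effect summaries.

### Centering and identifiability

Outcomes are centered (via the training-fold standardizer), so the model
omits an intercept.  That omission is only valid if the linear predictor
is centered too: binary and `cmo`-encoded columns have nonzero means, and
leaving them uncentered forces the fit to absorb the mean of `theta` into
exactly those columns (in recovery experiments this appeared as a common
~3-posterior-SD shift on all genetic loadings).  The likelihood therefore
uses `(X - x_bar) A B^T` with `x_bar` the training-row column means; for an
ordinal column the mean is recomputed per draw from the sampled spacings,
`x_bar = sum_l zeta_l q_l` with `q_l` the training fraction of codes `>= l`.
Effects, spacings and significance are unchanged in meaning; the reported
composite score stays `theta = X A`.

The multiplicative non-identifiability `(A c, B / c)` is constrained only
by the priors, as in the model's design; diagnostics therefore also cover
the identifiable product `C = A B^T`, and split-R-hat is recorded for all
raw parameters.

### Sampling

Posterior sampling uses an in-package No-U-Turn Sampler (dynamic
Hamiltonian Monte Carlo with multinomial trajectory sampling,
dual-averaging step-size adaptation targeting 0.8 acceptance, and a
diagonal mass matrix estimated from the middle warmup window).  Gradients
of the log posterior are analytic; the Laplace prior contributes a
subgradient at 0, as in other HMC treatments of double-exponential priors.
Unconstrained parameterizations: `B = exp(u)` with a normal prior on `u`;
each simplex is softmax-normalized from log-gamma-augmented coordinates
(`p(y_i) ∝ exp(alpha y_i − e^{y_i})`), whose pushforward is exactly
`Dirichlet(alpha)` — chosen over stick-breaking for its trivial Jacobian.

Reference settings: 2 chains, 2000 burn-in, 500 retained draws each
(1000 posterior draws per parameter).  Tests and the evaluation harness
use reduced settings (chains × 150–500 draws after 150–300 burn-in),
which the diagnostics justify on these well-conditioned posteriors
(split-R-hat ≲ 1.05, no divergences); the sampler warns when the
divergence fraction exceeds 5%.  A leapfrog energy error above 1000 counts
as a divergence; maximum tree depth is 10.

### Significance

A predictor is significant when the 95% highest-posterior-density interval
of its loading excludes 0.  The HPD is the narrowest window of the sorted
draws containing `ceil(0.95 S)` draws; it is oracle-tested against
exhaustive window enumeration and cross-checked against arviz (which keeps
one more order statistic).  OLS coefficients use t-tests with a Bonferroni
threshold of 0.05 divided by the number of coefficient tests performed —
by default pooled across all 13 models (the conservative reading), with a
per-model option; intercepts are not counted.

## Evaluation protocol

5-fold cross-validation grouped by subject: subjects (not visits) are
randomly partitioned, so repeated visits never straddle train and test
(≈80/20 split).  Per fold, outcome and continuous-predictor
standardization is refit on training rows.  The score is

```
R^2 = 1 − MSE / var(whole dataset)
```

with the variance taken per outcome over *all* rows (train and test) on
that fold's standardized scale, so the five fold scores share one
normalizer; the score is negative when a prediction is worse than the
whole-dataset mean.  Each OLS model trains on every row where its own
outcome is observed; the RRR trains once on the union of those rows; both
are scored on exactly the same observed test cells.  The Bayesian fold
score is the mean over posterior draws of the per-draw R², then averaged
over folds.  Fold-wise scores of the two arms are compared per outcome
with a t-test — paired across the shared folds by default (the folds are
identical for both models), with an unpaired option; zero-variance inputs
are flagged as degenerate rather than tested.  Final coefficients come
from refits on the complete dataset.

Open protocol choices resolved here: the whole-dataset variance is
computed globally per outcome (not per fold-standardizer); the ordinal
spacings are refit per fold along with everything else; the fixed `sigma`
is shared across outcomes (per-outcome override available).

## Synthetic cohorts

The generator emulates a biennial aging-cohort visit table from a known
instance of the model itself: 15 predictors (sex; education; age advancing
2 years per visit; BMI; skeletal muscle index; pack-years; lognormal
serum NFL; hypertension; family history of PD/dementia; activity and
alcohol ratings 0–4; GBA/SNCA/ApoE4/MAPT doses) with normal / lognormal /
Bernoulli / categorical marginals — plausible shapes, fully configurable,
with no attempt to match any real cohort's prevalences.  A sparse `A_true`
(a configurable fraction of entries exactly 0, nonzero magnitudes
`effect_scale × U(0.5, 1.5)` with random signs), positive lognormal
`B_true`, and Dirichlet-drawn true spacings produce latent targets
`theta B^T + E`.

Raw clinical columns are obtained by *inverting* the outcome formulas, so
that running the preprocessing stage on a noise-free cohort returns the
latent targets exactly (to 1e-10).  Each latent target column is mapped
onto a plausible clinical mean/SD (stored in the truth record); because
the two walking-dual conditions share the single max-walk speed, their
four composites carry only three raw degrees of freedom, and the
`cost_walk_box` row of `B_true` (and its noise column) is set to the
implied combination of the other three — exactly the linear dependence any
cohort derived from raw measurements would exhibit.  Rows whose implied
raw speeds would be negative or whose TMT times would exceed the caps get
their noise resampled (bounded retries, then a hard error).

Missingness is injected cell-wise at configured rates for predictors and
raw outcomes, with the guarantee that every retained subject keeps at
least one observed value per predictor (so the imputation eligibility rule
is exercised); subjects for which that cannot hold are dropped with a
warning.  Geometric visit dropout is available (default off).

**What passing tests show — and what they do not.**  The generator draws
from the model's own generative assumptions: linear effects, rank-k
structure, Gaussian noise (with the one raw-consistency dependence above),
monotone ordinal effects, missingness completely at random.  Recovery and
performance results on these cohorts validate the inference machinery,
not the model's adequacy for real cohort data, where nonlinearity,
informative missingness, within-subject correlation, and distribution
shift are all in play.

## Numerical choices and limitations

- Problem sizes: recovery tests use 400 subjects × 4 visits with
  reduced sampling (2 × 300/300); pipeline tests use 40–60 subjects.
  These sizes give stable diagnostics while keeping the default suite
  quick.
- Zero-variance columns are excluded from standardization with a warning;
  rows with no observed outcome are excluded from the likelihood with a
  warning; degenerate all-equal posterior draws yield a zero-width HPD,
  significant iff nonzero.
- Visits are treated as independent given the predictors (no random
  effects); `k > 2`, nonlinear links, and mixed-model extensions are out
  of scope.
- The paired fold t-test has 4 degrees of freedom; it flags only large,
  consistent performance differences.
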