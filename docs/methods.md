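# Methods

`elemdyn` analyses longitudinal biomarker profiles — several hundred ordered
measurements per subject, such as elemental concentrations laid down in
dentine over childhood — as realisations of a dynamical system, and asks two
questions per series: *how many quasi-stable regimes does it occupy* and
*how periodic is it*. The per-subject answers become features for
covariate-adjusted group comparisons and case/control classification.

## Potential landscapes and state counting

A series z(t) is treated as an overdamped stochastic system
dz = −U′(z) dt + σ dW. At steady state the Fokker–Planck equation ties the
stationary density P_d to the potential, U = −(σ²/2) log P_d. The series is
standardised to unit sample SD (σ = 1) and the potential reported on the
noise scale U/σ², so U = −log(P_d)/2 and landscapes are comparable across
elements and subjects; the state count is invariant under affine rescaling
of the raw values by construction.

P_d is a Gaussian KDE with Scott's bandwidth h = n^(−1/5)·SD, evaluated on a
500-point grid spanning the data range padded by 3h. Local minima of U are
quasi-stable states; local maxima are tipping points. Numerically, extrema
are first-difference sign changes (plateaus collapse to their left edge),
and minima are only accepted where the density exceeds a floor of
`floor_fraction` × max density. The floor defaults to 0.02: −log P_d
diverges in empty tails, and at n ≈ 500 the kernel bump of a single
isolated tail point reaches ≈ 0.7% of the density maximum, so a floor of
10⁻³ (a common choice) fails to suppress one- or two-point artefacts; 0.02
removes bumps supported by up to ~3 points while genuine basins (≥ 10% of
the maximum in every simulated regime here) are untouched. Exactly one
tipping point — the potential argmax between them — is reported per
adjacent pair of accepted minima, so minima and maxima always alternate and
every proper density yields at least one state. No basin-depth or
basin-mass criterion beyond the floor is applied; consequently, shallow
ripples of the KDE occasionally register as states on smooth mono-stable
series (measured: ~10–15% of 500-sample Ornstein–Uhlenbeck runs show a
second minimum whose confining barrier is below 0.01 on the U/σ² scale).
A depth filter would remove these but is deliberately out of scope.

Rolling landscapes repeat the estimate in windows of 50 samples (step 1 by
default) on a shared grid for rendering state formation over time. Windows
are standardised individually. Fifty-point KDEs are noisy: even stationary
series show spurious window-level bimodality in a minority of windows, so
rolling output is a visualisation aid, not the statistic; the full-series
landscape is what feeds the state count.

## Delay embedding and recurrence quantification

Periodicity is measured on the Takens delay embedding of each series: rows
(z_i, z_{i+τ}, …, z_{i+(m−1)τ}). The delay τ is the first local minimum of
the average mutual information between the series and its lagged copy
(joint histogram, 16 equal-width bins by default; quantile binning is
available and makes AMI invariant under monotone rescaling). Strict
inequality on both sides defines a local minimum and plateaus take their
left edge; if no interior minimum exists the global minimiser is returned
with a warning. Note a structural property of this estimator: for strongly
periodic signals the AMI valley is nearly flat around the quarter period,
and the first-local-minimum rule lands on the valley's left shoulder, a few
samples early — e.g. lag 6 rather than 10 for a noiseless sinusoid sampled
40 points per period (the valley bottom is at 8–10). The embedding
dimension m is the smallest dimension at which the Kennel
false-nearest-neighbour fraction drops below 1% (ratio threshold 10,
attractor-size threshold 2, all configurable); pairs coincident to within
float rounding are never counted false. Parameters are estimated per
subject and element; cohort tables also carry the per-series (τ, m) as
diagnostics.

The recurrence plot marks pairs of embedded points within ε of each other
(Euclidean norm by default; maximum norm available). ε is adaptive: the
quantile of the off-Theiler pairwise distance distribution that realises a
fixed 10% recurrence rate, making features comparable across elements with
different scales and spread. A Theiler window w excludes pairs with
|i − j| < w; the default w = 1 excludes exactly the line of identity. The
diagonal-line histogram P(l) counts maximal runs on the superdiagonals
(upper triangle only; border-truncated lines count at observed length) and
yields

- determinism DET = Σ_{l≥lmin} l·P(l) / Σ_{l≥1} l·P(l),
- mean diagonal length MDL = Σ_{l≥lmin} l·P(l) / Σ_{l≥lmin} P(l),
- diagonal entropy ENT = −Σ_{l≥lmin} p(l) ln p(l) (nats, over l ≥ lmin),

with lmin = 3 successive measurements. Undefined cases (no recurrent
points; no line reaching lmin) propagate as missing values, never zeros.

## Synthetic cohorts

Real dentine profiles are not publicly deposited, so the package generates
cohorts with the structure the analysis assumes: 36 cases / 31 controls,
five elements (Cu, Li, Mg, Mn, Zn), per-subject series lengths uniform on
300–600 samples at ~0.021 yr/sample (roughly weekly sampling over up to
~12.6 years), sex ~ Bernoulli(0.5) and age ~ N(55, 10²) as covariates.

Three series generators cover the observed phenomenology:

- **bistable_well** — Euler–Maruyama integration of dz = −V′(z)dt + σdW in
  the quartic double well V = barrier·(z⁴ − 2z²) (+ an optional linear tilt
  that starves one basin); defaults barrier 1, σ 1, one emitted sample per
  0.3 model-time units with 10 substeps of h = 0.03. At these defaults the
  Kramers escape time (≈ 8 time units) is short against the record, so
  series switch basins repeatedly — series that visit a high- and a
  low-concentration regime. The integrator refuses non-confining
  polynomials, raises on blow-up naming dt, and warns when
  h·max|V″| ≥ 2 on the visited range.
- **monostable_well** — the same integrator in V = z²/2 (OU-like), the
  mono-stable analogue.
- **oscillation** — piecewise sinusoids with segment-wise frequency, mean,
  amplitude and Gaussian noise, emulating a shift from slow to fast cycling.

The planted (case vs control) cohort plants the two effect axes: copper is
bistable in controls and mono-stable in cases (state-count effect); Mg and
Mn keep identical oscillatory signals but triple the case noise SD
(determinism/entropy effect); Li carries a mild state effect through a
tilted case well; Zn is null. Noise-based determinism planting was chosen
over amplitude reduction because amplitude-starved series drift to higher
estimated embedding dimensions, where the determinism of near-noise series
becomes high-variance. A side effect worth knowing: changing the noise SD
also reshapes the marginal density, so DET-planted elements leak a weak
state-count contrast as well. The null cohort uses the control generator on
both arms for every element.

What the generators do *not* emulate: measurement error of the assay,
non-uniform or missing sampling, age-varying trends, between-element
correlation within subject, and covariate–outcome confounding (covariates
are independent of group, as in a matched design). Passing tests therefore
demonstrate that the machinery recovers planted dynamical structure under
these idealisations, not that it would on any particular real dataset.

## Group statistics

State counts are modelled per element with Poisson regression (log link,
ML/IRLS) of count on group + sex + age (+ smoking when present); RQA
features with OLS under the same adjustment. Group Wald p-values are
reported raw and Benjamini–Hochberg adjusted, within each feature family
across elements (5 tests per family; pooling is available). Degenerate
outcomes (constant across subjects, separation, non-convergence) yield
flagged results rather than exceptions; missing features drop casewise.

A calibration caveat carried by design: detected state counts live on
{1, 2, 3}, are bounded below by 1 and have variance well below their mean,
so the Poisson Wald test is structurally conservative (empirically ~0%
type-I at α = 0.05 on null cohorts). The linear-model tests are exactly
calibrated in the same simulations. The classifier AUC rank test is
conservative too, for a different reason: under the null the
cross-validated LASSO often shrinks to an intercept-only model, the test
scores tie, and the rank test returns its null midpoint, so its rejection
rate sits below nominal (~1% measured). Both behaviours control type-I
error; they only cost power. The Poisson family is retained because it is
the standard published treatment of such counts.

## Classification

Predictors are exclusively the dynamical features (n_states, DET, MDL, ENT
per element); the label and covariates are excluded by schema. The table is
split 60/40 train/test (floor rule, stratified with largest-remainder
allocation, seeded); the published description of the split direction is
contradictory, so the fraction is a parameter with default 0.6 for
training. Two families are fitted on the training split only:

- **LASSO** — L1-penalised logistic regression on internally standardised
  features; penalty chosen by cross-validated deviance (5-fold by default,
  reduced automatically when a class is smaller) over a log-spaced grid of
  25 strengths. Zero coefficients are reported as excluded features.
- **Gradient-boosted trees** — xgboost classifier tuned by stratified
  3-fold CV over a small declared grid (depth {2,3}, trees {50,150},
  learning rate {0.1,0.3}), scored by ROC AUC.

Test-set scores yield the empirical ROC (trapezoid AUC, identical to the
Mann–Whitney pair statistic); the decision threshold maximises TPR − FPR
(max distance from the chance diagonal; ties to the lower threshold, a
perfect classifier returns the midpoint of the separating gap); uncertainty
comes from 2000 bootstrap resamples of the test (score, label) pairs
(percentile AUC CI and a sensitivity band on a fixed 101-point specificity
grid; single-class resamples are skipped). Significance against chance is
the one-sided Mann–Whitney rank test of case vs control scores (exact when
sizes permit and scores are tie-free; normal approximation with tie
correction otherwise; fully tied scores return p = 0.5). A top-5 refit
repeats the fit on the features with the largest |coefficient| or
importance and is evaluated on the untouched test split.

## Validation-study sizes

The repeatable studies in `elemdyn.benchmarks` (used by the test suite and
`scripts/acceptance.py`) run at the following problem sizes, chosen as the
package's own balance of precision and turnaround: adaptive-threshold check
on n = 500 Gaussian noise; state recovery over 100 seeds of 500-sample
wells; periodicity on a 400-sample sinusoid (40 samples/period); null
calibration over 200 cohorts of 36/31 subjects with one element at a fixed
250-sample length and embedding caps (max τ 25, max m 4); planted-effect
discrimination over 25 full five-element cohorts. Classifier significance
in the repeated studies uses the rank test on test scores directly; the
2000-resample bootstrap is exercised in the single-run workflow and its own
tests.

## Known limitations

- State counting inherits KDE small-sample artefacts (see the floor
  discussion); counts on series much shorter than ~300 samples are noisy.
- The first-local-minimum delay rule is systematically a few samples early
  on strongly periodic signals (flat AMI valley).
- The Poisson state-count test is conservative by construction on bounded
  underdispersed counts.
- Rolling 50-sample landscapes are qualitative.
- Embedding assumes uniform sampling; the time axis is carried but gaps are
  not modelled.
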