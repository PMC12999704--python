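# Methods

## Model family

A growth phase is a sigmoid written in terms of the quantities an
experimentalist actually reports: the asymptotes `y_i` and `y_f` (response
units), the lag time `λ` (time units, tangent-line construction at the
inflection point) and the maximum rate `r_max` (response/time, the slope at
the inflection point). Two shapes are provided:

* Boltzmann — symmetric around the inflection; its canonical slope scale γ
  relates to the maximum rate by `r_max = (y_f−y_i)/(4γ)` and to the lag by
  `λ = x0 − 2γ`. The value at the lag time is always `(1+e²)⁻¹ ≈ 0.119` of
  the amplitude, and the points one γ before/after the inflection sit at
  27% and 73% of the amplitude — useful sanity anchors for any fit.
* Gompertz — asymmetric (fast rise, slow saturation); canonical `(b, c)`
  map to `r_max = (y_f−y_i)·c/e`, `λ = (ln b − 1)/c`, inflection
  `x0 = ln b / c`, ordinate at the inflection `y_i + (y_f−y_i)/e`.

An n-phase (polyauxic) curve stacks normalized phase sigmoids:
`y = y_i + (y_f−y_i)·Σ p_j f_j`, where each `f_j ∈ (0,1)` carries its own
lag and rate and the weights satisfy `p_j > 0`, `Σ p_j = 1`. The per-phase
rate scale inside `f_j` is `r_max,j / (|y_f−y_i|·p_j)`, so `r_max,j` is the
actual maximum slope contributed by phase j regardless of the weight.

Decreasing curves (substrate depletion) use the same types with
`y_f < y_i`; the amplitude sign carries the direction while `r_max` stays
positive. Evaluation uses `|A|` in the exponent scale so the curve always
runs from `y_i` (early) to `y_f` (late). Exponents are clamped at |x|=700,
which is exact saturation in double precision.

Conversions to the specific growth rate μ_max evaluate `(1/X)·dX/dt` at the
inflection: `r_max = μ_max·(X_f−X_i)/2` (Boltzmann, where the inflection
biomass is the midpoint) and `r_max = μ_max·(X_i + (X_f−X_i)/e)`
(Gompertz). The biomass-form curve with μ_max as the explicit parameter is
derived from these identities rather than hard-coded, so the two routes
cannot drift apart.

## Fitting pipeline

1. **Normalization.** Time and response are divided by their maxima, so all
   searches happen in O(1) units. Decreasing series are first reflected as
   `c − y` with `c = max(y)+min(y)`; this maps them onto the same
   increasing-curve search box as any other dataset (simply negating the
   response would place it outside the normalized bounds) and is inverted
   exactly on output. De-normalization: asymptotes ×`y_max`, lags
   ×`t_max`, rates ×`y_max/t_max`.
2. **Latent encoding.** Weights are softmax logits with the last logit
   pinned to zero (gauge); lags are `λ_1 ≥ 0` plus log-increments
   (`λ_{j+1} = λ_j + e^{g}`); rates are log-encoded. Every point of the
   box-bounded latent space decodes to a valid model, so no penalty terms
   are needed. Bounds (normalized units): `y_f ∈ [0.5, 1.5]`,
   `y_i ∈ [−0.5, 0.5]`, `λ_1 ∈ [0, 1]`, increments `∈ [10⁻³, 1]`,
   `ln r ∈ [ln 10⁻³, ln 10³]`, logits `∈ [−10, 10]`.
3. **Heuristic initialization.** The response is smoothed (5-point moving
   average), differentiated, and up to n derivative peaks are located by
   prominence; lags are seeded half a peak-width before each peak, rates
   from the peak heights, weights from the amplitude partition between
   peaks. Half the Differential Evolution population is jittered around
   this seed, the rest drawn uniformly in the bounds; a flat signal falls
   back to a fully uniform population with a warning.
4. **Global search.** Differential Evolution (rand-to-best/1/bin, dithered
   mutation (0.5, 1.0), crossover 0.7, population 15×dim, up to 1000
   generations, tolerance 1e-8, vectorized objective) minimizes the
   Charbonnier loss `Σ(√(r²+ε²) − ε)` with ε = 10⁻³ in normalized response
   units — quadratic for residuals below ~0.1% of the amplitude, linear
   above, so gross outliers cannot steer the search. All randomness flows
   from the single user seed.
5. **Outlier pass (ROUT-style, single pass).** Residuals of the robust fit
   are scaled by the robust standard deviation of residuals
   (68.27th percentile of |r|, corrected by N/(N−k)), converted to
   two-tailed p-values from a t distribution with N−k degrees of freedom,
   and flagged by Benjamini–Hochberg step-up at FDR level Q (default 1%,
   a conservative setting exposed as `--fdr-q`). All exclusions are
   reported; nothing is silently dropped.
6. **Local refinement.** L-BFGS-B minimizes the RSS on the cleaned data
   from the robust optimum, under the same bounds; the result is kept only
   if it does not worsen the loss.
7. **Uncertainty.** The Hessian of the RSS is taken by central finite
   differences (step `max(10⁻⁵, 10⁻⁴·|θ|)` per coordinate) with respect to
   the natural reporting parameters (`y_i`, `y_f`, free logits, lags,
   rates); the covariance is `σ̂²·H⁺` with `σ̂² = RSS/(N−k)` and `H⁺` the
   SVD pseudo-inverse truncated at 10⁻¹⁰ of the largest singular value.
   Truncated directions are surfaced through the reported numerical rank
   rather than inflated. Weight standard errors come from the delta method
   through the softmax Jacobian `J_jl = p_j(δ_jl − p_l)` (the gauge logit
   enters with zero variance). SEs are de-normalized with the same scale
   factors as the parameters.

The parameter count charged by the information criteria is `k = 2 + 3n`
(asymptotes + per-phase weight, lag, rate), although the softmax gauge
makes one weight redundant; charging the full count is the conservative
choice and keeps k comparable across software.

## Likelihood and model selection

The Gaussian log-likelihood uses the profiled MLE variance `σ² = RSS/N`,
giving the closed form `ln L̂ = −N/2·(ln(2π·RSS/N)+1)`; the
`RSS/(N−k)` estimate is reserved for the parameter covariance. N is the
post-exclusion point count, since the likelihood is evaluated on the
cleaned set. Criteria: `AIC = 2k − 2lnL̂`,
`AICc = AIC + 2k(k+1)/(N−k−1)`, `BIC = k·lnN − 2lnL̂`. The automatic rule
picks AIC when `N/k ≥ 40` and `N ≤ 200`, AICc when `N/k < 40` and
`N ≤ 200`, BIC when `N > 200`; at the overlapping N = 200 boundary the
small-sample-safe AICc is kept. For `auto`, the rule is applied once with
the n = 1 parameter count and held fixed across the sweep so per-n values
are comparable.

The sweep fits n = 1, 2, … and stops at the first n whose successor does
not improve the criterion (equality within 10⁻⁶ counts as a plateau and
the smaller n wins); `--sweep-full` fits every n up to `n_max` instead and
then applies the same first-local-minimum rule. Counts whose AICc is
undefined (`N ≤ k+1`) terminate the sweep.

**Known limitation — over-selection at moderate N.** With N ≈ 60 points at
1% noise, the (n+1)-phase model can lower the RSS by parking a tiny-weight
phase (p of order 0.01–0.05) on a local noise excursion; the AICc penalty
for three extra parameters (~8 units at N = 60) does not always reject
this, so a monoauxic dataset is classified as diauxic in roughly 15% of
replicates. The effect is purely statistical — the single-phase fits reach
their global optimum — and shrinks rapidly with smaller N (the penalty is
~15 units at N = 20, where selection is near-perfect) or stricter
criteria (BIC). Fits whose chosen model contains a phase with a very small
weight or a lag increment at the search-box floor deserve scrutiny before
biological interpretation.

## Synthetic data

The generator produces the exact model mean (it calls the same evaluation
code as the fitter) plus i.i.d. Gaussian noise of constant standard
deviation, matching the error model assumed by the likelihood. Defaults
emulate typical cumulative-assay conditions: 60 uniform points spanning
`[0, 1.2·(last inflection) + 3/r_min]` so the final plateau is visible,
noise 1% of amplitude. Outliers are additive gross errors (±magnitude·σ at
random positions, sign random), not heavy-tailed noise, so detection
scoring is unambiguous. Plateau truncation emulates batch-assay
termination rules: the series is cut at the first step (after growth is
underway, i.e. after the steepest increment) whose gain falls below a
fraction of the accumulated value.

What the generator does **not** emulate: autocorrelated or
heteroscedastic measurement error, replicate-to-replicate biological
variability, instrument drift, and negative-control subtraction artifacts.
Passing the recovery and selection suites therefore demonstrates
correctness of the estimator under its own assumptions, not robustness to
every failure mode of real assay data.

## Numerical choices and degenerate inputs

* Exponent clamp ±700 (exact to double precision); per-phase rate scale
  guarded by `|A| ≥ 10⁻¹²`.
* DE is deterministic given the seed; the final refinement never returns a
  point worse than its start; ties in the selection sweep break toward the
  smaller n.
* Fits are rejected up-front when `N ≤ k`, and after outlier removal when
  the cleaned set would leave no residual degrees of freedom.
* A zero robust residual scale with nonzero residuals is reported as a
  degenerate-scale error rather than flagging everything.
* `fix_yi` removes `y_i` from the search entirely (exact zero, for assays
  that start at zero accumulated product), while k = 2+3n is still charged.

## Test problem sizes

The simulation suites use 60-point datasets at 1% noise with 20–25 seed
replicates for recovery/selection/outlier studies and 200 replicates for
the standard-error concordance and false-positive-rate studies; these
sizes give stable pass/fail margins for the documented tolerances while
keeping the full test suite in the minutes range on one CPU.
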