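# polyauxic

Robust fitting of mono- and polyauxic growth curves — cumulative biomass,
product (e.g. methane volume in BMP assays) or substrate time series — with
sigmoidal models whose parameters are directly interpretable: lag time
λ, maximum rate r_max, and the asymptotes y_i and y_f.

Microbial cultures on complex or mixed substrates often grow in several
sequential or overlapping phases (diauxie and beyond). A single sigmoid, or
a first-order model, then hides real metabolic transitions. This package
decomposes such curves into a weighted sum of sigmoids and decides, by
information criterion, how many phases the data actually support.

## Models

Two reparameterized sigmoid families are available. For one phase with
amplitude A = y_f − y_i:

* **Boltzmann** (symmetric, logistic-type):
  `y(x) = y_i + A / (1 + exp(4·r_max·(λ−x)/A + 2))`
* **Gompertz** (asymmetric, slow-saturating tail):
  `y(x) = y_i + A·exp(−exp(1 + r_max·e·(λ−x)/A))`

λ comes from the tangent-line construction at the inflection point and
r_max is the slope there. An n-phase (polyauxic) curve is

```
y(x) = y_i + (y_f − y_i) · Σ_j p_j · f_j(x; λ_j, r_max,j)
```

with fractional amplitudes p_j > 0, Σ p_j = 1 (softmax-parameterized) and
strictly ordered lags λ_1 < λ_2 < … A reparameterized first-order model
`y = y_f·(1 − e^(−r₁t))` and a Monod saturation fit
`r(S) = r*·S/(K_M + S)` round out the family.

Fitting pipeline: max-normalization of both axes → derivative-peak
heuristic initialization → Differential Evolution under a Charbonnier
robust loss → a single ROUT outlier pass (robust residual scale, t-tail
p-values, Benjamini–Hochberg step-up at FDR level Q) → L-BFGS-B
refinement of the RSS on the cleaned data → standard errors from the
finite-difference Hessian via SVD pseudo-inverse, with delta-method
propagation to the weights. The number of phases is chosen as the first
local minimum of AIC/AICc/BIC (picked automatically from N and k) across
an n = 1, 2, … sweep.

## Worked example

```python
import numpy as np
import polyauxic as px

# simulate a diauxic Gompertz curve with 1% noise
truth = px.KineticModel(
    "gompertz", 0.0, 1.0,
    [px.PhaseParams(0.4, 5.0, 0.05), px.PhaseParams(0.6, 40.0, 0.02)],
)
data, _ = px.simulate(px.SyntheticSpec(truth, np.linspace(0, 60, 60),
                                       noise_sd=0.01, seed=1))

result = px.fit(data, px.FitOptions(family="gompertz", n=2, seed=1))
for j, ph in enumerate(result.model.phases, 1):
    print(f"phase {j}: p={ph.p:.3f}  lam={ph.lam:.2f}  rmax={ph.rmax:.4f}")
print(f"rss={result.rss:.5f}  AICc={result.ic['aicc']:.1f}")
```

prints

```
phase 1: p=0.422  lam=4.93  rmax=0.0490
phase 2: p=0.578  lam=40.05  rmax=0.0203
rss=0.00426  AICc=-384.0
```

i.e. the two lag times (true 5 and 40), the two maximum rates (true 0.05
and 0.02 response units per time unit) and the amplitude split (true
0.4/0.6) are recovered from 60 noisy points; the AICc value is what the
phase-count sweep compares across n.

The same works from the shell:

```bash
polyauxic fit data.csv --family gompertz --n 2 --seed 1 -o out/
polyauxic select data.csv --family gompertz --n-max 5 --seed 1 -o out/
polyauxic simulate --model-json model.json --noise-sd 0.01 --seed 1 -o sim/
```

`fit` and `select` write a JSON report (parameters ± SE, RSS, log-likelihood,
AIC/AICc/BIC, excluded outliers, config echo) plus a curve CSV with the
fitted and per-phase components and an outlier flag column.

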