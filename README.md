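# idras

Data-driven identification of **dynamically regulated quantities** in
multivariate time series.

Biological systems hold important internal quantities close to reference
values — but those set-points are often *moving targets* (circadian
modulation of transcription, slowly drifting division thresholds, hormonal
cycles). Given only regularly sampled observations `z^k ∈ ℝⁿ`, this package
simultaneously learns

* a scalar **combination** `c^k = g(z^k; θ)` of the observed channels, and
* a **one-step prediction filter** `ĉ^k = F(c^{k−T:k−1}; Θ)` for its time
  course (encoder → latent ODE drift → decoder),

such that `g(z(t))` tracks an unknown dynamic reference `c(t)`. Direct
minimization of the prediction error `e^k = c^k − ĉ^k` collapses to trivial
solutions, so the fit is adversarial: a **combination player** minimizes the
variance ratio

```
ratio(Ω) = var(e | real windows) / var(e | surrogate windows),   Ω = [θ, Θ]
```

against a **shuffle player** that builds surrogate windows whose final
sample is drawn from the pooled marginal (temporal order destroyed) and then
ζ-resamples them so the surrogate filtering-error *distribution* matches the
data's — blocking "constraint detector" shortcuts. A final ratio well below
1 means the temporal order of the data is genuinely more predictable than
chance; a ratio ≈ 1 means no dynamic regulation was found. Setting the
filter to zero (`static_mode`) recovers the classic fixed-set-point search
with channel-shuffled surrogates.

The learned `g` is identifiable only up to sign/affine gauge, so outputs are
standardized and scored by sign-aligned Pearson correlation `|ρ|` and the
prediction error by `NMSE = var(c − ĉ)/var(c)`.

Everything is validated against bundled ground-truth simulators:

* **kinetic gene expression** — mRNA M drives proteins P and S whose sum is
  held by strong negative feedback near a set-point proportional to an
  oscillating transcription rate K(t); observables `[P, S]`, truth `P+S`;
* **bacterial growth–division lineages** — exponential growth to a slowly
  drifting Ornstein–Uhlenbeck division threshold (a dynamic "sizer");
  observables `[x_b, α, T]` per cycle, truth `x_b·e^{αT}`, with the analytic
  one-step prediction floor `1 − e^{−2T̄/τ_u}`;
* **two-objective toy** — two disjoint channel groups, each regulated to its
  own independent slow sinusoid, for selectivity checks.

## Worked example

Simulate the oscillating-set-point kinetic model, fit, and score:

```bash
printf 'n_series: 4\nduration: 200.0\n' > sim.yaml
printf 'T: 4\nouter_iters: 20\ninner_epochs: 5\npatience: 20\nseed: 1\n' > fit.yaml

idras simulate --preset kinetic --out demo/sim --seed 0 --config sim.yaml
idras fit demo/sim/observations.csv --out demo/fit --config fit.yaml
idras evaluate demo/fit --truth demo/sim/ground_truth.csv --out demo/report.json
```

which prints (last fit iterations, then the evaluation):

```
iter   18  ratio 0.3130  entry 0.9796  KS 0.0230
iter   19  ratio 0.7507  entry 0.9943  KS 0.0472
converged: best variance ratio 0.0825
rho(|c_star|, c) = 0.9943
NMSE(c, c_hat)   = 0.0378
```

Reading this: after every shuffle-player step the ratio re-enters at ≈ 1
(`entry`), and the combination player repeatedly pushes it far below 1
(best 0.083) — strong evidence of dynamic regulation. The learned
combination correlates 0.994 with the ground-truth regulated quantity P+S,
and the filter predicts its next value to within ≈ 4% of its variance.

The same loop is available as a library:

```python
import numpy as np
from idras import KineticParams, simulate_kinetic, FitConfig, idras_fit, pearson_aligned

ts, truth = simulate_kinetic(KineticParams(n_series=4, duration=200.0),
                             np.random.default_rng(0))
result = idras_fit(ts, FitConfig(T=4, outer_iters=20, seed=1))
print(result.status, pearson_aligned(truth, result.c))
```

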