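# iwrecords

Statistical inference for **upper record values** under the **Inverse Weibull
(Fréchet-type) distribution**, motivated by accelerated thermal-stability
studies of heat-sensitive compounds (e.g. ascorbic acid), where the extreme
values of a degradation index — not its average — drive risk.

An upper record is an observation strictly larger than everything observed
before it; the i-th record is written X_u(i). The parent model is the
heavy-tailed Inverse Weibull CDF

    F(x) = exp(−ϕ x^(−γ)),   x > 0,  ϕ, γ > 0,

with cumulative hazard H(x) = −ln(1 − F(x)). Two identities organize
everything in the package:

* the record likelihood of x_u(1) < … < x_u(n) is
  f(x_u(n)) · ∏_{i<n} f(x_u(i)) / (1 − F(x_u(i)));
* H(X_u(i)) is Gamma(i, 1)-distributed, which yields both record simulators
  and the conditional density of a future record,
  g(y | z) = [H(y) − H(z)]^(k−1) e^{−(H(y)−H(z))} h(y) for the record k steps
  after a record at z.

## What the package does

* **records** — extract upper records from a raw series; simulate record
  samples by the quantile-transform (cumulative-hazard) and the
  truncated-CDF Markov constructions.
* **model / mle** — `InverseWeibullRecords` with `fit()`: record-likelihood
  MLE of (ϕ, γ) by safeguarded Newton iteration in log space, analytic score
  and observed information, Wald intervals, `summary()`.
* **bayes** — `fit_bayes()`: independent Gamma(e, f) and Gamma(g, h) priors,
  Metropolis–Hastings with per-coordinate gamma proposal kernels (exact
  Hastings correction), posterior summaries with batch-means MC error,
  equal-tailed credible intervals, hyperparameter sensitivity tables.
* **prediction** — Bayesian posterior-predictive point/median/interval for
  X_u(m), m > n, and the classical Basak–Balakrishnan predictive-likelihood
  fit that maximizes jointly over (ϕ, γ, y).
* **gof** — fit gamma, Weibull, inverse Weibull, log-normal,
  inverse-exponential and log-logistic to i.i.d. positive data and rank them
  by AIC, with BIC and the KS/AD/CvM EDF statistics.
* **simstudy** — a synthetic thermal-degradation fixture generator
  (70/85/100 °C, 10–120 min, 100 samples per temperature) and replicated
  simulation-study drivers for the MLE and Bayes estimators.

## Worked example

```python
import numpy as np
from iwrecords import (
    IWDParams, GammaPrior, MHConfig,
    InverseWeibullRecords, simulate_records_quantile, classical_predictive_fit,
)

rec = simulate_records_quantile(20, IWDParams(1.0, 1.0), seed=7)
model = InverseWeibullRecords(rec)

fit = model.fit()
print(fit.summary().round(4))
#        estimate  std err  ci 2.5%  ci 97.5%
# phi      1.7038   1.6505  -1.5310    4.9387
# gamma    1.0215   0.2234   0.5838    1.4593

post = model.fit_bayes(GammaPrior(3, 3, 3, 3), MHConfig(iterations=20000, seed=1))
print(post.summary().round(4))
#        estimate      se  mc_error    2.5%  median   97.5%
# phi      1.1266  0.5642    0.0196  0.3004  1.0304  2.4568
# gamma    0.9992  0.2074    0.0038  0.6416  0.9833  1.4295

pred = post.predict_record(m=21, level=0.95, seed=2)
print(f"next record: median {pred.conditional_median:.4g}, "
      f"95% interval ({pred.lower:.4g}, {pred.upper:.4g})")
# next record: median 1.649e+09, 95% interval (8.436e+08, 4.324e+10)
```

Reading the output: the 20 simulated records end at x_u(20) ≈ 8.2×10⁸ —
upper records of this heavy-tailed family grow like exp(i/γ), so enormous
values are expected, not errors. The MLE of γ (the tail exponent) is precise
(0.98–1.02 across methods, truth 1.0), while ϕ is weakly identified by
records — its Wald interval is wide and its posterior is right-skewed; the
Gamma(3, 3) prior (mean 1, variance 1/3) tightens it to 1.13 ± 0.56. The
predictive median for the 21st record exceeds the last observed record, as
it must.

A command-line interface mirrors the library
(`iwrecords simulate-records`, `extract-records`, `fit-mle`, `fit-bayes`,
`sensitivity`, `predict`, `predict-classical`, `gof`, `make-fixture`,
`simstudy-mle`, `simstudy-bayes`); run `iwrecords --help`.

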