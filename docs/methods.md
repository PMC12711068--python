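# Methods

## Model and parameterization

The parent distribution is the Inverse Weibull (Fréchet-type) law with CDF
F(x) = exp(−ϕ x^(−γ)) for x > 0. The package uses this (ϕ, γ) *tail*
parameterization everywhere; the scale–shape convention
F(x) = exp(−(λ/x)^γ) is reachable through λ = ϕ^(1/γ)
(`to_scale_shape` / `from_scale_shape`). Both parameters are dimensionless;
γ is the tail exponent (smaller γ means heavier upper tail; moments of order
≥ γ do not exist), and ϕ shifts the distribution (ϕ^(1/γ) is a scale).

For an upper-record sample x_u(1) < … < x_u(n) the likelihood is the density
of the last record times the hazard contributions of the earlier ones,

    L(ϕ, γ) = f(x_u(n)) ∏_{i<n} f(x_u(i)) / (1 − F(x_u(i))).

The central distributional fact is that H(X_u(i)) ~ Gamma(i, 1), where
H = −ln(1 − F) is the cumulative hazard. It supplies (a) the record
simulators, (b) the conditional density of a future record, and (c) the
master validation oracle used throughout the test suite.

## Record simulation

Two constructions are implemented and proven equivalent in distribution by a
two-sample test at 5000 replicates:

* **quantile transform**: Γ_i = cumulative sums of standard exponentials;
  the i-th uniform upper record is V_i = 1 − exp(−Γ_i) and
  X_i = F^{-1}(V_i). The composition is evaluated as X_i = H^{-1}(Γ_i),
  which is the same function written stably: V_i rounds to 1.0 in double
  precision once Γ_i ≳ 37, while H^{-1} stays accurate out to hazards of
  several hundred.
* **truncated-CDF Markov chain**: X_1 is a parent draw; X_{i+1} is a draw
  from the parent left-truncated at X_i, carried in survival space as
  S_{i+1} = (1 − U) S_i so no precision is lost as F → 1.

Records of this family grow like exp(i/γ): the 50th record at γ = 1 is of
order e^50 ≈ 5×10²¹. These magnitudes are correct and are neither clamped
nor warned about; computations that touch the deep tail go through
log1p/expm1 compositions.

## Maximum likelihood

`fit()` maximizes the record log likelihood in (ln ϕ, ln γ) with damped
Newton steps using the exact analytic gradient and Hessian (backtracking to
guarantee ascent), falling back to a quasi-Newton sweep plus up to five
jittered restarts if the direct path stalls. Defaults: score tolerance 1e-8,
200 iterations, start γ₀ = 1 and ϕ₀ = n / Σ x^(−1) (the ϕ score root at
γ = 1 ignoring the record-correction sum). The observed information is the
analytic negated Hessian; `converged` additionally requires it to be
positive definite, and the covariance of the estimates is its inverse. The
score and Hessian are exact derivatives of the log likelihood — verified
against central finite differences over a range of parameter values — and
the limits w/s → 1/ϕ and (u − s)/s → 0 as u = ϕ x^(−γ) → 0 are substituted
explicitly so the formulas stay finite when x^(−γ) underflows.

A single record is refused (n ≥ 2 required): with one record the likelihood
is unbounded in γ. Wald intervals are the standard estimate ± z·se; they are
symmetric and may cross zero for ϕ when the sample is small — a known
limitation of the normal approximation for a weakly identified, positively
skewed estimand.

### Identifiability of ϕ from records

Records concentrate information about the tail exponent γ (the Fisher
information for γ grows with n) but not about ϕ: later records are
essentially pure tail draws, so the information about ϕ saturates and the
MLE of ϕ is dominated by the first few records. At γ = 1 the estimator
ϕ̂ ≤ n / Σ x_i^(−γ̂) inherits the index-1 tail of 1/x_u(1), whose mean does
not exist: Monte-Carlo averages of ϕ̂ over replicated record samples do not
stabilize no matter how many replicates are used (medians do). The
replicated-study drivers report what is computed; users averaging ϕ̂ across
simulations should prefer medians or trimmed means. The same weak
identification makes the ϕ posterior right-skewed, so posterior means of ϕ
sit visibly above posterior medians unless the prior is concentrated.

## Bayesian inference

Priors are independent gammas, ϕ ~ Gamma(e, f) and γ ~ Gamma(g, h)
(shape/rate), and the sampler works with the unnormalized log posterior
(the normalizing constant is never evaluated). The Metropolis–Hastings chain
proposes both coordinates jointly from gamma kernels with mean at the
current state and tunable coefficient of variation; the kernel is
asymmetric, so the Hastings correction is computed exactly rather than set
to one. Defaults: 20000 iterations, 20% burn-in, thinning 1, proposal CV 0.5
auto-scaled during burn-in toward an acceptance rate in (0.2, 0.5) and
frozen afterwards (so the retained chain is a valid fixed-kernel MH sample).
The chain starts at the MLE when the data allow it, otherwise at the prior
means; a chain whose post-burn-in acceptance is exactly 0 or 1 raises
rather than summarize garbage. With an empty record sample the posterior is
the prior, which the tests exploit for prior-recovery validation; posterior
means are further validated against a 2-D trapezoid quadrature oracle on a
seeded 50-record sample.

Summaries follow the conventional MCMC report: posterior mean ("estimate"),
posterior standard deviation ("se"), batch-means Monte Carlo error with
⌈√K⌉ batches, and the 2.5/50/97.5% empirical quantiles. Credible intervals
are equal-tailed marginal quantiles. `sensitivity_table` repeats the fit
under a list of priors on identical data with identical chain lengths, two
rows (ϕ, γ) per prior.

## Prediction of future records

Given the last of n records z and a horizon m > n (k = m − n), the
conditional density of X_u(m) is the Gamma(k, 1) hazard-increment law pushed
through H:

    g(y | z) = [H(y) − H(z)]^(k−1) / Γ(k) · f(y) / S(z),   y > z.

* **Bayesian**: for each retained posterior draw, future records are
  simulated as H^{-1}(H(z) + Gamma(k, 1)); the pooled draws are draws from
  the posterior predictive density, from which the predictive mean, median
  and equal-tailed interval are read off. The predictive mean is reported as
  the point predictor with the median alongside; for heavy-tailed horizons
  the median is the more stable of the two.
* **Classical**: the predictive likelihood — the record likelihood times the
  future-record factor — is maximized jointly over (ϕ, γ, y) in
  (ln ϕ, ln γ, η) with y = z(1 + e^η), by a Nelder–Mead sweep polished with
  BFGS. For m = n + 1 the y-profile is the left-truncated parent density,
  which is decreasing whenever z exceeds the parent mode; the maximizer then
  sits at the boundary y → z and the fit returns y ≈ z. This is a property
  of the predictive-likelihood construction itself, not of the optimizer,
  and is covered by a dedicated test.

## Goodness of fit

The goodness-of-fit module addresses raw i.i.d. measurements (the
application data), not record samples, so ordinary likelihoods are used.
Families and parameterizations: gamma, Weibull, inverse Weibull and
log-logistic in their location-zero shape/scale forms (numerical MLE via
scipy); log-normal by the closed-form log-moment MLE; inverse-exponential —
the inverse Weibull with shape fixed at 1, CDF exp(−ϕ/x) — by its
closed-form MLE ϕ = n / Σ(1/x), with one parameter counted in the penalty.
The EDF statistics are computed from the sorted probability-integral
transform u_(i): KS = max_i max(i/n − u_(i), u_(i) − (i−1)/n),
CvM = 1/(12n) + Σ (u_(i) − (2i−1)/(2n))², and
AD = −n − (1/n) Σ (2i−1)[ln u_(i) + ln(1 − u_(n+1−i))]. Statistic values are
reported, not p-values: with estimated parameters the textbook critical
values are invalid, and bootstrap calibration is out of scope. PIT values of
exactly 0 or 1 (possible through floating-point underflow of a fitted CDF)
are clipped to machine bounds with a warning. Ranking is by AIC with ties
broken by BIC then name; families that fail to fit are flagged and excluded
from the ranking rather than silently dropped.

## Synthetic degradation fixture

`generate_degradation_fixture` emulates an accelerated-stability experiment:
a positive degradation index measured on 100 samples at each of 70, 85 and
100 °C with exposure times on a 10–120 minute grid, the index drawn from a
per-temperature Inverse Weibull. Default parameters (ϕ, γ) = (8, 3), (27, 3)
and (64, 3) put the per-temperature scales at 2, 3 and 4, so the index
distribution shifts right as thermal stress increases while keeping a heavy
upper tail; they are illustrative, chosen for a realistic-looking fixture
rather than calibrated to any laboratory dataset (none is available). What
the fixture does *not* emulate: within-sample kinetics over time (the time
column is a design label, not a covariate of the index distribution),
measurement error structure, or temperature-dependence laws such as
Arrhenius kinetics. Tests passing on this fixture therefore validate the
estimators and the analysis pipeline, not any chemical model of degradation.

## Simulation-study drivers and reproducibility

`run_mle_simulation` simulates `reps` record samples per sample size at the
true parameters (quantile construction), fits each and reports the
Monte-Carlo mean of each estimate with its standard error sd/√reps;
non-converged fits are excluded and their rate reported, never imputed.
`run_bayes_simulation` averages the per-replicate posterior summary columns
over replicate datasets (the averaging convention is column-wise over
replicates). Default replication counts are 2000 (MLE study) and 200 (Bayes
study) with 20000-iteration chains — sizes chosen so the Monte-Carlo error
of every reported average is well below the differences of interest while a
full study completes in minutes on one CPU. Every stochastic function takes
a seed or Generator; identical seeds give identical output, and the study
drivers derive per-replicate seeds from a single root seed.

## Numerical choices

* All tail quantities go through expm1/log1p compositions; the inverse
  cumulative hazard switches to its asymptotic log form once exp(−h)
  underflows.
* Domain violations (nonpositive x, u outside (0,1), nonpositive
  hyperparameters) raise `ValueError` rather than clamp, so misuse inside
  samplers surfaces immediately. The one exception is the log prior, which
  returns −inf outside the positive quadrant so that MH proposals are
  rejected rather than crash the chain.
* Record extraction treats ties strictly: a repeat of the running maximum is
  not a record.
* The batch-means MC error uses ⌈√K⌉ batches and is capped at the chain's
  standard deviation (the bound is attained only by degenerate chains).

## Known limitations

* ϕ is weakly identified by record data (see above); report medians and
  intervals for ϕ, not bare point estimates, at small n.
* Wald intervals for ϕ can include negative values; the Bayesian intervals
  respect positivity by construction.
* The classical predictive fit for m = n + 1 is usually a boundary solution
  at the last observed record.
* Credible intervals built under a prior centered at the truth over-cover
  slightly in simulation calibrations (≈0.99 observed coverage for a 95%
  interval for ϕ at n = 50 with Gamma(3, 3) priors) — expected behavior for
  an informative, well-specified prior, not a defect of the sampler.
* No censoring, truncation, lower records or k-records; a single canonical
  parameterization is used throughout.
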