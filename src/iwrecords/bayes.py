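"""Gamma-prior Bayesian inference for Inverse Weibull record samples.

Independent gamma priors phi ~ Gamma(e, f) and gamma ~ Gamma(g, h) (shape,
rate) are combined with the record likelihood; the normalizing constant of
the posterior is never evaluated — a Metropolis-Hastings chain works with the
unnormalized log posterior.  The proposal is an independent-per-coordinate
gamma kernel centered (in mean) at the current value; because that kernel is
asymmetric, the Hastings correction is computed exactly rather than assumed
to be one.

Posterior summaries follow the conventional MCMC report: posterior mean,
posterior standard deviation, batch-means Monte Carlo error, and the 2.5%,
50% and 97.5% empirical quantiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .distribution import IWDParams
from .records import RecordSample

__all__ = [
    "GammaPrior",
    "MHConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "prior_moments",
    "log_prior",
    "log_posterior",
    "mh_sample",
    "summarize_chain",
    "posterior_summary",
    "credible_interval",
    "sensitivity_table",
    "RecordPosteriorResults",
]


class GammaPrior(NamedTuple):
    """Hyperparameters (e, f) for phi and (g, h) for gamma; shape/rate."""

    e: float
    f: float
    g: float
    h: float

    def validated(self) -> "GammaPrior":
        if any(not (math.isfinite(v) and v > 0) for v in self):
            raise ValueError("all four gamma hyperparameters must be positive and finite")
        return GammaPrior(*map(float, self))


def prior_moments(prior: GammaPrior) -> tuple[float, float, float, float]:
    """(mean_phi, var_phi, mean_gamma, var_gamma) of the gamma priors."""
    e, f, g, h = prior.validated() if isinstance(prior, GammaPrior) else GammaPrior(*prior).validated()
    return (e / f, e / f**2, g / h, g / h**2)


def log_prior(p: IWDParams, prior: GammaPrior) -> float:
    """Unnormalized log prior density; -inf outside the positive quadrant."""
    e, f, g, h = GammaPrior(*prior).validated()
    phi, gamma = p
    if not (phi > 0 and gamma > 0) or not (math.isfinite(phi) and math.isfinite(gamma)):
        return -math.inf
    return (e - 1.0) * math.log(phi) - f * phi + (g - 1.0) * math.log(gamma) - h * gamma


def log_posterior(r: RecordSample, p: IWDParams, prior: GammaPrior) -> float:
    """Unnormalized log posterior = log prior + record log likelihood.

    An empty record sample contributes no likelihood, so the posterior is the
    prior — useful for sampler validation.
    """
    lp = log_prior(p, prior)
    if not math.isfinite(lp) or r.n == 0:
        return lp
    from .model import log_likelihood

    return lp + log_likelihood(r, p)


@dataclass(frozen=True)
class MHConfig:
    """Metropolis-Hastings run configuration.

    ``proposal_scale`` is the per-coordinate coefficient of variation of the
    gamma proposal kernel; during burn-in it is auto-scaled toward an
    acceptance rate in (0.2, 0.5) and then frozen.
    """

    iterations: int = 20_000
    burn_in: int | None = None  # default: 20% of iterations
    proposal_scale: tuple[float, float] = (0.5, 0.5)
    seed: int = 0
    thin: int = 1
    adapt: bool = True

    def resolved_burn_in(self) -> int:
        b = self.burn_in if self.burn_in is not None else int(0.2 * self.iterations)
        if not 0 <= b < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        return b


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained MH draws (columns phi, gamma) and chain diagnostics."""

    pairs: np.ndarray
    acceptance_rate: float
    config: MHConfig

    def __post_init__(self):
        pairs = np.atleast_2d(np.asarray(self.pairs, dtype=float))
        object.__setattr__(self, "pairs", pairs)
        if pairs.shape[1] != 2:
            raise ValueError("pairs must have two columns (phi, gamma)")
        if np.any(pairs <= 0):
            raise ValueError("posterior draws must be strictly positive")

    @property
    def phi(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def gamma(self) -> np.ndarray:
        return self.pairs[:, 1]

    def __len__(self) -> int:
        return self.pairs.shape[0]


class PosteriorSummary(NamedTuple):
    estimate: float  # posterior mean
    se: float  # posterior standard deviation
    mc_error: float  # batch-means Monte Carlo standard error
    q025: float
    median: float
    q975: float


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return shape * math.log(rate) - math.lgamma(shape) + (shape - 1.0) * math.log(x) - rate * x


def _make_log_posterior(r: RecordSample, prior: GammaPrior):
    """Fast closure over the data for use inside the MH loop."""
    e, f, g, h = GammaPrior(*prior).validated()
    if r.n == 0:
        def lp_empty(phi: float, gamma: float) -> float:
            return (e - 1.0) * math.log(phi) - f * phi + (g - 1.0) * math.log(gamma) - h * gamma

        return lp_empty

    lx = np.log(r.values)
    sum_lx = float(lx.sum())
    n = r.n

    def lp(phi: float, gamma: float) -> float:
        with np.errstate(over="ignore", under="ignore"):
            w = np.exp(-gamma * lx)
            sw = float(w.sum())
            if not math.isfinite(sw):
                return -math.inf
            tail = -float(np.sum(np.log(-np.expm1(-phi * w[:-1])))) if n > 1 else 0.0
        if not math.isfinite(tail):
            return -math.inf
        ll = n * math.log(phi) + n * math.log(gamma) - (gamma + 1.0) * sum_lx - phi * sw + tail
        prior_term = (e - 1.0) * math.log(phi) - f * phi + (g - 1.0) * math.log(gamma) - h * gamma
        return ll + prior_term

    return lp


def mh_sample(r: RecordSample, prior: GammaPrior, cfg: MHConfig = MHConfig()) -> PosteriorDraws:
    """Sample the (phi, gamma) posterior by Metropolis-Hastings.

    The chain proposes both coordinates jointly from gamma kernels with mean
    at the current state, accepts with probability min(w1 * w2, 1) where w1
    is the posterior ratio and w2 the exact Hastings correction, discards the
    burn-in, and thins.  A chain whose post-burn-in acceptance is exactly 0
    or 1 is reported as a failure rather than summarized.
    """
    prior = GammaPrior(*prior).validated()
    if cfg.iterations < 100:
        raise ValueError("iterations must be at least 100")
    if cfg.thin < 1:
        raise ValueError("thin must be >= 1")
    burn = cfg.resolved_burn_in()
    rng = np.random.default_rng(cfg.seed)
    lp_fn = _make_log_posterior(r, prior)

    # start at the MLE when the data allow it, otherwise at the prior means
    phi, gamma = prior.e / prior.f, prior.g / prior.h
    if r.n >= 2:
        try:
            from .model import InverseWeibullRecords

            fit = InverseWeibullRecords(r).fit(n_restarts=2)
            if fit.converged:
                phi, gamma = fit.params
        except Exception:
            pass

    cv = list(cfg.proposal_scale)
    if any(c <= 0 for c in cv):
        raise ValueError("proposal_scale entries must be positive")
    lp = lp_fn(phi, gamma)
    kept = []
    accepted_post = 0
    total_post = 0
    window_acc = 0
    for it in range(cfg.iterations):
        a1 = 1.0 / cv[0] ** 2
        a2 = 1.0 / cv[1] ** 2
        phi_new = rng.gamma(a1, phi / a1)
        gamma_new = rng.gamma(a2, gamma / a2)
        accept = False
        if phi_new > 0 and gamma_new > 0:
            lp_new = lp_fn(phi_new, gamma_new)
            if math.isfinite(lp_new):
                log_w1 = lp_new - lp
                log_w2 = (
                    _gamma_logpdf(phi, a1, a1 / phi_new)
                    + _gamma_logpdf(gamma, a2, a2 / gamma_new)
                    - _gamma_logpdf(phi_new, a1, a1 / phi)
                    - _gamma_logpdf(gamma_new, a2, a2 / gamma)
                )
                log_w = log_w1 + log_w2
                if log_w >= 0 or math.log(rng.uniform()) < log_w:
                    accept = True
        if accept:
            phi, gamma, lp = phi_new, gamma_new, lp_new
            window_acc += 1
        if it < burn:
            if cfg.adapt and (it + 1) % 100 == 0:
                rate = window_acc / 100.0
                if rate < 0.2:
                    cv[0] *= 0.7
                    cv[1] *= 0.7
                elif rate > 0.5:
                    cv[0] /= 0.7
                    cv[1] /= 0.7
                cv[0] = min(max(cv[0], 1e-3), 10.0)
                cv[1] = min(max(cv[1], 1e-3), 10.0)
                window_acc = 0
        else:
            total_post += 1
            if accept:
                accepted_post += 1
            if (it - burn) % cfg.thin == 0:
                kept.append((phi, gamma))

    rate = accepted_post / total_post if total_post else 0.0
    if rate <= 0.0 or rate >= 1.0:
        raise RuntimeError(
            f"degenerate Metropolis-Hastings chain (post-burn-in acceptance {rate:.3f})"
        )
    return PosteriorDraws(np.asarray(kept), rate, cfg)


def summarize_chain(values: Sequence[float]) -> PosteriorSummary:
    """Posterior summary of a single scalar chain (mean, sd, MC error, quantiles).

    The Monte Carlo error uses batch means with ceil(sqrt(K)) batches, which
    is assumption-light and bounded above by the chain's spread.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("empty chain")
    est = float(v.mean())
    se = float(v.std(ddof=1)) if v.size > 1 else 0.0
    nb = max(int(math.ceil(math.sqrt(v.size))), 2)
    bs = v.size // nb
    if bs >= 1:
        batches = v[: nb * bs].reshape(nb, bs).mean(axis=1)
        mc = float(batches.std(ddof=1) / math.sqrt(nb)) if nb > 1 else 0.0
    else:
        mc = se
    q025, med, q975 = np.quantile(v, [0.025, 0.5, 0.975])
    return PosteriorSummary(est, se, min(mc, se), float(q025), float(med), float(q975))


def posterior_summary(d: PosteriorDraws) -> dict[str, PosteriorSummary]:
    """Table-style summary (Estimate, SE, MC Error, quantiles) per parameter."""
    if len(d) < 100:
        raise ValueError("posterior_summary requires at least 100 retained draws")
    return {"phi": summarize_chain(d.phi), "gamma": summarize_chain(d.gamma)}


def credible_interval(d: PosteriorDraws, level: float = 0.95) -> np.ndarray:
    """Equal-tailed credible intervals, rows (phi, gamma), columns (lower, upper)."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if len(d) < 100:
        raise ValueError("credible_interval requires at least 100 retained draws")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(d.pairs, [alpha, 1.0 - alpha], axis=0)
    return np.column_stack([lo, hi])


def sensitivity_table(
    r: RecordSample, priors: Sequence[GammaPrior], cfg: MHConfig = MHConfig()
) -> pd.DataFrame:
    """Posterior summaries under each prior, same data and chain length.

    Returns two rows per prior (one for phi, one for gamma) with the
    hyperparameter pair in the row label, mirroring the usual
    hyperparameter-sensitivity report.
    """
    priors = list(priors)
    if not priors:
        raise ValueError("at least one prior is required")
    rows = []
    for j, prior in enumerate(priors):
        prior = GammaPrior(*prior).validated()
        draws = mh_sample(r, prior, replace(cfg, seed=cfg.seed + j))
        summ = posterior_summary(draws)
        for name, hyper in (("phi", (prior.e, prior.f)), ("gamma", (prior.g, prior.h))):
            s = summ[name]
            rows.append(
                {
                    "parameter": name,
                    "prior": f"({hyper[0]:g},{hyper[1]:g})",
                    "mean": s.estimate,
                    "se": s.se,
                    "mc_error": s.mc_error,
                    "q2.5": s.q025,
                    "median": s.median,
                    "q97.5": s.q975,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RecordPosteriorResults:
    """Posterior fit of a record model: draws plus reporting conveniences."""

    model: "object"
    prior: GammaPrior
    draws: PosteriorDraws

    @property
    def params(self) -> IWDParams:
        """Posterior means (squared-error Bayes estimates)."""
        return IWDParams(float(self.draws.phi.mean()), float(self.draws.gamma.mean()))

    def summary(self) -> pd.DataFrame:
        summ = posterior_summary(self.draws)
        return pd.DataFrame(
            [summ["phi"], summ["gamma"]],
            index=["phi", "gamma"],
            columns=["estimate", "se", "mc_error", "2.5%", "median", "97.5%"],
        )

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        return credible_interval(self.draws, level)

    def predict_record(self, m: int, level: float = 0.95, seed=None, draws_per_posterior: int = 1):
        """Bayesian predictive summary of the m-th future record."""
        from .prediction import bayesian_predict

        return bayesian_predict(
            self.model.records, self.draws, m, level=level, seed=seed,
            draws_per_posterior=draws_per_posterior,
        )

    def plot_trace(self, axes=None):
        """Trace and marginal-density plots for both parameters."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(2, 2, figsize=(9, 5))
        for i, (name, chain) in enumerate((("phi", self.draws.phi), ("gamma", self.draws.gamma))):
            axes[i, 0].plot(chain, lw=0.4)
            axes[i, 0].set_ylabel(name)
            axes[i, 1].hist(chain, bins=50, density=True)
        axes[0, 0].set_title("trace")
        axes[0, 1].set_title("posterior density")
        return axes
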