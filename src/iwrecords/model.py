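"""Likelihood inference for Inverse Weibull upper-record samples.

For a record sample x_{u(1)} < ... < x_{u(n)} the likelihood is the density
of the last record times the hazard contributions of its predecessors,

    L(phi, gamma) = f(x_{u(n)}) * prod_{i<n} f(x_{u(i)}) / (1 - F(x_{u(i)})),

whose log is

    l = n ln phi + n ln gamma - (gamma+1) sum ln x_i - phi sum x_i^(-gamma)
        - sum_{i<n} ln(1 - exp(-phi x_i^(-gamma))).

``InverseWeibullRecords`` is the model object; ``fit`` maximizes l by
quasi-Newton iteration in (ln phi, ln gamma) with an exact-Newton polish and
jittered restarts, and returns a ``RecordMLEResults`` carrying the estimates,
the inverse observed information, Wald intervals and a summary table.
Analytic score and Hessian are exact derivatives of l (the test suite checks
them against finite differences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .distribution import IWDParams
from .records import RecordSample, extract_upper_records

__all__ = [
    "InverseWeibullRecords",
    "RecordMLEResults",
    "log_likelihood",
    "score",
    "observed_information",
    "fit_mle",
    "wald_interval",
]


def _terms(r: RecordSample, p: IWDParams):
    """Shared record-correction pieces, in underflow-safe compositions.

    With w_i = x_i^(-gamma), u_i = phi * w_i, s_i = 1 - exp(-u_i) and
    rho_i = exp(-u_i), the score and Hessian only need the combinations
    ratio = w/s (limit 1/phi as u -> 0) and g2 = (u - s)/s (limit 0), which
    stay finite even when w underflows to zero.
    """
    p = IWDParams(*p).validated()
    x = r.values
    lx = np.log(x)
    with np.errstate(over="ignore", under="ignore"):
        w = np.exp(-p.gamma * lx)
        u = p.phi * w
        s = -np.expm1(-u)
        rho = np.exp(-u)
        ratio = np.where(s > 0, np.divide(w, s, out=np.full_like(w, 1.0 / p.phi), where=s > 0),
                         1.0 / p.phi)
        g2 = np.where(s > 0, np.divide(u, s, out=np.ones_like(u), where=s > 0) - 1.0, 0.0)
    return p, lx, w, u, s, rho, ratio, g2


def log_likelihood(r: RecordSample, p: IWDParams) -> float:
    """Record-sample log likelihood at parameters p."""
    if r.n < 1:
        raise ValueError("log_likelihood requires at least one record")
    p, lx, w, u, s, rho, ratio, g2 = _terms(r, p)
    n = r.n
    head = n * math.log(p.phi) + n * math.log(p.gamma)
    core = -(p.gamma + 1.0) * lx.sum() - p.phi * w.sum()
    if n > 1:
        uh, sh = u[:-1], s[:-1]
        # log s; once u underflows, s = u to machine precision and
        # log u = log phi - gamma log x stays finite
        log_u = math.log(p.phi) - p.gamma * lx[:-1]
        with np.errstate(divide="ignore"):
            log_s = np.where(uh > 1e-15, np.log(np.maximum(sh, 1e-300)), log_u)
        tail = -float(np.sum(log_s))
    else:
        tail = 0.0
    return float(head + core + tail)


def score(r: RecordSample, p: IWDParams) -> np.ndarray:
    """Gradient (d l/d phi, d l/d gamma) of the record log likelihood."""
    if r.n < 1:
        raise ValueError("score requires at least one record")
    p, lx, w, u, s, rho, ratio, g2 = _terms(r, p)
    n = r.n
    lh = lx[:-1]
    corr = (ratio * rho)[:-1]  # = w exp(-u) / (1 - exp(-u)), record correction
    s_phi = n / p.phi - w.sum() - np.sum(corr)
    s_gamma = n / p.gamma - lx.sum() + p.phi * np.sum(w * lx) + p.phi * np.sum(lh * corr)
    return np.array([s_phi, s_gamma])


def observed_information(r: RecordSample, p: IWDParams) -> np.ndarray:
    """Negated Hessian of the record log likelihood at p (symmetric 2x2)."""
    if r.n < 1:
        raise ValueError("observed_information requires at least one record")
    p, lx, w, u, s, rho, ratio, g2 = _terms(r, p)
    n = r.n
    lh = lx[:-1]
    # w^2 rho / s^2 = (w/s)^2 rho ; w rho (u - s)/s^2 = ratio * rho * g2
    quad = (ratio**2 * rho)[:-1]
    cross = (ratio * rho * g2)[:-1]
    l_pp = -n / p.phi**2 + np.sum(quad)
    l_pg = np.sum(w * lx) - np.sum(lh * cross)
    l_gg = -n / p.gamma**2 - p.phi * np.sum(w * lx**2) + p.phi * np.sum(lh**2 * cross)
    return -np.array([[l_pp, l_pg], [l_pg, l_gg]])


@dataclass
class RecordMLEResults:
    """Maximum-likelihood fit of (phi, gamma) to a record sample."""

    model: "InverseWeibullRecords"
    params: IWDParams
    vcov: np.ndarray
    converged: bool
    score_norm: float
    n_iter: int
    llf: float

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    @property
    def se(self) -> np.ndarray:  # alias
        return self.bse

    def cov_params(self) -> np.ndarray:
        return self.vcov

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        return wald_interval(self, level)

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int(0.95)
        return pd.DataFrame(
            {
                "estimate": [self.params.phi, self.params.gamma],
                "std err": self.bse,
                "ci 2.5%": ci[:, 0],
                "ci 97.5%": ci[:, 1],
            },
            index=["phi", "gamma"],
        )

    def predict_record(self, m: int, **kwargs):
        """Classical predictive-likelihood prediction of the m-th record."""
        from .prediction import classical_predictive_fit

        return classical_predictive_fit(self.model.records, m, init=self.params, **kwargs)


def wald_interval(fit: RecordMLEResults, level: float = 0.95) -> np.ndarray:
    """Symmetric large-sample intervals estimate +/- z_{alpha/2} * se."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    est = np.array(fit.params)
    se = fit.bse
    return np.column_stack([est - z * se, est + z * se])


class InverseWeibullRecords:
    """Model for an upper-record sample assumed to come from an Inverse Weibull parent."""

    def __init__(self, records: RecordSample):
        if not isinstance(records, RecordSample):
            records = RecordSample(np.asarray(records, dtype=float))
        self.records = records

    @classmethod
    def from_sequence(cls, sequence) -> "InverseWeibullRecords":
        """Build the model from a raw series by extracting its upper records."""
        return cls(extract_upper_records(sequence))

    # -- likelihood surface -------------------------------------------------
    def loglike(self, params: IWDParams) -> float:
        return log_likelihood(self.records, params)

    def score(self, params: IWDParams) -> np.ndarray:
        return score(self.records, params)

    def observed_information(self, params: IWDParams) -> np.ndarray:
        return observed_information(self.records, params)

    # -- estimation ---------------------------------------------------------
    def _default_start(self) -> np.ndarray:
        # moment-flavored start: gamma = 1 and the phi score root at gamma = 1
        # ignoring the record-correction sum
        x = self.records.values
        phi0 = self.records.n / np.sum(1.0 / x)
        return np.array([max(phi0, 1e-6), 1.0])

    def fit(
        self,
        start: IWDParams | None = None,
        tol: float = 1e-8,
        max_iter: int = 200,
        n_restarts: int = 5,
        seed: int = 0,
    ) -> RecordMLEResults:
        """Maximize the record likelihood; n >= 2 required.

        At n = 1 the likelihood is unbounded in gamma, so a single record is
        refused outright rather than returning a spurious optimum.
        """
        r = self.records
        if r.n < 2:
            raise ValueError("MLE from records requires n >= 2 (n = 1 is divergent)")

        def neg_ll_log(theta):
            p = IWDParams(math.exp(theta[0]), math.exp(theta[1]))
            return -log_likelihood(r, p)

        def neg_grad_log(theta):
            p = IWDParams(math.exp(theta[0]), math.exp(theta[1]))
            return -score(r, p) * np.array(p)

        start_nat = np.array(start if start is not None else self._default_start(), float)
        rng = np.random.default_rng(seed)
        best = None
        theta0 = np.log(start_nat)
        for attempt in range(n_restarts + 1):
            t0 = theta0 if attempt == 0 else theta0 + rng.normal(scale=0.5, size=2)
            try:
                # direct damped Newton from the start is usually enough; the
                # quasi-Newton sweep is the safety net for bad starts
                theta = self._newton_polish(t0, tol, max_iter)
                p_try = IWDParams(math.exp(theta[0]), math.exp(theta[1]))
                if np.linalg.norm(score(r, p_try)) >= tol:
                    res = optimize.minimize(
                        neg_ll_log, t0, jac=neg_grad_log, method="BFGS",
                        options={"maxiter": max_iter, "gtol": 1e-10},
                    )
                    theta = self._newton_polish(res.x, tol, max_iter)
            except (FloatingPointError, OverflowError, ValueError):
                continue
            p = IWDParams(math.exp(theta[0]), math.exp(theta[1]))
            sn = float(np.linalg.norm(score(r, p)))
            cand = (sn, theta, attempt)
            if best is None or sn < best[0]:
                best = cand
            if sn < tol:
                break

        if best is None:
            raise RuntimeError("record MLE failed to evaluate from every start")
        sn, theta, n_used = best
        p = IWDParams(math.exp(theta[0]), math.exp(theta[1]))
        info = observed_information(r, p)
        eigvals = np.linalg.eigvalsh(info)
        pd_ok = bool(np.all(eigvals > 0))
        converged = bool(sn < tol and pd_ok)
        vcov = np.linalg.inv(info) if pd_ok else np.full((2, 2), np.nan)
        return RecordMLEResults(
            model=self,
            params=p,
            vcov=vcov,
            converged=converged,
            score_norm=sn,
            n_iter=n_used,
            llf=log_likelihood(r, p),
        )

    def _newton_polish(self, theta: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
        """Damped Newton steps on the score, in log-parameter space."""
        r = self.records
        theta = theta.copy()
        for _ in range(max_iter):
            p = IWDParams(math.exp(theta[0]), math.exp(theta[1]))
            g_nat = score(r, p)
            if np.linalg.norm(g_nat) < tol:
                break
            nat = np.array(p)
            g_log = g_nat * nat  # chain rule to log space
            hess_nat = -observed_information(r, p)
            # Hessian in log space: D H D + diag(params * score)
            h_log = nat[:, None] * hess_nat * nat[None, :] + np.diag(nat * g_nat)
            try:
                step = np.linalg.solve(h_log, -g_log)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)):
                break
            ll_old = log_likelihood(r, p)
            scale = 1.0
            for _bt in range(40):
                trial = theta + scale * step
                if np.all(np.abs(trial) < 50):
                    pt = IWDParams(math.exp(trial[0]), math.exp(trial[1]))
                    if log_likelihood(r, pt) >= ll_old:
                        theta = trial
                        break
                scale *= 0.5
            else:
                break
        return theta

    def fit_bayes(self, prior=None, config=None):
        """Gamma-prior Metropolis-Hastings posterior fit; see ``iwrecords.bayes``."""
        from .bayes import GammaPrior, MHConfig, RecordPosteriorResults, mh_sample

        prior = prior if prior is not None else GammaPrior(1.0, 1.0, 1.0, 1.0)
        config = config if config is not None else MHConfig()
        draws = mh_sample(self.records, prior, config)
        return RecordPosteriorResults(model=self, prior=prior, draws=draws)


def fit_mle(r: RecordSample, **opts) -> RecordMLEResults:
    """Convenience wrapper: fit the record MLE directly from a sample."""
    return InverseWeibullRecords(r).fit(**opts)
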