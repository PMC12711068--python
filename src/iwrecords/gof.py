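"""Goodness-of-fit comparison of candidate distributions for positive data.

Fits each candidate family to an i.i.d. positive sample by maximum
likelihood (ordinary likelihood — this is the raw-measurement analysis, not
the record likelihood) and ranks the families by AIC, with BIC and the three
EDF statistics (Kolmogorov-Smirnov, Anderson-Darling, Cramér-von Mises)
reported alongside.  Statistic values are reported rather than p-values:
with estimated parameters the textbook critical values do not apply.

Parameterizations: gamma, Weibull, inverse Weibull and log-logistic are the
scipy location-zero forms (shape c, scale s); log-normal uses the closed-form
log-moment MLE; inverse-exponential is the inverse Weibull with shape fixed
at 1, CDF exp(-phi/x), whose single parameter has the closed-form MLE
phi = n / sum(1/x).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FAMILIES",
    "CandidateFit",
    "GofRow",
    "fit_candidate",
    "information_criteria",
    "edf_statistics",
    "rank_models",
]

FAMILIES = (
    "gamma",
    "weibull",
    "inverse-weibull",
    "log-normal",
    "inverse-exponential",
    "log-logistic",
)


@dataclass
class CandidateFit:
    family: str
    params: dict
    loglik: float
    k: int
    dist: object  # frozen scipy distribution
    converged: bool = True

    def cdf(self, x):
        return self.dist.cdf(x)


@dataclass
class GofRow:
    family: str
    aic: float
    bic: float
    ks: float
    ad: float
    cvm: float
    converged: bool = True


def _check_sample(data) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 1 or arr.size < 5:
        raise ValueError("sample must be one-dimensional with at least 5 values")
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError("sample values must be positive and finite")
    return arr


def fit_candidate(data, family: str) -> CandidateFit:
    """Maximum-likelihood fit of one candidate family to an i.i.d. sample."""
    x = _check_sample(data)
    n = x.size
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "gamma":
            a, _, s = stats.gamma.fit(x, floc=0)
            dist, params, k = stats.gamma(a, scale=s), {"shape": a, "scale": s}, 2
        elif family == "weibull":
            c, _, s = stats.weibull_min.fit(x, floc=0)
            dist, params, k = stats.weibull_min(c, scale=s), {"shape": c, "scale": s}, 2
        elif family == "inverse-weibull":
            c, _, s = stats.invweibull.fit(x, floc=0)
            dist, params, k = stats.invweibull(c, scale=s), {"shape": c, "scale": s}, 2
        elif family == "log-normal":
            mu = float(np.mean(np.log(x)))
            sigma = float(np.std(np.log(x)))  # MLE uses the 1/n variance
            dist, params, k = stats.lognorm(sigma, scale=math.exp(mu)), {"mu": mu, "sigma": sigma}, 2
        elif family == "inverse-exponential":
            phi = n / float(np.sum(1.0 / x))
            dist, params, k = stats.invweibull(1.0, scale=phi), {"phi": phi}, 1
        elif family == "log-logistic":
            c, _, s = stats.fisk.fit(x, floc=0)
            dist, params, k = stats.fisk(c, scale=s), {"shape": c, "scale": s}, 2
        else:
            raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    loglik = float(np.sum(dist.logpdf(x)))
    converged = math.isfinite(loglik) and all(math.isfinite(v) and v > 0 or key == "mu"
                                              for key, v in params.items())
    return CandidateFit(family, params, loglik, k, dist, bool(converged))


def information_criteria(fit: CandidateFit, n: int) -> tuple[float, float]:
    """AIC = 2k - 2 loglik; BIC = k ln n - 2 loglik."""
    if n < 2:
        raise ValueError("n must be at least 2")
    aic = 2.0 * fit.k - 2.0 * fit.loglik
    bic = fit.k * math.log(n) - 2.0 * fit.loglik
    return (aic, bic)


def edf_statistics(data, fitted_cdf) -> tuple[float, float, float]:
    """(KS, AD, CvM) statistics of the probability-integral-transformed sample.

    With u_(i) the sorted fitted CDF values:
      KS  = max_i max(i/n - u_(i), u_(i) - (i-1)/n)
      AD  = -n - (1/n) sum (2i-1) [ln u_(i) + ln(1 - u_(n+1-i))]
      CvM = 1/(12n) + sum (u_(i) - (2i-1)/(2n))^2
    """
    x = np.sort(np.asarray(data, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    u = np.asarray(fitted_cdf(x), dtype=float)
    eps = np.finfo(float).tiny
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        warnings.warn("fitted CDF values of exactly 0 or 1 were clipped", RuntimeWarning)
        u = np.clip(u, eps, 1.0 - np.finfo(float).epsneg)
    i = np.arange(1, n + 1)
    ks = float(np.max(np.maximum(i / n - u, u - (i - 1) / n)))
    ad = float(-n - np.sum((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))) / n)
    cvm = float(1.0 / (12 * n) + np.sum((u - (2 * i - 1) / (2 * n)) ** 2))
    return (ks, ad, cvm)


def rank_models(data, families=None) -> pd.DataFrame:
    """Fit each family and rank by AIC (ties: BIC, then name).

    Families that fail to fit are kept in the table with a failure flag and
    sorted to the bottom; the frame's ``attrs["best"]`` records the winning
    family for each criterion among the successful fits.
    """
    x = _check_sample(data)
    families = list(families) if families is not None else list(FAMILIES)
    rows = []
    for family in families:
        try:
            fit = fit_candidate(x, family)
            if not fit.converged:
                raise RuntimeError("non-finite fit")
            aic, bic = information_criteria(fit, x.size)
            ks, ad, cvm = edf_statistics(x, fit.cdf)
            rows.append(GofRow(family, aic, bic, ks, ad, cvm, True))
        except Exception:
            rows.append(GofRow(family, np.nan, np.nan, np.nan, np.nan, np.nan, False))
    frame = pd.DataFrame([r.__dict__ for r in rows])
    frame = frame.sort_values(
        ["converged", "aic", "bic", "family"], ascending=[False, True, True, True]
    ).reset_index(drop=True)
    ok = frame[frame["converged"]]
    if len(ok):
        frame.attrs["best"] = {
            col: ok.loc[ok[col].idxmin(), "family"] for col in ("aic", "bic", "ks", "ad", "cvm")
        }
    return frame
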