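"""Inverse Weibull (Fréchet-type) distribution in its canonical tail parameterization.

The distribution function used throughout the package is

    F(x) = exp(-phi * x**(-gamma)),    x > 0, phi > 0, gamma > 0,

with density f(x) = phi * gamma * x**(-(gamma+1)) * exp(-phi * x**(-gamma)).
``phi`` multiplies the power tail in the exponent and ``gamma`` is the shape
exponent; both are dimensionless.  The scale-shape convention
F(x) = exp(-(lam/x)**gamma) is related by lam = phi**(1/gamma), and
converters are provided for users of that form.

All tail quantities are computed through ``log1p``/``expm1`` compositions so
that survival probabilities, hazards and their inverses remain accurate deep
in the tails, where upper records of this heavy-tailed family live.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

__all__ = [
    "IWDParams",
    "pdf",
    "logpdf",
    "cdf",
    "logcdf",
    "sf",
    "logsf",
    "quantile",
    "isf",
    "cumulative_hazard",
    "inverse_cumulative_hazard",
    "to_scale_shape",
    "from_scale_shape",
]


class IWDParams(NamedTuple):
    """Parameter pair (phi, gamma) of the canonical Inverse Weibull CDF."""

    phi: float
    gamma: float

    def validated(self) -> "IWDParams":
        phi, gamma = float(self.phi), float(self.gamma)
        if not (math.isfinite(phi) and phi > 0):
            raise ValueError(f"phi must be positive and finite, got {self.phi!r}")
        if not (math.isfinite(gamma) and gamma > 0):
            raise ValueError(f"gamma must be positive and finite, got {self.gamma!r}")
        return IWDParams(phi, gamma)


def to_scale_shape(p: IWDParams) -> tuple[float, float]:
    """Return (scale lam, shape gamma) with F(x) = exp(-(lam/x)**gamma)."""
    p = IWDParams(*p).validated()
    return (p.phi ** (1.0 / p.gamma), p.gamma)


def from_scale_shape(scale: float, shape: float) -> IWDParams:
    """Build canonical (phi, gamma) from the scale-shape convention."""
    if scale <= 0 or shape <= 0:
        raise ValueError("scale and shape must be positive")
    return IWDParams(scale**shape, shape)


def _prepare(x, name: str = "x", *, strict_positive: bool = True):
    """Validate and coerce an argument array; return (array, was_scalar)."""
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    if strict_positive and np.any(arr <= 0):
        raise ValueError(f"{name} must be strictly positive")
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr, scalar


def _ret(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def _t(x: np.ndarray, p: IWDParams) -> np.ndarray:
    """The exponent t = phi * x**(-gamma), computed in log space."""
    return p.phi * np.exp(-p.gamma * np.log(x))


def logpdf(x, p: IWDParams):
    p = IWDParams(*p).validated()
    arr, scalar = _prepare(x)
    lx = np.log(arr)
    out = math.log(p.phi) + math.log(p.gamma) - (p.gamma + 1.0) * lx - p.phi * np.exp(-p.gamma * lx)
    return _ret(out, scalar)


def pdf(x, p: IWDParams):
    """Density f(x); underflows smoothly to 0 at both ends of the support."""
    p = IWDParams(*p).validated()
    arr, scalar = _prepare(x)
    return _ret(np.exp(logpdf(arr, p)), scalar)


def logcdf(x, p: IWDParams):
    p = IWDParams(*p).validated()
    arr, scalar = _prepare(x)
    return _ret(-_t(arr, p), scalar)


def cdf(x, p: IWDParams):
    """Distribution function F(x) = exp(-phi * x**(-gamma))."""
    p = IWDParams(*p).validated()
    arr, scalar = _prepare(x)
    return _ret(np.exp(-_t(arr, p)), scalar)


def sf(x, p: IWDParams):
    """Survival function 1 - F(x), computed as -expm1(-t) for accuracy."""
    p = IWDParams(*p).validated()
    arr, scalar = _prepare(x)
    return _ret(-np.expm1(-_t(arr, p)), scalar)


def logsf(x, p: IWDParams):
    p = IWDParams(*p).validated()
    arr, scalar = _prepare(x)
    return _ret(np.log(-np.expm1(-_t(arr, p))), scalar)


def quantile(u, p: IWDParams):
    """Quantile function F^{-1}(u) = (phi / (-ln u))**(1/gamma) for u in (0,1)."""
    p = IWDParams(*p).validated()
    arr, scalar = _prepare(u, "u", strict_positive=False)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("u must lie strictly inside (0, 1)")
    t = -np.log(arr)
    out = np.exp((math.log(p.phi) - np.log(t)) / p.gamma)
    return _ret(out, scalar)


def isf(q, p: IWDParams):
    """Inverse survival function: x with sf(x) = q, for q in (0,1).

    Computed as t = -log1p(-q) so that tiny survival probabilities (deep
    upper tail) do not lose precision through 1 - q.
    """
    p = IWDParams(*p).validated()
    arr, scalar = _prepare(q, "q", strict_positive=False)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("q must lie strictly inside (0, 1)")
    t = -np.log1p(-arr)
    out = np.exp((math.log(p.phi) - np.log(t)) / p.gamma)
    return _ret(out, scalar)


def cumulative_hazard(x, p: IWDParams):
    """H(x) = -ln(1 - F(x)); strictly increasing, H -> 0 as x -> 0+."""
    p = IWDParams(*p).validated()
    arr, scalar = _prepare(x)
    out = -np.log(-np.expm1(-_t(arr, p)))
    return _ret(out, scalar)


def inverse_cumulative_hazard(h, p: IWDParams):
    """Solve H(x) = h for x > 0, for h > 0.

    Uses t = -log(-expm1(-h)); once exp(-h) underflows the asymptotic
    log(t) = -h is exact to double precision, which keeps the inverse finite
    out to hazards of several hundred (records there are astronomically
    large, as heavy-tailed upper records legitimately are).
    """
    p = IWDParams(*p).validated()
    arr, scalar = _prepare(h, "h", strict_positive=False)
    if np.any(arr <= 0):
        raise ValueError("h must be strictly positive")
    eh = np.exp(-arr)
    with np.errstate(divide="ignore"):
        tau = -np.log1p(-eh)  # exponent phi * x**(-gamma) at the solution
        log_tau = np.where(tau > 0, np.log(tau), -arr)
    # tau == 0 means exp(-h) underflowed entirely; then log tau = -h exactly
    out = np.exp((math.log(p.phi) - log_tau) / p.gamma)
    return _ret(out, scalar)
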