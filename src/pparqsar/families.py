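"""Continuous dose-response model families for benchmark-dose estimation.

Eight sigmoidal families are supported, each written as

    m(x) = a * (1 + (c - 1) * F(x; b, d))

where ``a`` is the background response (fold-induction at dose 0, ~1 for a
reporter assay normalized to solvent control), ``c`` is the plateau expressed
as a fold-change over background (so the curve saturates at ``a * c``), and
``F`` is a CDF-like saturating function with F(0) = 0 and F(inf) = 1,
parameterized by a dose-scale ``b`` (µM) and a dimensionless shape ``d``.

For a ratio-type benchmark response ``bmr`` (median response at the BMD equals
``bmr * a``), the BMD solves F(BMD) = z with z = (bmr - 1)/(c - 1), which is
available in closed form for every family below.  When the plateau does not
reach the BMR (c <= bmr), the BMD does not exist and ``bmd`` returns +inf
(NOT_REACHED).

Families
--------
exponential            F = 1 - exp(-(x/b)^d)                  (Weibull-type)
inverse_exponential    F = exp(-(b/x)^d)                      (Fréchet-type)
hill                   F = x^d / (x^d + b^d)                  (log-logistic)
lognormal              F = Phi(d * ln(x/b))
gamma                  F = P(d, d*x/b)    regularized lower incomplete gamma
quadratic_exponential  F = 1 - exp(-(u + d*u^2)), u = x/b
probit                 F = (Phi(d*(x/b - 1)) - Phi(-d)) / (1 - Phi(-d))
logit                  as probit with the logistic CDF

The probit and logit families act on the raw dose axis, shifted and
renormalized so that F(0) = 0 exactly; a log-dose probit would coincide with
the lognormal family.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammainc, gammaincinv, logit as _logit, ndtr, ndtri

__all__ = ["FAMILY_NAMES", "median_response", "bmd_exact", "scale_for_bmd"]

FAMILY_NAMES = (
    "exponential",
    "inverse_exponential",
    "hill",
    "lognormal",
    "gamma",
    "quadratic_exponential",
    "probit",
    "logit",
)


def _F(family: str, x, b, d):
    """Saturating fraction F(x) in [0, 1]; vectorized over x (and b, d)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        if family == "exponential":
            return -np.expm1(-((x / b) ** d))
        if family == "inverse_exponential":
            out = np.where(x > 0, np.exp(-((b / np.where(x > 0, x, 1.0)) ** d)), 0.0)
            return out
        if family == "hill":
            xd = x**d
            return xd / (xd + b**d)
        if family == "lognormal":
            out = np.where(
                x > 0, ndtr(d * np.log(np.where(x > 0, x, 1.0) / b)), 0.0
            )
            return out
        if family == "gamma":
            return gammainc(d, d * x / b)
        if family == "quadratic_exponential":
            u = x / b
            return -np.expm1(-(u + d * u * u))
        if family == "probit":
            lo = ndtr(-d)
            return (ndtr(d * (x / b - 1.0)) - lo) / (1.0 - lo)
        if family == "logit":
            lo = expit(-d)
            return (expit(d * (x / b - 1.0)) - lo) / (1.0 - lo)
    raise ValueError(f"unknown dose-response family: {family!r}")


def median_response(family: str, x, a: float, c: float, b: float, d: float):
    """Median response m(x) = a * (1 + (c-1) * F(x))."""
    return a * (1.0 + (c - 1.0) * _F(family, x, b, d))


def _invF(family: str, z, b, d):
    """Dose at which F equals z (0 < z < 1).  Vectorized over z, b, d."""
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        if family == "exponential":
            return b * (-np.log1p(-z)) ** (1.0 / d)
        if family == "inverse_exponential":
            return b * (-np.log(z)) ** (-1.0 / d)
        if family == "hill":
            return b * (z / (1.0 - z)) ** (1.0 / d)
        if family == "lognormal":
            return b * np.exp(ndtri(z) / d)
        if family == "gamma":
            return b * gammaincinv(d, z) / d
        if family == "quadratic_exponential":
            ell = -np.log1p(-z)
            # stable root of d*u^2 + u - ell = 0 as d -> 0
            return b * 2.0 * ell / (1.0 + np.sqrt(1.0 + 4.0 * d * ell))
        if family == "probit":
            lo = ndtr(-d)
            w = lo + z * (1.0 - lo)
            return b * (1.0 + ndtri(w) / d)
        if family == "logit":
            lo = expit(-d)
            w = lo + z * (1.0 - lo)
            return b * (1.0 + _logit(w) / d)
    raise ValueError(f"unknown dose-response family: {family!r}")


def bmd_exact(family: str, c, b, d, bmr: float = 1.5):
    """Benchmark dose: smallest x with m(x) = bmr * m(0).

    The background ``a`` cancels for a ratio-type BMR.  Returns +inf where the
    plateau never reaches the BMR (c <= bmr) and 0 where bmr <= 1.
    Vectorized over c, b, d (posterior draws).
    """
    c = np.asarray(c, dtype=float)
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    if bmr <= 1.0:
        return np.zeros(np.broadcast(c, b, d).shape)
    z = np.where(c > 1.0, (bmr - 1.0) / np.where(c > 1.0, c - 1.0, 1.0), np.inf)
    reachable = z < 1.0
    zc = np.clip(z, 1e-300, 1.0 - 1e-16)
    out = np.where(reachable, _invF(family, zc, b, d), np.inf)
    if out.ndim == 0:
        return float(out)
    return out


def scale_for_bmd(family: str, true_bmd: float, c: float, d: float,
                  bmr: float = 1.5) -> float:
    """Dose-scale ``b`` such that the curve passes through its BMD exactly.

    Inverts ``bmd_exact`` for ``b``: since the BMD is proportional to ``b`` at
    fixed (c, d), b = true_bmd / bmd_exact(b=1).
    """
    if not true_bmd > 0:
        raise ValueError("true_bmd must be positive")
    if not c > bmr:
        raise ValueError(
            f"plateau fold-change c={c} never reaches bmr={bmr}; curve has no BMD"
        )
    unit = bmd_exact(family, c, 1.0, d, bmr=bmr)
    return true_bmd / float(unit)
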