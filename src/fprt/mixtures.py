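"""Binary mixtures of two base response-time distributions and their fixed point.

When every trial's response time is generated by one of two latent
strategies, the observed density is a binary mixture

    g(t) = p * f1(t) + (1 - p) * f2(t),

where ``p`` is the probability that strategy 1 was used.  If the two base
densities overlap, they are equal at some time ``t0`` (``f1(t0) = f2(t0)``),
and then ``g(t0) = f1(t0)`` for *every* mixture proportion: all members of
the mixture family pass through the common point ``(t0, f1(t0))``.  This is
the fixed-point property, and the quantity this package tests for.

The module provides the two base families used throughout (normal and
inverse-Gaussian, the standard unimodal RT models), the mixture container,
the analytic fixed point, the standardized separation d' of the two base
distributions, and seeded samplers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "BaseDistribution",
    "MixtureSpec",
    "NoOverlapError",
    "normal",
    "inverse_gaussian",
    "base_pdf",
    "mixture_pdf",
    "analytic_fixed_point",
    "dprime",
    "sample_invgauss",
    "sample_mixture",
]

_FAMILIES = ("normal", "inverse_gaussian")


class NoOverlapError(ValueError):
    """Raised when two densities have no crossing between their means."""


@dataclass(frozen=True)
class BaseDistribution:
    """One base (strategy) distribution.

    Parameters
    ----------
    family : {"normal", "inverse_gaussian"}
    location : float
        Mean ``mu`` in RT units.
    dispersion : float
        Standard deviation ``sigma`` for the normal family, shape
        ``lambda`` for the inverse-Gaussian family (variance ``mu**3 / lambda``).
    """

    family: str
    location: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        if not (np.isfinite(self.location) and np.isfinite(self.dispersion)):
            raise ValueError("location and dispersion must be finite")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.family == "inverse_gaussian" and self.location <= 0:
            raise ValueError("inverse-Gaussian mean must be positive")

    @property
    def mean(self) -> float:
        return self.location

    @property
    def variance(self) -> float:
        if self.family == "normal":
            return self.dispersion**2
        return self.location**3 / self.dispersion

    def _frozen(self):
        if self.family == "normal":
            return stats.norm(loc=self.location, scale=self.dispersion)
        # scipy's invgauss(mu, scale) has mean mu*scale and shape equal to scale
        return stats.invgauss(self.location / self.dispersion, scale=self.dispersion)

    def pdf(self, t):
        return base_pdf(self, t)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 0:
            raise ValueError("n must be non-negative")
        if self.family == "normal":
            return rng.normal(self.location, self.dispersion, size=n)
        return sample_invgauss(self.location, self.dispersion, n, rng)


def normal(mu: float, sigma: float) -> BaseDistribution:
    """Normal base distribution with mean ``mu`` and SD ``sigma``."""
    return BaseDistribution("normal", float(mu), float(sigma))


def inverse_gaussian(mu: float, lam: float) -> BaseDistribution:
    """Inverse-Gaussian (Wald) base distribution with mean ``mu`` and shape ``lam``."""
    return BaseDistribution("inverse_gaussian", float(mu), float(lam))


@dataclass(frozen=True)
class MixtureSpec:
    """Binary mixture ``p * first + (1 - p) * second``.

    ``proportion`` is the weight on ``first`` and may be 0 or 1 (a degenerate
    mixture equal to one base distribution).
    """

    first: BaseDistribution
    second: BaseDistribution
    proportion: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError("mixture proportion must lie in [0, 1]")

    @property
    def mean(self) -> float:
        p = self.proportion
        return p * self.first.mean + (1.0 - p) * self.second.mean

    def pdf(self, t):
        return mixture_pdf(self, t)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return sample_mixture(self, n, rng)


def base_pdf(dist: BaseDistribution, t):
    """Density of a base distribution, vectorized over ``t``.

    Inverse-Gaussian densities are 0 for non-positive ``t``.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("evaluation points must be finite")
    out = dist._frozen().pdf(t)
    if t.ndim == 0:
        return float(out)
    return out


def mixture_pdf(spec: MixtureSpec, t):
    """``g(t) = p f1(t) + (1-p) f2(t)``, elementwise."""
    p = spec.proportion
    return p * base_pdf(spec.first, t) + (1.0 - p) * base_pdf(spec.second, t)


def analytic_fixed_point(f1: BaseDistribution, f2: BaseDistribution) -> float:
    """Crossing point of two base densities, between their means.

    Solves ``f1(t) = f2(t)`` by bracketed root finding on the interval
    between the two distribution means.  This is the crossing that separates
    the two modes; unequal-dispersion pairs may have additional crossings in
    the tails, which are not returned.

    Raises
    ------
    NoOverlapError
        If ``f1 - f2`` has no sign change between the means (including the
        degenerate equal-means case).
    """
    lo, hi = sorted((f1.mean, f2.mean))
    if hi - lo <= 0:
        raise NoOverlapError("distribution means coincide; no crossing between the means")

    def diff(t: float) -> float:
        return base_pdf(f1, t) - base_pdf(f2, t)

    da, db = diff(lo), diff(hi)
    if da == 0.0:
        return float(lo)
    if db == 0.0:
        return float(hi)
    if math.copysign(1.0, da) == math.copysign(1.0, db):
        raise NoOverlapError("densities do not cross between the means")
    root = brentq(diff, lo, hi, xtol=1e-12 * max(1.0, hi - lo), rtol=8.9e-16)
    return float(root)


def dprime(f1: BaseDistribution, f2: BaseDistribution) -> float:
    """Standardized separation of the two base distributions.

    d' = |mu2 - mu1| / sqrt((var1 + var2) / 2), the mean difference over the
    root-mean of the two variances.  For the inverse-Gaussian family the
    variance is ``mu**3 / lambda``.
    """
    v1, v2 = f1.variance, f2.variance
    pooled = (v1 + v2) / 2.0
    if pooled <= 0:
        raise ValueError("base distributions must have positive variance")
    return abs(f2.mean - f1.mean) / math.sqrt(pooled)


def sample_invgauss(mu: float, lam: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` inverse-Gaussian variates (mean ``mu``, shape ``lam``).

    Uses the Michael–Schucany–Haas transformation: a chi-square variate is
    mapped to the smaller root of the IG quantile relation, which is then
    accepted with probability ``mu / (mu + x)`` (otherwise the conjugate
    root ``mu**2 / x`` is taken).  All outputs are strictly positive.
    """
    if mu <= 0 or lam <= 0:
        raise ValueError("mu and lam must be positive")
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return np.empty(0)
    y = rng.standard_normal(n) ** 2
    x = mu + (mu**2 * y) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * y + mu**2 * y**2
    )
    # guard against tiny negative values from cancellation at y ~ 0
    x = np.maximum(x, np.finfo(float).tiny)
    u = rng.random(n)
    return np.where(u <= mu / (mu + x), x, mu**2 / x)


def sample_mixture(spec: MixtureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` trials from a binary mixture.

    Each trial's latent strategy is Bernoulli(``proportion``); the number of
    draws from each base distribution is therefore itself random, as in a
    real experiment where only the mixture proportion is under experimental
    control.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    pick_first = rng.random(n) < spec.proportion
    out = np.empty(n)
    n1 = int(pick_first.sum())
    out[pick_first] = spec.first.rvs(n1, rng)
    out[~pick_first] = spec.second.rvs(n - n1, rng)
    return out
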