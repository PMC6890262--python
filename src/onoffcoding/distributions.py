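"""Parametric 1-D stimulus distributions.

Every family exposes the probability density, cumulative distribution,
quantile (inverse cdf), partial moments over an interval, and a *compressed*
cdf/quantile built on the one-third power of the density,

    x(theta) = Z * integral_{-inf}^{theta} p(s)^(1/3) ds,

the companding law that allocates thresholds of the optimal linear readout in
the noiseless large-population limit (for the mutual-information criterion the
thresholds equalize the plain cdf instead).

For the Laplace, asymmetric Laplace, Gaussian, uniform and truncated power-law
families the one-third power of the density is again (proportional to) a
density of the same family, so the compressed transforms are closed form: the
compressed distribution is represented as a *companion* distribution object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "StimulusDistribution",
    "Laplace",
    "AsymmetricLaplace",
    "Gaussian",
    "Uniform",
    "TruncatedPowerLaw",
    "load_distribution",
    "load_thresholds",
]

_QUAD_TOL = 1e-10


class UnsupportedDistributionError(ValueError):
    """Raised when p(s)^(1/3) is not normalizable for the requested family."""


class StimulusDistribution:
    """Base class for parametric scalar stimulus distributions.

    Subclasses must provide ``pdf``, ``cdf``, ``quantile`` and the support;
    partial moments and the compressed transforms fall back to adaptive
    quadrature with absolute tolerance 1e-10 unless overridden in closed form.
    """

    #: (lower, upper) support; may be +-inf
    support: tuple[float, float] = (-np.inf, np.inf)

    # -- primitives -------------------------------------------------------
    def pdf(self, s):
        raise NotImplementedError

    def cdf(self, s):
        raise NotImplementedError

    def quantile(self, x):
        """Return s with cdf(s) = x, for x in (0, 1)."""
        x = np.asarray(x, dtype=float)
        if np.any((x <= 0.0) | (x >= 1.0)):
            raise ValueError("quantile argument must lie strictly in (0, 1)")
        return self._quantile(x)

    def _quantile(self, x):
        # generic bracketed inversion of the monotone cdf (Brent to 1e-10)
        def invert_one(xi):
            lo, hi = self.support
            if not np.isfinite(lo):
                lo = -1.0
                while self.cdf(lo) > xi:
                    lo *= 2.0
            if not np.isfinite(hi):
                hi = 1.0
                while self.cdf(hi) < xi:
                    hi *= 2.0
            return optimize.brentq(lambda s: self.cdf(s) - xi, lo, hi, xtol=1e-10)

        return np.vectorize(invert_one)(x)[()]

    # -- moments ----------------------------------------------------------
    def mean(self) -> float:
        return self.partial_mean(*self.support)

    def second_moment(self) -> float:
        lo, hi = self.support
        val, _ = integrate.quad(lambda s: s * s * self.pdf(s), lo, hi,
                                epsabs=_QUAD_TOL, limit=200)
        return val

    def var(self) -> float:
        m = self.mean()
        return self.second_moment() - m * m

    def mass(self, a: float, b: float) -> float:
        """P(a < s <= b)."""
        if b <= a:
            return 0.0
        return float(self.cdf(b) - self.cdf(a))

    def first_moment_cdf(self, s):
        """Partial first moment M1(s) = integral_{-inf}^{s} u p(u) du (vectorized)."""

        def one(si):
            lo = self.support[0]
            if si <= lo:
                return 0.0
            val, _ = integrate.quad(lambda u: u * self.pdf(u), lo, min(si, self.support[1]),
                                    epsabs=_QUAD_TOL, limit=200)
            return val

        return np.vectorize(one)(np.asarray(s, dtype=float))[()]

    def partial_mean(self, a: float, b: float) -> float:
        """integral_a^b s p(s) ds (not normalized by the mass)."""
        if b <= a:
            return 0.0
        return float(self.first_moment_cdf(b) - self.first_moment_cdf(a))

    # -- compressed (one-third power) transforms --------------------------
    def _companion(self) -> "StimulusDistribution":
        """Distribution with density proportional to p(s)^(1/3)."""
        raise NotImplementedError

    def compression_norm(self) -> float:
        """Z^{-1} = integral of p(s)^(1/3) over the support."""
        lo, hi = self.support
        val, err = integrate.quad(lambda s: self.pdf(s) ** (1.0 / 3.0), lo, hi,
                                  epsabs=_QUAD_TOL, limit=200)
        if not np.isfinite(val) or val <= 0:
            raise UnsupportedDistributionError(
                "p(s)^(1/3) is not normalizable for this distribution")
        return val

    def compressed_cdf(self, s):
        try:
            return self._companion().cdf(s)
        except NotImplementedError:
            pass
        zinv = self.compression_norm()
        lo = self.support[0]

        def one(si):
            val, _ = integrate.quad(lambda u: self.pdf(u) ** (1.0 / 3.0), lo, si,
                                    epsabs=_QUAD_TOL, limit=200)
            return val / zinv

        return np.vectorize(one)(np.asarray(s, dtype=float))[()]

    def compressed_quantile(self, x):
        """Return theta with Z * int_{-inf}^{theta} p^(1/3) = x."""
        x = np.asarray(x, dtype=float)
        if np.any((x <= 0.0) | (x >= 1.0)):
            raise ValueError("compressed_quantile argument must lie in (0, 1)")
        try:
            return self._companion().quantile(x)
        except NotImplementedError:
            pass

        def invert_one(xi):
            lo, hi = self.support
            if not np.isfinite(lo):
                lo = -1.0
                while self.compressed_cdf(lo) > xi:
                    lo *= 2.0
            if not np.isfinite(hi):
                hi = 1.0
                while self.compressed_cdf(hi) < xi:
                    hi *= 2.0
            return optimize.brentq(lambda s: self.compressed_cdf(s) - xi,
                                   lo, hi, xtol=1e-10)

        return np.vectorize(invert_one)(x)[()]

    # -- misc -------------------------------------------------------------
    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Sample by inverse-cdf transform (reproducible given the rng)."""
        return np.asarray(self.quantile(rng.uniform(size=size)))


@dataclass(frozen=True)
class AsymmetricLaplace(StimulusDistribution):
    """Two-sided exponential p(s) = A- e^{s/tau-} (s<0), A+ e^{-s/tau+} (s>=0).

    Normalization requires A+ tau+ + A- tau- = 1. If the amplitudes are not
    given, the continuous choice A+ = A- = 1/(tau+ + tau-) is used. The ratio
    tau-/tau+ is the negative stimulus bias.
    """

    tau_plus: float = 1.0
    tau_minus: float = 1.0
    A_plus: float | None = None
    A_minus: float | None = None

    def __post_init__(self):
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("scales tau+ and tau- must be positive")
        if (self.A_plus is None) != (self.A_minus is None):
            raise ValueError("give both amplitudes or neither")
        if self.A_plus is None:
            a = 1.0 / (self.tau_plus + self.tau_minus)
            object.__setattr__(self, "A_plus", a)
            object.__setattr__(self, "A_minus", a)
        norm = self.A_plus * self.tau_plus + self.A_minus * self.tau_minus
        if abs(norm - 1.0) > 1e-8:
            raise ValueError("normalization A+ tau+ + A- tau- = 1 violated")

    # probability mass on each side of zero
    @property
    def _mass_neg(self) -> float:
        return self.A_minus * self.tau_minus

    def pdf(self, s):
        s = np.asarray(s, dtype=float)
        neg = self.A_minus * np.exp(np.minimum(s, 0.0) / self.tau_minus)
        pos = self.A_plus * np.exp(-np.maximum(s, 0.0) / self.tau_plus)
        return np.where(s < 0, neg, pos)[()]

    def cdf(self, s):
        s = np.asarray(s, dtype=float)
        neg = self._mass_neg * np.exp(np.minimum(s, 0.0) / self.tau_minus)
        pos = 1.0 - self.A_plus * self.tau_plus * np.exp(-np.maximum(s, 0.0) / self.tau_plus)
        return np.where(s < 0, neg, pos)[()]

    def _quantile(self, x):
        x = np.asarray(x, dtype=float)
        lower = self.tau_minus * np.log(np.minimum(x, self._mass_neg) / self._mass_neg)
        upper = -self.tau_plus * np.log(
            np.maximum(1.0 - x, 1e-300) / (self.A_plus * self.tau_plus))
        return np.where(x < self._mass_neg, lower, upper)[()]

    def mean(self) -> float:
        return self.A_plus * self.tau_plus ** 2 - self.A_minus * self.tau_minus ** 2

    def second_moment(self) -> float:
        return 2.0 * (self.A_plus * self.tau_plus ** 3 + self.A_minus * self.tau_minus ** 3)

    def first_moment_cdf(self, s):
        s = np.asarray(s, dtype=float)
        am, tm = self.A_minus, self.tau_minus
        ap, tp = self.A_plus, self.tau_plus
        sn = np.minimum(s, 0.0)
        sp = np.maximum(s, 0.0)
        # int_{-inf}^{s} u A- e^{u/tau-} du = A- tau- e^{s/tau-} (s - tau-)
        neg = am * tm * np.exp(sn / tm) * (sn - tm)
        # plus int_0^s u A+ e^{-u/tau+} du for s > 0
        pos = (-am * tm ** 2
               + ap * (tp ** 2 - tp * np.exp(-sp / tp) * (sp + tp)))
        return np.where(s < 0, neg, pos)[()]

    def _companion(self) -> "AsymmetricLaplace":
        # p^(1/3) is again two-sided exponential with tripled scales
        ap, am = self.A_plus ** (1 / 3), self.A_minus ** (1 / 3)
        z = 3.0 * (ap * self.tau_plus + am * self.tau_minus)
        return AsymmetricLaplace(tau_plus=3.0 * self.tau_plus,
                                 tau_minus=3.0 * self.tau_minus,
                                 A_plus=ap / z, A_minus=am / z)

    @property
    def bias(self) -> float:
        """Negative-to-positive stimulus bias tau-/tau+."""
        return self.tau_minus / self.tau_plus


class Laplace(AsymmetricLaplace):
    """Symmetric Laplace p(s) = (1/2tau) e^{-|s|/tau}."""

    def __init__(self, tau: float = 1.0):
        super().__init__(tau_plus=tau, tau_minus=tau)

    @property
    def tau(self) -> float:
        return self.tau_plus


@dataclass(frozen=True)
class Gaussian(StimulusDistribution):
    mu: float = 0.0
    sigma: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def _frozen(self):
        return stats.norm(self.mu, self.sigma)

    def pdf(self, s):
        return self._frozen().pdf(s)

    def cdf(self, s):
        return self._frozen().cdf(s)

    def _quantile(self, x):
        return self._frozen().ppf(x)

    def mean(self) -> float:
        return self.mu

    def second_moment(self) -> float:
        return self.mu ** 2 + self.sigma ** 2

    def first_moment_cdf(self, s):
        fr = self._frozen()
        # int_{-inf}^s u phi(u) du = mu Phi(z) - sigma^2 phi(s)
        return self.mu * fr.cdf(s) - self.sigma ** 2 * fr.pdf(s)

    def _companion(self) -> "Gaussian":
        # phi^{1/3} is a Gaussian with scale sqrt(3) sigma
        return Gaussian(self.mu, math.sqrt(3.0) * self.sigma)


@dataclass(frozen=True)
class Uniform(StimulusDistribution):
    a: float = 0.0
    b: float = 1.0

    def __post_init__(self):
        if not self.b > self.a:
            raise ValueError("need b > a")
        object.__setattr__(self, "support", (self.a, self.b))

    def pdf(self, s):
        s = np.asarray(s, dtype=float)
        inside = (s >= self.a) & (s <= self.b)
        return np.where(inside, 1.0 / (self.b - self.a), 0.0)[()]

    def cdf(self, s):
        s = np.asarray(s, dtype=float)
        return np.clip((s - self.a) / (self.b - self.a), 0.0, 1.0)[()]

    def _quantile(self, x):
        return self.a + np.asarray(x, dtype=float) * (self.b - self.a)

    def mean(self) -> float:
        return 0.5 * (self.a + self.b)

    def second_moment(self) -> float:
        return (self.a ** 2 + self.a * self.b + self.b ** 2) / 3.0

    def first_moment_cdf(self, s):
        s = np.clip(np.asarray(s, dtype=float), self.a, self.b)
        return (0.5 * (s ** 2 - self.a ** 2) / (self.b - self.a))[()]

    def _companion(self) -> "Uniform":
        # compression is the identity for flat densities
        return Uniform(self.a, self.b)


@dataclass(frozen=True)
class TruncatedPowerLaw(StimulusDistribution):
    """p(s) proportional to s^exponent on [lower, upper], 0 < lower < upper."""

    exponent: float = -0.58
    lower: float = 1.0
    upper: float = 4.22e4

    def __post_init__(self):
        if not (0 < self.lower < self.upper):
            raise ValueError("need 0 < lower < upper")
        if not np.isfinite(self.upper) and self.exponent >= -1.0:
            raise ValueError("unbounded support needs exponent < -1")
        object.__setattr__(self, "support", (self.lower, self.upper))

    @staticmethod
    def _power_integral(a: float, lo: float, hi: float) -> float:
        # int_lo^hi s^a ds
        if abs(a + 1.0) < 1e-12:
            return math.log(hi / lo)
        return (hi ** (a + 1.0) - lo ** (a + 1.0)) / (a + 1.0)

    @property
    def _norm(self) -> float:
        return self._power_integral(self.exponent, self.lower, self.upper)

    def pdf(self, s):
        s = np.asarray(s, dtype=float)
        inside = (s >= self.lower) & (s <= self.upper)
        with np.errstate(invalid="ignore"):
            val = np.where(inside, s, 1.0) ** self.exponent / self._norm
        return np.where(inside, val, 0.0)[()]

    def cdf(self, s):
        s = np.asarray(s, dtype=float)

        def one(si):
            if si <= self.lower:
                return 0.0
            if si >= self.upper:
                return 1.0
            return self._power_integral(self.exponent, self.lower, si) / self._norm

        return np.vectorize(one)(s)[()]

    def _quantile(self, x):
        x = np.asarray(x, dtype=float)
        a = self.exponent
        if abs(a + 1.0) < 1e-12:
            return self.lower * (self.upper / self.lower) ** x
        lo1 = self.lower ** (a + 1.0)
        return (lo1 + x * (self.upper ** (a + 1.0) - lo1)) ** (1.0 / (a + 1.0))

    def first_moment_cdf(self, s):
        def one(si):
            hi = min(si, self.upper)
            if hi <= self.lower:
                return 0.0
            return self._power_integral(self.exponent + 1.0, self.lower, hi) / self._norm

        return np.vectorize(one)(np.asarray(s, dtype=float))[()]

    def second_moment(self) -> float:
        return self._power_integral(self.exponent + 2.0, self.lower, self.upper) / self._norm

    def _companion(self) -> "TruncatedPowerLaw":
        return TruncatedPowerLaw(self.exponent / 3.0, self.lower, self.upper)


_FAMILIES = {
    "laplace": Laplace,
    "asymmetric_laplace": AsymmetricLaplace,
    "gaussian": Gaussian,
    "uniform": Uniform,
    "truncated_power_law": TruncatedPowerLaw,
}


def load_distribution(source) -> StimulusDistribution:
    """Build a distribution from a mapping or a YAML/JSON config file.

    The config is a flat key-value mapping with a ``family`` key (one of
    laplace, asymmetric_laplace, gaussian, uniform, truncated_power_law) and
    family-specific parameters, e.g.::

        family: asymmetric_laplace
        tau_plus: 1.0
        tau_minus: 2.0
    """
    if isinstance(source, StimulusDistribution):
        return source
    if not isinstance(source, Mapping):
        import yaml

        with open(source) as fh:
            source = yaml.safe_load(fh)
    params = dict(source)
    family = params.pop("family", None)
    if family not in _FAMILIES:
        raise ValueError(f"unknown distribution family {family!r}; "
                         f"choose from {sorted(_FAMILIES)}")
    return _FAMILIES[family](**params)


def load_thresholds(path) -> np.ndarray:
    """Read a threshold list from one-value-per-line text or 1-column CSV."""
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip().rstrip(",")
            if not line:
                continue
            values.append(float(line.split(",")[0]))
    if not values:
        raise ValueError(f"no thresholds found in {path}")
    return np.asarray(values, dtype=float)
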