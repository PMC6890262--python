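"""Reverse inference: from measured thresholds to the stimulus distribution.

Efficient coding normally maps a known stimulus distribution to optimal
thresholds. For sensory systems where the stimulus distribution is unknown —
e.g. odorant concentrations encoded by olfactory receptor neurons whose
dose-response thresholds (EC50 values) have been measured — the framework can
be inverted: assume the measured thresholds are optimal and recover the
stimulus distribution they would be optimized for.

For a threshold set whose inverse-threshold survival function follows a power
law, P(1/theta > z) ~ z^{-lambda}, the threshold density is
p_theta(theta) ~ theta^{lambda - 1}. Under the infomax criterion thresholds
equalize the stimulus cdf, so the stimulus density has the *same* exponent;
under the linear-MSE criterion they equalize the cdf of p^{1/3}, so the
stimulus-density exponent is *three times* the threshold-density exponent.
(All exponents are density exponents; the cumulative-to-density conversion,
a -1 shift on the survival slope, happens only in ``fit_threshold_powerlaw``.)
Proportionality constants are never reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PowerLawFit", "fit_threshold_powerlaw", "infer_stimulus_distribution"]


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of the log-log survival of inverse thresholds."""

    slope: float | None           # d log P(1/theta > z) / d log z  (= -lambda)
    density_exponent: float | None  # threshold-density exponent, lambda - 1
    cutoff: float | None          # largest threshold (upper support edge)
    r_squared: float | None
    n: int
    degenerate: bool = False
    hill_density_exponent: float | None = None  # ML (Hill) cross-check; OLS is reported

    @property
    def lam(self) -> float | None:
        """Survival-law exponent lambda with P(1/theta > z) ~ z^{-lambda}."""
        return None if self.slope is None else -self.slope


def fit_threshold_powerlaw(thresholds, min_count: int = 20,
                           survival_min: float = 0.01) -> PowerLawFit:
    """Fit a power law to the cumulative distribution of inverse thresholds.

    Ordinary least squares of log P(1/theta > z) against log z over the
    empirical survival points (the presentation used for pooled ORN threshold
    data); the slope is -lambda and the implied threshold-density exponent is
    lambda - 1. ECDF points with survival below ``survival_min`` — the noisy,
    truncation-dominated extreme tail of the survival plot — are excluded
    from the regression. A maximum-likelihood (Hill) exponent is attached as
    a cross-check. Identical inputs give identical fits. Unbiased recovery
    needs several decades between the lower and upper threshold cutoffs; see
    the methods note for the finite-range bias.
    """
    th = np.sort(np.asarray(thresholds, dtype=float))
    if len(th) < min_count:
        raise ValueError(f"need at least {min_count} thresholds, got {len(th)}")
    if np.any(th <= 0):
        raise ValueError("thresholds must be strictly positive")
    if np.ptp(th) <= 1e-12 * th[-1]:
        return PowerLawFit(slope=None, density_exponent=None, cutoff=float(th[-1]),
                           r_squared=None, n=len(th), degenerate=True)

    z = np.sort(1.0 / th)
    n = len(z)
    survival = 1.0 - np.arange(1, n + 1) / n
    keep = survival >= max(survival_min, 0.5 / n)
    logz, logs = np.log(z[keep]), np.log(survival[keep])
    slope, intercept = np.polyfit(logz, logs, 1)
    resid = logs - (slope * logz + intercept)
    ss_tot = float(np.sum((logs - logs.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0

    lam = -slope
    # maximum-likelihood (Hill) exponent of the Pareto tail of 1/theta,
    # converted to the same threshold-density convention, as a cross-check
    hill_lam = 1.0 / float(np.mean(np.log(z / z[0])))
    return PowerLawFit(slope=float(slope), density_exponent=float(lam - 1.0),
                       cutoff=float(th[-1]), r_squared=r2, n=n,
                       hill_density_exponent=hill_lam - 1.0)


def infer_stimulus_distribution(density_exponent: float, criterion: str) -> float:
    """Predicted stimulus-density power-law exponent from a threshold exponent.

    ``infomax``: thresholds equalize the stimulus cdf, so the stimulus density
    inherits the threshold-density exponent unchanged. ``linear_mse``:
    thresholds equalize the cdf of p^{1/3}, so the exponent is tripled. The
    two predictions always differ by exactly a factor of three.
    """
    if criterion == "infomax":
        return float(density_exponent)
    if criterion == "linear_mse":
        return 3.0 * float(density_exponent)
    raise ValueError("criterion must be 'infomax' or 'linear_mse'")
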