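"""Mutual information of binary ON/OFF Poisson populations.

A population of N neurons encodes a scalar stimulus s through binary rate
functions: an ON neuron fires Poisson spikes with expected count R = nu_max*T
whenever s >= theta, an OFF neuron whenever s < theta, and is exactly silent
otherwise. Because the rate takes only two values, all nonzero spike counts
can be lumped into a single "spike" state without information loss, leaving a
binary channel per neuron with p(0|active) = q = e^{-R}.

This module provides

* closed forms: the noise entropy H_q, the maximal information
  I = log(1 + N e^{-H_q}) (identical for every non-overlapping ON/OFF mixture
  — the Equal Coding Theorem), and the optimal interval partition / threshold
  positions that achieve it;
* exact evaluation of the information for arbitrary threshold profiles by
  enumerating the 2^N response patterns, and an equivalent recursive form for
  homogeneous populations;
* numerical maximization of the information over thresholds for fixed or
  enumerated ON/OFF label strings (label 'N' = ON, 'F' = OFF along the sorted
  thresholds), including the enforced-overlap constraint;
* the mean spike count per neuron of a profile.

Information is computed internally in nats; results carry both nats and bits.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .distributions import StimulusDistribution

__all__ = [
    "PopulationSpec",
    "ThresholdProfile",
    "IntervalPartition",
    "CodingResult",
    "noise_entropy",
    "max_information",
    "optimal_partition",
    "optimal_thresholds",
    "exact_information",
    "pattern_information",
    "information_recursive",
    "optimize_thresholds",
    "mean_spike_count",
]

LOG2 = math.log(2.0)
_MAX_ENUM_N = 20


class OverlappingLabelsError(ValueError):
    """Closed forms only exist for non-overlapping mixtures."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

def _check_labels(labels: str) -> str:
    labels = labels.upper()
    if not labels or set(labels) - {"F", "N"}:
        raise ValueError("labels must be a non-empty string over {'F','N'}")
    return labels


def labels_overlap(labels: str) -> bool:
    """True if some ON ('N') threshold lies below some OFF ('F') threshold."""
    labels = _check_labels(labels)
    return "NF" in "".join(k for k, _ in itertools.groupby(labels))


@dataclass(frozen=True)
class PopulationSpec:
    """N neurons with ON/OFF labels along sorted thresholds and noise R.

    ``labels[i]`` gives the identity of the i-th smallest threshold:
    'F' for OFF, 'N' for ON. The noise parameter is q = e^{-R}; R = inf
    (q = 0) is the exact noiseless limit.
    """

    N: int
    labels: str
    R: float

    def __post_init__(self):
        object.__setattr__(self, "labels", _check_labels(self.labels))
        if self.N < 1 or len(self.labels) != self.N:
            raise ValueError("labels length must equal N >= 1")
        if not self.R > 0:
            raise ValueError("expected spike count R must be positive")

    @property
    def q(self) -> float:
        return math.exp(-self.R) if np.isfinite(self.R) else 0.0

    @property
    def n_on(self) -> int:
        return self.labels.count("N")

    @property
    def overlapping(self) -> bool:
        return labels_overlap(self.labels)

    @classmethod
    def mixture(cls, N: int, m: int, R: float) -> "PopulationSpec":
        """Non-overlapping mixture with m ON cells above N-m OFF cells."""
        if not 0 <= m <= N:
            raise ValueError("need 0 <= m <= N")
        return cls(N=N, labels="F" * (N - m) + "N" * m, R=R)


@dataclass(frozen=True)
class ThresholdProfile:
    """Sorted thresholds with cumulative positions x_i = cdf(theta_i)."""

    thresholds: np.ndarray
    positions: np.ndarray
    labels: str
    dist: StimulusDistribution | None = None

    def __post_init__(self):
        th = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        x = np.atleast_1d(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "thresholds", th)
        object.__setattr__(self, "positions", x)
        object.__setattr__(self, "labels", _check_labels(self.labels))
        if len(th) != len(x) or len(th) != len(self.labels):
            raise ValueError("thresholds, positions and labels must align")
        if np.any(np.diff(th) < -1e-12) or np.any(np.diff(x) < -1e-12):
            raise ValueError("thresholds must be sorted ascending")
        if np.any((x < 0) | (x > 1)):
            raise ValueError("cumulative positions must lie in [0, 1]")
        if self.dist is not None:
            err = np.max(np.abs(np.asarray(self.dist.cdf(th)) - x))
            if err > 1e-8:
                raise ValueError("positions inconsistent with cdf(thresholds)")

    @property
    def N(self) -> int:
        return len(self.thresholds)

    @classmethod
    def from_positions(cls, positions, labels: str,
                       dist: StimulusDistribution | None = None) -> "ThresholdProfile":
        x = np.atleast_1d(np.asarray(positions, dtype=float))
        th = np.asarray(dist.quantile(x), dtype=float) if dist is not None else x.copy()
        return cls(thresholds=th, positions=x, labels=labels, dist=dist)

    def interval_masses(self) -> np.ndarray:
        """Stimulus probability mass of the N+1 intervals cut by thresholds."""
        edges = np.concatenate(([0.0], self.positions, [1.0]))
        return np.diff(edges)

    def response_masses(self) -> np.ndarray:
        """P(neuron i active) for each sorted threshold."""
        x = self.positions
        on = np.array([c == "N" for c in self.labels])
        return np.where(on, 1.0 - x, x)


@dataclass(frozen=True)
class IntervalPartition:
    """Optimal interval masses p_0 ... p_N over stimulus space."""

    masses: np.ndarray
    p: float
    p_edge: float
    p_silent: float
    silent_index: int

    def __post_init__(self):
        m = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "masses", m)
        if np.any(m < -1e-12):
            raise AssertionError("negative interval mass")
        if abs(m.sum() - 1.0) > 1e-12:
            raise AssertionError("interval masses must sum to 1")


@dataclass(frozen=True)
class CodingResult:
    """Information (nats/bits) or MSE with solver diagnostics."""

    nats: float | None = None
    mse: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def bits(self) -> float | None:
        return None if self.nats is None else self.nats / LOG2

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))


# --------------------------------------------------------------------------
# closed forms
# --------------------------------------------------------------------------

def noise_entropy(q: float) -> float:
    """H_q = -[(1-q)log(1-q) + q log q]/(1-q) in nats; H_0 = 0 by continuity."""
    if q < 0.0 or q >= 1.0:
        raise ValueError("noise parameter q must satisfy 0 <= q < 1")
    if q == 0.0:
        return 0.0
    return -((1.0 - q) * math.log1p(-q) + q * math.log(q)) / (1.0 - q)


def max_information(N: int, q: float | None = None, *, R: float | None = None) -> CodingResult:
    """Maximal information I = log(1 + N e^{-H_q}) for optimized thresholds.

    Identical for every non-overlapping ON/OFF mixture and independent of the
    stimulus distribution. Pass either q or R = -log q.
    """
    if (q is None) == (R is None):
        raise ValueError("give exactly one of q and R")
    if q is None:
        q = math.exp(-R) if np.isfinite(R) else 0.0
    if N < 1:
        raise ValueError("N must be >= 1")
    nats = math.log1p(N * math.exp(-noise_entropy(q)))
    return CodingResult(nats=nats, diagnostics={"N": N, "q": q, "method": "closed_form"})


def optimal_partition(N: int, m: int, q: float) -> IntervalPartition:
    """Optimal interval masses for m ON cells above N - m OFF cells.

    Interior intervals carry p = 1/(N + e^{H_q}); the two outermost intervals
    (the response regions of the most extreme cells) carry p_edge = p/(1-q);
    the remaining mass sits in the silent interval separating ON from OFF
    thresholds (below all thresholds for a homogeneous population).
    """
    if not 0 <= m <= N:
        raise ValueError("need 0 <= m <= N")
    hq = noise_entropy(q)
    p = 1.0 / (N + math.exp(hq))
    p_edge = p / (1.0 - q)
    homogeneous = m in (0, N)
    if homogeneous:
        p_silent = 1.0 - (N - 1) * p - p_edge
        if m == 0:  # all OFF: silence above the largest threshold
            masses = np.concatenate(([p_edge], np.full(N - 1, p), [p_silent]))
            silent_index = N
        else:  # all ON: silence below the smallest threshold
            masses = np.concatenate(([p_silent], np.full(N - 1, p), [p_edge]))
            silent_index = 0
    else:
        p_silent = 1.0 - (N - 2) * p - 2.0 * p_edge
        masses = np.concatenate((
            [p_edge], np.full(N - m - 1, p),      # OFF block
            [p_silent],
            np.full(m - 1, p), [p_edge],          # ON block
        ))
        silent_index = N - m
    return IntervalPartition(masses=masses, p=p, p_edge=p_edge,
                             p_silent=p_silent, silent_index=silent_index)


def optimal_thresholds(spec: PopulationSpec,
                       dist: StimulusDistribution | None = None) -> ThresholdProfile:
    """Closed-form information-maximizing thresholds for a non-overlapping mixture.

    Cumulative positions are the running sums of the optimal partition;
    stimulus-space thresholds follow by quantile mapping (identity when no
    distribution is given).
    """
    if spec.overlapping:
        raise OverlappingLabelsError(
            "closed-form thresholds exist only for non-overlapping mixtures; "
            "use optimize_thresholds for overlapping label strings")
    part = optimal_partition(spec.N, spec.n_on, spec.q)
    positions = np.cumsum(part.masses)[:-1]
    labels = "F" * (spec.N - spec.n_on) + "N" * spec.n_on
    return ThresholdProfile.from_positions(positions, labels, dist)


# --------------------------------------------------------------------------
# exact information for arbitrary profiles
# --------------------------------------------------------------------------

def _binary_entropy(u: float) -> float:
    if u <= 0.0 or u >= 1.0:
        return 0.0
    return -u * math.log(u) - (1.0 - u) * math.log1p(-u)


def pattern_information(interval_masses, labels: str, q: float) -> CodingResult:
    """Exact I(s; n) from the N+1 interval masses and the sorted label string.

    Enumerates all 2^N lumped binary response patterns. Within interval j the
    active set is fixed, so the conditional response entropy is
    |active| * h(1-q) and only the marginal pattern distribution needs the
    enumeration. Exact for q = 0 as well (deterministic neurons).
    """
    labels = _check_labels(labels)
    N = len(labels)
    if N > _MAX_ENUM_N:
        raise ValueError(
            f"pattern enumeration is limited to N <= {_MAX_ENUM_N}; "
            "use spiking.mc_mutual_information for larger populations")
    masses = np.asarray(interval_masses, dtype=float)
    if len(masses) != N + 1:
        raise ValueError("need N+1 interval masses for N neurons")
    if np.any(masses < -1e-12) or abs(masses.sum() - 1.0) > 1e-9:
        raise ValueError("interval masses must be a probability vector")
    if q < 0.0 or q >= 1.0:
        raise ValueError("noise parameter q must satisfy 0 <= q < 1")

    on = np.array([c == "N" for c in labels])
    # active-set bitmask per interval: neuron i (bit i) is active in interval
    # j iff (ON and j >= i+1) or (OFF and j <= i)
    idx = np.arange(N)
    patterns = np.arange(1 << N, dtype=np.int64)
    popcount = np.zeros(1 << N, dtype=np.int64)
    for i in range(N):
        popcount += (patterns >> i) & 1

    prob = np.zeros(1 << N)
    h_cond = 0.0
    h1q = _binary_entropy(1.0 - q)
    for j in range(N + 1):
        if masses[j] <= 0.0:
            continue
        active = np.where(on, j >= idx + 1, j <= idx)
        mask = int(np.sum(np.where(active, 1 << idx, 0)))
        n_active = int(active.sum())
        sub = patterns[(patterns & ~mask) == 0]
        k = popcount[sub]
        if q == 0.0:
            prob[mask] += masses[j]
        else:
            prob[sub] += masses[j] * (1.0 - q) ** k * q ** (n_active - k)
        h_cond += masses[j] * n_active * h1q

    nz = prob[prob > 0.0]
    h_resp = -float(np.sum(nz * np.log(nz)))
    nats = max(h_resp - h_cond, 0.0)
    return CodingResult(nats=nats, diagnostics={
        "method": "pattern_enumeration", "N": N, "q": q,
        "response_entropy_nats": h_resp, "noise_entropy_nats": h_cond})


def exact_information(profile: ThresholdProfile, q: float) -> CodingResult:
    """Exact mutual information of an arbitrary threshold profile."""
    return pattern_information(profile.interval_masses(), profile.labels, q)


def information_recursive(u, q: float) -> CodingResult:
    """Nested-form information of a homogeneous ON population.

    ``u`` are the response-region probabilities 0 < u_1 < ... < u_N < 1 of the
    N ON cells counted from the largest threshold down (u_i is the mass above
    the i-th largest threshold). Evaluates

        I = g(u_1) + (1 - u_1(1-q)) [ g(u_2') + ... ]

    with g(u) = h(u(1-q)) - u h(1-q) and the posterior revisions
    u_i' = (u_i - u_k(1-q)) / (1 - u_k(1-q)) applied after each observed
    silence. Equals the pattern-enumeration information on the same intervals.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float)).copy()
    if np.any(np.diff(u) <= 0):
        raise ValueError("u must be strictly increasing")
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie strictly in (0, 1)")
    if q < 0.0 or q >= 1.0:
        raise ValueError("noise parameter q must satisfy 0 <= q < 1")

    def g(ui: float) -> float:
        return _binary_entropy(ui * (1.0 - q)) - ui * _binary_entropy(1.0 - q)

    nats, weight = 0.0, 1.0
    for k in range(len(u)):
        nats += weight * g(u[k])
        denom = 1.0 - u[k] * (1.0 - q)
        weight *= denom
        u[k + 1:] = (u[k + 1:] - u[k] * (1.0 - q)) / denom
    return CodingResult(nats=nats, diagnostics={"method": "recursive", "q": q})


def mean_spike_count(spec: PopulationSpec, profile: ThresholdProfile) -> float:
    """Mean spikes per neuron per coding window, (R/N) * sum_i P(active_i)."""
    if profile.N != spec.N:
        raise ValueError("profile size does not match population spec")
    return spec.R / spec.N * float(np.sum(profile.response_masses()))


# --------------------------------------------------------------------------
# numerical threshold optimization
# --------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - np.max(z)
    e = np.exp(z)
    return e / e.sum()


def _optimize_fixed_labels(labels: str, q: float, n_restarts: int,
                           rng: np.random.Generator, tol: float):
    """Maximize pattern information over the (N+1)-simplex of interval masses."""
    N = len(labels)

    def neg_info(z):
        return -pattern_information(_softmax(z), labels, q).nats

    starts = [np.zeros(N + 1)]  # equal-mass partition ansatz
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(np.log(rng.dirichlet(np.ones(N + 1)) + 1e-12))

    best_val, best_masses, any_ok = -np.inf, None, False
    for z0 in starts:
        res = optimize.minimize(neg_info, z0, method="L-BFGS-B",
                                options={"ftol": 1e-14, "gtol": 1e-10,
                                         "maxiter": 500})
        any_ok = any_ok or res.success
        if -res.fun > best_val:
            best_val, best_masses = -res.fun, _softmax(res.x)
    # polish with a simplex pass from the best point
    res = optimize.minimize(neg_info, np.log(best_masses + 1e-300),
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": tol, "maxiter": 4000})
    if -res.fun > best_val:
        best_val, best_masses = -res.fun, _softmax(res.x)
    return best_val, best_masses, any_ok


def optimize_thresholds(spec: PopulationSpec,
                        mode: str = "fixed_labels",
                        *,
                        dist: StimulusDistribution | None = None,
                        n_restarts: int = 12,
                        seed: int | None = 0,
                        tol: float = 1e-10,
                        config_tol_bits: float = 1e-3):
    """Numerically maximize the exact information over thresholds.

    mode
        ``fixed_labels`` optimizes the thresholds of ``spec.labels`` only;
        ``allow_overlap`` enumerates every length-N label string and returns
        the best; ``enforce_overlap`` restricts the enumeration to strings
        with at least one ON threshold below an OFF threshold.

    Returns ``(profile, result)``; ``result.diagnostics['configurations']``
    lists every label string whose optimum lies within ``config_tol_bits`` of
    the best (Table-2 style reporting).
    """
    if mode not in ("fixed_labels", "allow_overlap", "enforce_overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode != "fixed_labels" and spec.N > 10:
        raise ValueError("label enumeration is limited to N <= 10; "
                         "use mode='fixed_labels' for larger populations")
    rng = np.random.default_rng(seed)
    q = spec.q

    if mode == "fixed_labels":
        label_sets = [spec.labels]
    else:
        label_sets = ["".join(c) for c in itertools.product("FN", repeat=spec.N)]
        if mode == "enforce_overlap":
            label_sets = [s for s in label_sets if labels_overlap(s)]

    per_label: dict[str, float] = {}
    best = (-np.inf, None, None, True)
    for labels in label_sets:
        val, masses, ok = _optimize_fixed_labels(labels, q, n_restarts, rng, tol)
        per_label[labels] = val
        if val > best[0]:
            best = (val, masses, labels, ok)

    nats, masses, labels, ok = best
    configs = sorted(s for s, v in per_label.items()
                     if (nats - v) / LOG2 <= config_tol_bits)
    positions = np.cumsum(masses)[:-1]
    profile = ThresholdProfile.from_positions(positions, labels, dist)
    result = CodingResult(nats=nats, diagnostics={
        "method": "numerical", "mode": mode, "labels": labels,
        "configurations": configs, "converged": ok,
        "per_label_bits": {k: v / LOG2 for k, v in per_label.items()},
        "n_restarts": n_restarts})
    return profile, result
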