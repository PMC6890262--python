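"""Forward spiking simulator and Monte-Carlo validation oracles.

Generates Poisson spike counts from binary ON/OFF rate functions and
estimates the mutual information and the linear-readout MSE empirically, as
independent cross-checks of the analytic machinery in ``infomax`` and
``linear_readout``. Raw Poisson counts are kept (lumping to binary states
happens at analysis time) so the 1/R-normalized decoder is simulated exactly
as defined. All stochastic outputs are deterministic functions of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import StimulusDistribution
from .infomax import ThresholdProfile
from .linear_readout import LinearReadout

__all__ = [
    "SpikeBatch",
    "simulate_responses",
    "mc_mutual_information",
    "mc_mse",
    "generate_power_law_thresholds",
]


@dataclass(frozen=True)
class SpikeBatch:
    """Simulated stimuli and integer spike counts (trials x neurons)."""

    stimuli: np.ndarray
    counts: np.ndarray
    R: float
    profile: ThresholdProfile

    @property
    def n_trials(self) -> int:
        return len(self.stimuli)


def _active_matrix(profile: ThresholdProfile, stimuli: np.ndarray) -> np.ndarray:
    """Boolean (trials x neurons): ON fires for s >= theta, OFF for s < theta."""
    s = np.asarray(stimuli, dtype=float)[:, None]
    th = profile.thresholds[None, :]
    on = np.array([c == "N" for c in profile.labels])[None, :]
    return np.where(on, s >= th, s < th)


def simulate_responses(profile: ThresholdProfile, R: float, stimuli,
                       seed: int | np.random.Generator) -> SpikeBatch:
    """Draw Poisson(R) spike counts wherever a neuron's step function is active."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stimuli = np.asarray(stimuli, dtype=float)
    active = _active_matrix(profile, stimuli)
    counts = np.where(active, rng.poisson(R, size=active.shape), 0)
    return SpikeBatch(stimuli=stimuli, counts=counts, R=R, profile=profile)


def _plugin_mi(table: np.ndarray) -> float:
    """Plug-in MI (nats) of a joint count table."""
    n = table.sum()
    pj = table.sum(axis=1, keepdims=True) / n
    pb = table.sum(axis=0, keepdims=True) / n
    p = table / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / (pj * pb)), 0.0)
    return float(terms.sum())


def mc_mutual_information(profile: ThresholdProfile, q: float, n_trials: int,
                          seed: int | np.random.Generator,
                          dist: StimulusDistribution | None = None):
    """Monte-Carlo MI estimate (bits are in result.diagnostics; value in nats).

    Samples stimuli, binarizes the simulated responses, and evaluates the
    plug-in MI between the stimulus interval index (a sufficient statistic
    for the piecewise-constant rates) and the binary response pattern. The
    standard error is the leave-one-out jackknife, grouped by the occupied
    cells of the joint table. Returns ``(mi_nats, se_nats)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dist is not None:
        stimuli = dist.rvs(n_trials, rng)
        edges = profile.thresholds
    else:  # positions live in cumulative space: sample uniformly
        stimuli = rng.uniform(size=n_trials)
        edges = profile.positions
    R = -np.log(q) if q > 0 else np.inf
    active = _active_matrix(profile, stimuli)
    if q > 0:
        fired = active & (rng.uniform(size=active.shape) < 1.0 - q)
    else:
        fired = active
    interval = np.searchsorted(edges, stimuli, side="right")
    pattern = fired @ (1 << np.arange(profile.N))

    # joint table over occupied (interval, pattern) cells
    pat_ids, pat_idx = np.unique(pattern, return_inverse=True)
    table = np.zeros((profile.N + 1, len(pat_ids)))
    np.add.at(table, (interval, pat_idx), 1.0)

    mi = _plugin_mi(table)
    # leave-one-out jackknife, grouped by cell (removing any one of the
    # n_jk samples in cell (j,b) yields the same estimate)
    occupied = np.argwhere(table > 0)
    loo = np.empty(len(occupied))
    for k, (j, b) in enumerate(occupied):
        t = table.copy()
        t[j, b] -= 1.0
        loo[k] = _plugin_mi(t)
    w = table[table > 0]
    mean_loo = float(np.sum(w * loo) / n_trials)
    var_jk = (n_trials - 1) / n_trials * float(np.sum(w * (loo - mean_loo) ** 2))
    return mi, np.sqrt(var_jk)


def mc_mse(readout: LinearReadout, dist: StimulusDistribution, R: float,
           n_trials: int, seed: int | np.random.Generator):
    """Monte-Carlo MSE of a readout on simulated spike counts.

    Returns ``(mse, se)`` with the standard error of the mean squared
    residual. R = inf decodes the deterministic step responses.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stimuli = dist.rvs(n_trials, rng)
    if np.isinf(R):
        y = readout.decode_stimulus(stimuli)
    else:
        batch = simulate_responses(readout.profile, R, stimuli, rng)
        y = readout.decode_counts(batch.counts)
    sq = (y - stimuli) ** 2
    return float(sq.mean()), float(sq.std(ddof=1) / np.sqrt(n_trials))


def generate_power_law_thresholds(exponent: float, cutoff: float, n: int,
                                  seed: int | np.random.Generator,
                                  lower: float = 1.0) -> np.ndarray:
    """Draw n thresholds from a density ~ theta^exponent on [lower, cutoff].

    Defaults emulate a pooled set of olfactory receptor neuron activation
    thresholds: density exponent -0.58 with an upper cutoff of 4.22e4 when
    called with those values. Sampling is by inverse-cdf, so the output is a
    deterministic function of the seed.
    """
    from .distributions import TruncatedPowerLaw

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = TruncatedPowerLaw(exponent=exponent, lower=lower, upper=cutoff)
    return np.sort(dist.rvs(n, rng))
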