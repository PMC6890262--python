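"""Optimal linear decoding of a scalar stimulus from ON/OFF spike counts.

A downstream readout estimates the stimulus as a weighted sum of spike
counts, y = (1/R) sum_i w_i n_i + w0 (the 1/R normalization makes the weights
stimulus-valued; for R = inf the responses are deterministic step functions
and the readout reduces to y = sum_i w_i a_i(s) + w0 with a_i in {0,1}).
Weights, offset and thresholds are chosen to minimize the mean squared error
<(y - s)^2>.

Without noise the optimal solution is the classic Lloyd-Max quantizer with
N+1 reconstruction levels: interval centers of mass, midpoint thresholds, an
MSE proportional to 1/N^2, and — in the large-N limit — a threshold density
proportional to p(s)^{1/3} (the compressed quantile of ``distributions``).
The MSE is identical for every ON/OFF mixture; only the offset w0 and the
weight signs differ.

With Poisson noise the mixture matters. The solver alternates an exact linear
solve for (w, w0) given thresholds with the stationarity update for the
thresholds,

    theta_i = y_above(theta_i) - (w_i/2)(1 - 1/R)   (ON)
    theta_i = y_above(theta_i) + (w_i/2)(1 + 1/R)   (OFF)

where y_above is the decoded value just above the threshold. In the large-N
regime the optimal threshold density becomes proportional to sqrt(1 - F(s))
for ON cells and sqrt(F(s)) for OFF cells (F the stimulus cdf) — a linear
bulk with logarithmic tails for Laplace stimuli — and the common first ON/OFF
threshold phi of a mixed population satisfies the junction condition
n_OFF(phi)/n_ON(phi) = F(phi)/(1 - F(phi)), solved in
``first_threshold_mixed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .distributions import AsymmetricLaplace, StimulusDistribution
from .infomax import CodingResult, PopulationSpec, ThresholdProfile, optimal_thresholds

__all__ = [
    "LinearReadout",
    "MseCurve",
    "solve_noiseless",
    "solve_with_noise",
    "evaluate_mse",
    "sweep_off_fraction",
    "asymptotic_thresholds",
    "AsymptoticThresholds",
    "first_threshold_mixed",
]


@dataclass(frozen=True)
class LinearReadout:
    """Decoding weights (per sorted neuron), offset and thresholds."""

    weights: np.ndarray
    w0: float
    profile: ThresholdProfile
    R: float = np.inf

    def __post_init__(self):
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "weights", w)
        if len(w) != self.profile.N:
            raise ValueError("one weight per neuron required")

    @property
    def labels(self) -> str:
        return self.profile.labels

    def decode_counts(self, counts: np.ndarray) -> np.ndarray:
        """Apply y = (1/R) sum w_i n_i + w0 (or the step form if R = inf)."""
        counts = np.asarray(counts, dtype=float)
        scale = 1.0 if np.isinf(self.R) else 1.0 / self.R
        return scale * counts @ self.weights + self.w0

    def decode_stimulus(self, s) -> np.ndarray:
        """Noise-free staircase y(s) = sum_i w_i a_i(s) + w0."""
        s = np.asarray(s, dtype=float)[..., None]
        th = self.profile.thresholds
        on = np.array([c == "N" for c in self.labels])
        a = np.where(on, s >= th, s < th)
        return (a @ self.weights + self.w0)[()]


@dataclass(frozen=True)
class MseCurve:
    """Normalized MSE versus OFF fraction alpha (alpha derived from m)."""

    alphas: np.ndarray
    mse: np.ndarray
    normalized: np.ndarray
    alpha_star: float
    results: list = field(default_factory=list)


# --------------------------------------------------------------------------
# moment assembly
# --------------------------------------------------------------------------

def _activation_matrix(labels: str) -> np.ndarray:
    """A[i, j] = 1 if neuron i (sorted) is active in interval j (0..N)."""
    N = len(labels)
    j = np.arange(N + 1)
    rows = [(j >= i + 1) if lab == "N" else (j <= i)
            for i, lab in enumerate(labels)]
    return np.asarray(rows, dtype=float)


def _interval_moments(dist: StimulusDistribution, thresholds: np.ndarray):
    edges = np.concatenate(([-np.inf], thresholds, [np.inf]))
    lo, hi = dist.support
    edges = np.clip(edges, lo, hi) if np.isfinite(lo) or np.isfinite(hi) else edges
    cdf = np.concatenate(([0.0], np.asarray(dist.cdf(thresholds), dtype=float), [1.0]))
    m1 = np.concatenate(([0.0],
                         np.asarray(dist.first_moment_cdf(thresholds), dtype=float),
                         [dist.mean()]))
    return np.diff(cdf), np.diff(m1)


def _normal_system(dist, thresholds, labels, R):
    """Second-moment system for (w, w0): M v = c minimizes the analytic MSE."""
    A = _activation_matrix(labels)
    masses, pmeans = _interval_moments(dist, thresholds)
    act_mass = A @ masses                    # <a_i>
    M = (A * masses) @ A.T                   # <a_i a_j>
    if np.isfinite(R):
        M = M + np.diag(act_mass) / R        # Poisson variance term
    n = len(labels)
    Mfull = np.empty((n + 1, n + 1))
    Mfull[:n, :n] = M
    Mfull[:n, n] = Mfull[n, :n] = act_mass
    Mfull[n, n] = 1.0
    c = np.concatenate((A @ pmeans, [dist.mean()]))
    return Mfull, c, A, masses


def _solve_weights(Mfull, c):
    try:
        v = np.linalg.solve(Mfull, c)
    except np.linalg.LinAlgError:
        v = np.linalg.lstsq(Mfull, c, rcond=None)[0]
    return v


def evaluate_mse(readout: LinearReadout, dist: StimulusDistribution,
                 R: float | None = None) -> float:
    """Analytic MSE of an arbitrary (not necessarily optimal) readout.

    Computes E = v' M v - 2 c' v + <s^2> from exact activation moments; the
    full second-moment matrix is assembled, so overlapping ON/OFF response
    regions are handled without any special casing.
    """
    R = readout.R if R is None else R
    Mfull, c, _, _ = _normal_system(dist, readout.profile.thresholds,
                                    readout.labels, R)
    v = np.concatenate((readout.weights, [readout.w0]))
    return float(v @ Mfull @ v - 2.0 * c @ v + dist.second_moment())


# --------------------------------------------------------------------------
# noiseless solver (Lloyd-Max)
# --------------------------------------------------------------------------

def solve_noiseless(dist: StimulusDistribution, N: int, m: int,
                    tol: float = 1e-12, max_iter: int = 20000):
    """Noiseless optimal linear readout via the Lloyd-Max alternation.

    Iterates centers of mass <s>_i of the N+1 threshold intervals and
    midpoint thresholds theta_i = (<s>_i + <s>_{i-1})/2 until the MSE is
    stationary; the MSE is non-increasing at every step. The quantizer (and
    hence the MSE) is mixture-independent; the mixture only sets the offset
    w0 (center of mass of the silent interval between the largest OFF and the
    smallest ON threshold) and the weight signs.

    Returns ``(LinearReadout, CodingResult)`` with ``result.mse`` set.
    """
    if N < 1 or not 0 <= m <= N:
        raise ValueError("need N >= 1 and 0 <= m <= N")
    # start from the large-N companding ansatz: it is within O(1/N) of the
    # fixed point everywhere, whereas an equal-mass start leaves tail modes
    # that relax only diffusively (~N^2 sweeps)
    theta = np.asarray(dist.compressed_quantile(np.arange(1, N + 1) / (N + 1.0)),
                       dtype=float)
    s2 = dist.second_moment()
    mse_prev = np.inf
    converged = False
    trace = []
    for it in range(1, max_iter + 1):
        masses, pmeans = _interval_moments(dist, theta)
        with np.errstate(divide="ignore", invalid="ignore"):
            centers = np.where(masses > 0, pmeans / np.where(masses > 0, masses, 1.0), theta[
                np.clip(np.arange(N + 1), 0, N - 1)])
        mse = s2 - float(np.sum(masses * centers ** 2))
        trace.append(mse)
        theta = 0.5 * (centers[1:] + centers[:-1])
        if mse_prev - mse < tol * max(abs(mse), 1e-300) and it > 1:
            converged = True
            break
        mse_prev = mse

    labels = "F" * (N - m) + "N" * m
    masses, pmeans = _interval_moments(dist, theta)
    centers = pmeans / masses
    w0 = centers[N - m]                       # decoded value of the silent interval
    weights = np.empty(N)
    weights[N - m:] = np.diff(centers)[N - m:]            # ON: v_i - v_{i-1}
    weights[: N - m] = -np.diff(centers)[: N - m]         # OFF: v_{i-1} - v_i
    profile = ThresholdProfile(thresholds=theta, positions=np.asarray(dist.cdf(theta)),
                               labels=labels, dist=dist)
    readout = LinearReadout(weights=weights, w0=float(w0), profile=profile, R=np.inf)
    result = CodingResult(mse=mse, diagnostics={
        "iterations": it, "converged": converged, "method": "lloyd_max",
        "mse_trace": trace})
    return readout, result


# --------------------------------------------------------------------------
# noisy solver
# --------------------------------------------------------------------------

def solve_with_noise(dist: StimulusDistribution, N: int, m: int, R: float,
                     tol: float = 1e-12, max_iter: int = 10000):
    """Optimal linear readout with Poisson noise for m ON and N - m OFF cells.

    Alternates the exact linear solve for (w, w0) with the threshold
    stationarity update; thresholds are re-sorted every iteration and the
    update is damped (factor 0.5, engaged automatically) whenever the MSE
    increases — necessary when R < 1 flips the sign of the (1 - 1/R) factor.
    R = inf reproduces the noiseless Lloyd-Max solution.
    """
    if not R > 0:
        raise ValueError("R must be positive")
    if N < 1 or not 0 <= m <= N:
        raise ValueError("need N >= 1 and 0 <= m <= N")

    labels = np.array(list("F" * (N - m) + "N" * m))
    spec = PopulationSpec.mixture(N, m, R if np.isfinite(R) else 1e6)
    theta = optimal_thresholds(spec, dist).thresholds.copy()
    inv_R = 0.0 if np.isinf(R) else 1.0 / R
    s2 = dist.second_moment()

    mse_prev = np.inf
    damping = 1.0
    converged = False
    for it in range(1, max_iter + 1):
        order = np.argsort(theta, kind="stable")
        theta, labels = theta[order], labels[order]
        lab_str = "".join(labels)
        Mfull, c, A, _ = _normal_system(dist, theta, lab_str, R)
        v = _solve_weights(Mfull, c)
        w, w0 = v[:N], v[N]
        mse = s2 - float(c @ v)

        if mse > mse_prev * (1.0 + 1e-13):
            damping = max(0.5 * damping, 1e-3)
        rel_change = abs(mse_prev - mse) / max(abs(mse), 1e-300)
        mse_prev = mse

        # decoded value just above threshold i is the staircase on interval i
        values = A.T @ w + w0                 # length N+1, per interval
        y_above = values[1:]
        on = labels == "N"
        target = np.where(on,
                          y_above - 0.5 * w * (1.0 - inv_R),
                          y_above + 0.5 * w * (1.0 + inv_R))
        step = target - theta
        if rel_change < tol and it > 2 and np.max(np.abs(step)) < 1e-9:
            converged = True
            break
        theta = theta + damping * step

    lab_str = "".join(labels)
    profile = ThresholdProfile(thresholds=theta, positions=np.asarray(dist.cdf(theta)),
                               labels=lab_str, dist=dist)
    readout = LinearReadout(weights=w, w0=float(w0), profile=profile, R=R)
    from .infomax import labels_overlap

    result = CodingResult(mse=mse, diagnostics={
        "iterations": it, "converged": converged, "damping": damping,
        "non_overlapping": not labels_overlap(lab_str), "method": "noisy_fixed_point"})
    return readout, result


def sweep_off_fraction(dist: StimulusDistribution, N: int, R: float,
                       alphas=None) -> MseCurve:
    """MSE of the optimal readout versus OFF fraction alpha.

    Each grid value maps to an integer OFF count N - m = round(alpha * N);
    the reported alpha is derived from that count. The curve is normalized to
    the homogeneous all-ON population (alpha = 0), which is always computed.
    """
    if alphas is None:
        alphas = np.linspace(0.0, 1.0, 11)
    n_off = sorted({int(round(a * N)) for a in np.asarray(alphas, dtype=float)} | {0})
    out_alpha, out_mse, results = [], [], []
    for k in n_off:
        _, res = solve_with_noise(dist, N, N - k, R)
        out_alpha.append(k / N)
        out_mse.append(res.mse)
        results.append(res)
    out_alpha = np.asarray(out_alpha)
    out_mse = np.asarray(out_mse)
    ref = out_mse[out_alpha == 0.0][0]
    normalized = out_mse / ref
    return MseCurve(alphas=out_alpha, mse=out_mse, normalized=normalized,
                    alpha_star=float(out_alpha[np.argmin(out_mse)]), results=results)


# --------------------------------------------------------------------------
# large-N asymptotics (Laplace families)
# --------------------------------------------------------------------------

def _require_laplace(dist) -> AsymmetricLaplace:
    if not isinstance(dist, AsymmetricLaplace):
        raise ValueError("closed-form asymptotics require a Laplace-family "
                         "distribution; use the numerical solver otherwise")
    return dist


def _int_sqrt_1mF(dist: AsymmetricLaplace, a: float, b: float) -> float:
    """integral_a^b sqrt(1 - F(u)) du in closed form."""
    if b <= a:
        return 0.0
    cm, tm = dist.A_minus * dist.tau_minus, dist.tau_minus
    cp, tp = dist.A_plus * dist.tau_plus, dist.tau_plus

    def prim_neg(u):  # antiderivative of sqrt(1 - cm e^{u/tm}), u <= 0
        if np.isinf(u):
            return u  # slope -> 1 as u -> -inf
        t = math.sqrt(max(1.0 - cm * math.exp(u / tm), 0.0))
        return 2.0 * tm * (t - math.atanh(min(t, 1.0 - 1e-16)))

    def prim_pos(u):  # antiderivative of sqrt(cp) e^{-u/2tp}, u >= 0
        if np.isinf(u):
            return 0.0
        return -2.0 * tp * math.sqrt(cp) * math.exp(-u / (2.0 * tp))

    total = 0.0
    if a < 0:
        total += prim_neg(min(b, 0.0)) - prim_neg(a)
    if b > 0:
        total += prim_pos(b) - prim_pos(max(a, 0.0))
    return total


def _int_sqrt_F(dist: AsymmetricLaplace, a: float, b: float) -> float:
    """integral_a^b sqrt(F(u)) du in closed form (mirror of the above)."""
    mirror = AsymmetricLaplace(tau_plus=dist.tau_minus, tau_minus=dist.tau_plus,
                               A_plus=dist.A_minus, A_minus=dist.A_plus)
    return _int_sqrt_1mF(mirror, -b, -a)


def first_threshold_mixed(X: float, dist: StimulusDistribution | None = None) -> float:
    """Common first ON/OFF threshold phi of a noisy mixed population.

    ``X = f_OFF / f_ON`` is the OFF-to-ON fraction ratio (0 < X <= 1). In the
    large-N limit the ON and OFF threshold densities are proportional to
    sqrt(1-F) and sqrt(F) on either side of phi; joint optimality fixes their
    ratio at the junction to F(phi)/(1-F(phi)), giving the scalar equation

        X(phi) = sqrt(F/(1-F)) * [int_{-inf}^{phi} sqrt(F)] / [int_{phi}^{inf} sqrt(1-F)]

    solved here by bracketed root finding. X = 1 gives phi ~ 0 for symmetric
    stimuli; X = 1/4 gives phi = -0.79 for the unit symmetric Laplace.
    """
    if not 0.0 < X <= 1.0:
        raise ValueError("X = f_OFF/f_ON must lie in (0, 1]")
    dist = _require_laplace(dist if dist is not None else AsymmetricLaplace())

    def X_of(phi: float) -> float:
        F = float(dist.cdf(phi))
        z_off = _int_sqrt_F(dist, -np.inf, phi)
        z_on = _int_sqrt_1mF(dist, phi, np.inf)
        return math.sqrt(F / (1.0 - F)) * z_off / z_on

    lo = float(dist.quantile(1e-12))
    hi = float(dist.quantile(1.0 - 1e-12))
    flo, fhi = X_of(lo) - X, X_of(hi) - X
    if flo * fhi > 0:
        raise ValueError(f"no root of X(phi) = {X} in [{lo:.3g}, {hi:.3g}]; "
                         f"X(phi) ranges over [{flo + X:.3g}, {fhi + X:.3g}]")
    return float(optimize.brentq(lambda p: X_of(p) - X, lo, hi, xtol=1e-12))


@dataclass(frozen=True)
class AsymptoticThresholds:
    """Callable large-N threshold function theta(x), x = i/N in (0, 1)."""

    func: object
    phi: float | None = None
    description: str = ""

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if np.any((x <= 0) | (x >= 1)):
            raise ValueError("threshold index x must lie strictly in (0, 1)")
        return np.vectorize(self.func)(x)[()]


def _first_threshold_homogeneous(dist: AsymmetricLaplace, N: int, R: float) -> float:
    """First-threshold anchor theta_1 ~ tau- log(log(RN A- tau-)/(RN A- tau-^2))."""
    am, tm = dist.A_minus, dist.tau_minus
    arg = R * N * am * tm
    if arg <= math.e:
        raise ValueError("asymptotic first threshold requires RN >> 1")
    return tm * math.log(math.log(arg) / (arg * tm))


def asymptotic_thresholds(dist: StimulusDistribution, N: int, m: int,
                          R: float = np.inf) -> AsymptoticThresholds:
    """Closed/semi-closed-form large-N threshold function theta(x).

    Noiseless (R = inf): the one-third-power companding law — theta(x) is the
    compressed quantile, e.g. 3 log(2x) for x <= 1/2 on the unit symmetric
    Laplace, independent of the ON/OFF mixture.

    Noisy homogeneous: threshold density ~ sqrt(1 - F), a linear bulk and a
    logarithmic tail, anchored at the first threshold theta_1(RN).

    Noisy mixed: OFF branch theta = phi + 2 tau- log(x / f_OFF) (closed form),
    ON branch by inverting x(theta) = f_ON * int_phi^theta sqrt(1-F)/Z, both
    anchored at phi = first_threshold_mixed(f_OFF/f_ON).
    """
    if np.isinf(R):
        return AsymptoticThresholds(
            func=lambda x: float(dist.compressed_quantile(x)),
            description="noiseless 1/3-power companding")

    dist = _require_laplace(dist)
    if m in (0, N):
        sign = 1.0 if m == N else -1.0
        work = dist if m == N else AsymmetricLaplace(
            tau_plus=dist.tau_minus, tau_minus=dist.tau_plus,
            A_plus=dist.A_minus, A_minus=dist.A_plus)
        th1 = _first_threshold_homogeneous(work, N, R)
        Z = _int_sqrt_1mF(work, th1, np.inf)

        def theta_hom(x: float) -> float:
            xx = x if m == N else 1.0 - x
            return sign * optimize.brentq(
                lambda t: _int_sqrt_1mF(work, th1, t) / Z - xx,
                th1, work.quantile(1.0 - 1e-14) + 1.0, xtol=1e-11)

        return AsymptoticThresholds(func=theta_hom, phi=sign * th1,
                                    description="noisy homogeneous sqrt(1-F) law")

    f_on, f_off = m / N, (N - m) / N
    phi = first_threshold_mixed(f_off / f_on, dist)
    z_on = _int_sqrt_1mF(dist, phi, np.inf)
    tm = dist.tau_minus

    def theta_mixed(x: float) -> float:
        if x <= f_off:  # OFF block, ascending from the deepest threshold
            return phi + 2.0 * tm * math.log(x / f_off)
        xon = (x - f_off) / f_on
        return optimize.brentq(
            lambda t: _int_sqrt_1mF(dist, phi, t) / z_on - xon,
            phi, dist.quantile(1.0 - 1e-14) + 1.0, xtol=1e-11)

    return AsymptoticThresholds(func=theta_mixed, phi=phi,
                                description="noisy mixed sqrt-companding law")
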