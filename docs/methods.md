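# Methods

## Model

A scalar stimulus `s ~ p(s)` is encoded by `N` neurons with binary rate
functions: neuron `i` fires Poisson spikes with expected count
`R = ν_max·T` during a coding window whenever it is *active* — `s ≥ θ_i` for
an ON cell, `s < θ_i` for an OFF cell (the half-open convention makes exactly
one regime hold at `s = θ_i`, a measure-zero choice fixed for bit
reproducibility) — and is exactly silent otherwise. Spiking is conditionally
independent across neurons given `s`. Because the rate takes only the values
`0` and `ν_max`, all nonzero counts can be lumped into a single "spike" state
without changing the stimulus information; each neuron is then a binary
channel with `p(0|active) = q = e^{-R}`. `q → 0` is the noiseless limit,
`q → 1` the high-noise limit. The simulator nevertheless keeps raw Poisson
counts, because the linear decoder weights them by `1/R`.

Thresholds are described interchangeably in stimulus space (`θ_i`) and in
cumulative space (`x_i = F(θ_i)`, `F` the stimulus cdf); label strings such
as `FFNN` give the OFF/ON identity along the sorted thresholds, and "overlap"
means some ON threshold lies below some OFF threshold.

## Information machinery

`pattern_information` evaluates `I(s; n)` exactly: within each of the `N+1`
intervals cut by the sorted thresholds the active set is fixed, so the
conditional response entropy is `|active| · h(1-q)` per interval (`h` the
binary entropy) and only the marginal pattern distribution requires
enumerating the `2^N` binary patterns (refused above `N = 20`; the
Monte-Carlo estimator covers larger populations). `information_recursive`
evaluates the equivalent nested form for homogeneous populations, in which
each observed silence reweights the remaining response intervals by the
posterior; the two agree to ~1e-12 on random inputs, which is the main
internal consistency check of the information code.

Closed forms: noise entropy `H_q`, the optimized information
`I = log(1 + N e^{-H_q})`, and the optimal partition — interior intervals
`p = 1/(N + e^{H_q})`, edge intervals `p/(1-q)`, silent interval
`1 - (N-2)p - 2p_edge` (mixed) or `1 - (N-1)p - p_edge` (homogeneous).
Cumulative positions are the running sums; stimulus thresholds follow by
quantile mapping. Internally everything is in nats; results also carry bits.

The mean spike count per neuron is computed operationally as
`(R/N) Σ_i P(active_i)`. The closed partition form
`R[p_edge + p(m(m-1) + (N-m)(N-m-1))/(2N)]` follows, and reproduces the
anchors `r(α) = (R/2)(α² + (1-α)²)` in the large-population regime and
`r = R/e` in the high-noise regime.

`optimize_thresholds` maximizes the exact information over the
`(N+1)`-simplex of interval masses through a softmax reparameterization
(L-BFGS-B with numerical gradients, a configurable number of random Dirichlet
restarts plus the equal-mass start, and a Nelder-Mead polish). Label strings
are handled by enumeration — all `2^N` strings in `allow_overlap`, the
strings containing an ON-below-OFF pair in `enforce_overlap` — because the
information landscape is multimodal across labelings but smooth within one.
Ties among thresholds (zero-width intervals) need no special casing: the
information is continuous there. `q = 0` takes an exact deterministic branch.
Enumeration is limited to `N ≤ 10`.

## Optimal linear readout

The decoder is `y = (1/R) Σ_i w_i n_i + w_0` (step responses directly for
`R = ∞`). For fixed thresholds the MSE is an exact quadratic in `(w, w_0)`
built from activation moments — `⟨a_i⟩`, `⟨a_i a_j⟩`, `⟨s a_i⟩` and a
Poisson variance term `⟨a_i⟩/R` on the diagonal — assembled from closed-form
partial first moments for the Laplace, Gaussian, uniform and power-law
families (adaptive quadrature, absolute tolerance 1e-10, otherwise). The
solver always assembles the full `(N+1)×(N+1)` second-moment system
including `w_0` and the ON-OFF cross moments: at non-overlapping solutions
the cross terms vanish identically, recovering the block structure that the
theory assumes, while transiently overlapping iterates remain well defined.

**Noiseless case.** The stationarity conditions are the Lloyd-Max
alternation: interval centers of mass as decoded values, midpoint
thresholds. The MSE is non-increasing every sweep (asserted in tests). The
quantizer is mixture-independent; the mixture only sets `w_0` (the decoded
value of the silent interval between the largest OFF and smallest ON
threshold) and the weight signs. The solver starts from the large-N
companding ansatz `θ_i = compressed_quantile(i/(N+1))` rather than the
equal-mass infomax ansatz: both reach the same fixed point (verified at
N = 512: thresholds within 0.011, MSE within 5e-7 relative), but equal-mass
tail modes relax only diffusively (~N² sweeps versus ~2·10⁴). Convergence:
relative MSE change below 1e-12 (configurable), cap 2·10⁴ sweeps.

**Noisy case.** Differentiating the MSE with respect to a threshold gives

    θ_i = ŷ_above - (w_i/2)(1 - 1/R)   (ON)
    θ_i = ŷ_above + (w_i/2)(1 + 1/R)   (OFF)

with `ŷ_above` the decoded value just above the threshold; both reduce to the
Lloyd midpoint rule at `R = ∞`. The solver alternates the exact linear solve
with this update, re-sorting thresholds (labels attached to neurons) each
iteration, starting from the infomax thresholds. When `R < 1` the
`(1 - 1/R)` factor changes sign and the plain iteration can overshoot; a
damping factor of 0.5 engages automatically whenever the MSE increases.
Convergence requires both a relative MSE change below 1e-12 and threshold
movement below 1e-9; non-convergence is flagged in the diagnostics, never
raised. Singular moment systems (duplicate thresholds) fall back to a
least-squares solve. Final solutions are checked to be non-overlapping.

`sweep_off_fraction` maps each requested OFF fraction to an integer OFF
count `round(α·N)` and reports the count-derived α; the curve is normalized
to the always-computed all-ON population.

**Large-N asymptotics (Laplace families).** Expanding the stationarity
conditions to leading order in the interval widths, the noise term dominates
the quantization term and yields threshold densities

    n_ON(θ) ∝ sqrt(1 - F(θ)),     n_OFF(θ) ∝ sqrt(F(θ)),

i.e. a square-root companding law: for Laplace stimuli a linear bulk with
logarithmic tails (`θ ~ -2τ₊ log(1-x)` for the upper ON tail, and mirrored
closed form `θ = φ + 2τ₋ log(x/f_OFF)` for the OFF branch). The homogeneous
first threshold is anchored at
`θ₁ ≈ τ₋ log(log(RN A₋τ₋)/(RN A₋τ₋²))`, which follows from balancing the
uncoded-tail bias against the accumulated in-interval decoding bias; at
`(N, R) = (100, 1)` it predicts -2.55 against -2.59 from the full solver.
For mixed populations, joint optimality across the silent interval fixes the
density ratio at the common first threshold φ to
`n_OFF(φ)/n_ON(φ) = F(φ)/(1 - F(φ))`, giving the scalar junction equation

    X(φ) = sqrt(F/(1-F)) · ∫_{-∞}^{φ} sqrt(F) du / ∫_{φ}^{∞} sqrt(1-F) du

for the OFF-to-ON ratio `X = f_OFF/f_ON`, solved by bracketed bisection.
For the unit symmetric Laplace, `X = 1` gives `φ = 0` and `X = 1/4` gives
`φ = -0.79`; at `(N, R) = (100, 1)` with 20% OFF cells the numerical first
ON and OFF thresholds (-0.71, -0.83) bracket this root. All the sqrt-law
integrals are closed form (`2τ(t - atanh t)` primitives); the asymptotic
functions are restricted to Laplace families and validated against the
numerical solver in the tests rather than used by it.

## Simulator and Monte-Carlo oracles

`simulate_responses` draws Poisson(R) counts where the step function is
active; all randomness flows through a seeded generator, so outputs are
bit-reproducible. `mc_mutual_information` bins stimuli by threshold interval
(a sufficient statistic for the piecewise-constant rates), binarizes counts,
and computes the plug-in MI of the joint table with a grouped leave-one-out
jackknife standard error. `mc_mse` decodes simulated counts with the `1/R`
convention and reports the mean squared residual with its standard error of
the mean. Both agree with the analytic values within ~3 SE across randomized
configurations (the test allows a small absolute slack on top of 3 SE for
the plug-in MI bias, which is O(cells/n) at the trial counts used).

## Reverse inference

`fit_threshold_powerlaw` reproduces the plot-based procedure for pooled
threshold data: ordinary least squares of the log empirical survival of
inverse thresholds against log(1/θ). The slope is `-λ`; the implied
threshold-density exponent is `λ - 1` (the single documented place where the
cumulative-to-density conversion happens). ECDF points with survival below
1% are excluded — they sit in the truncation-dominated extreme tail of the
survival plot. A Hill maximum-likelihood exponent is attached as a
cross-check; the OLS value is the reported one, on purpose: the goal is the
measured procedure, not a better estimator. Unbiased recovery requires
several decades between the lower and upper cutoffs; at a ~4.6-decade range
the plot fit retains a bias of ≈0.03 in the slope from the curvature the
finite range induces, which is a property of the procedure, not of the
implementation (the tests calibrate recovery on a >7-decade synthetic set
and assert the biased value only loosely on the narrow-range set).
`infer_stimulus_distribution` then maps the threshold-density exponent to
the stimulus-density exponent: unchanged under infomax (thresholds equalize
the cdf), tripled under the linear-MSE criterion (thresholds equalize the
cdf of `p^{1/3}`). Proportionality constants are never reported.

## Synthetic data

`generate_power_law_thresholds` draws i.i.d. thresholds by inverse-cdf
sampling from a truncated power law; with exponent -0.58, upper cutoff
4.22e4 and a small lower cutoff it emulates a pooled set of ORN activation
thresholds (EC50 values pooled across odorants and concentrations). What it
does *not* emulate: measurement error in individual EC50 estimates,
inter-odorant structure (the pooling assumes thresholds for one odor are a
shuffled version of the pool), or any deviation from an exact power law —
so passing round-trip tests shows the inference pipeline is self-consistent,
not that real ORN data follow the law. Stimulus samples for the Monte-Carlo
oracles come from the parametric families by inverse-cdf sampling and
inherit the same caveat: conditional independence and exact binary rates are
assumed, not tested against biology.

## Parameters that matter

| parameter | meaning | default / units |
|---|---|---|
| `R` | expected spikes per neuron per coding window, `ν_max·T` | dimensionless count; `∞` = noiseless |
| `q` | `e^{-R}`, probability an active neuron stays silent | derived |
| `labels` | ON/OFF string along sorted thresholds | — |
| `τ₊, τ₋` | Laplace tail scales; `τ₋/τ₊` is the negative bias | stimulus units, default 1 |
| `n_restarts` | optimizer restarts per label string | 12 (6 suffices at N=5) |
| `tol` | solver convergence on information / relative MSE | 1e-10 / 1e-12 |

## Known limitations

Binary (two-level) rate functions only; no input noise before the
nonlinearity; no spontaneous firing; conditionally independent neurons.
Pattern enumeration is exponential in `N` (capped at 20); label enumeration
at `N ≤ 10`. Non-overlap of the free optimum is asserted only where it has
been checked numerically (up to `N = 10`), matching the state of the theory.
The asymptotic threshold laws are leading-order in `1/N` and assume
`RN ≫ 1`; their closed forms exist only for Laplace families. Problem sizes
in the test and acceptance suites (N up to 512 noiseless, 100 noisy, 10⁵
Monte-Carlo trials) were chosen as the smallest sizes at which the asymptotic
statements under test are clearly resolved.
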