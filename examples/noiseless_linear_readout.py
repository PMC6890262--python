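"""Noiseless optimal linear readout: Lloyd-Max structure and companding.

Solves the minimum-MSE linear decoder for a population of deterministic
binary neurons, verifies the 1/N^2 error scaling, and shows that the large-N
thresholds equalize the area under p(s)^{1/3} — three times as spread out in
the tails as the information-maximizing (histogram-equalizing) thresholds.
"""

import math

import numpy as np

from onoffcoding import Laplace, Uniform, solve_noiseless

# 1 neuron on uniform[0,1]: the classic two-level quantizer
readout, result = solve_noiseless(Uniform(0.0, 1.0), N=1, m=1)
print("uniform[0,1], N=1:"
      f"  theta = {readout.profile.thresholds[0]:.3f},"
      f"  w0 = {readout.w0:.3f}, w1 = {readout.weights[0]:.3f},"
      f"  MSE = {result.mse:.5f} (= 1/48)")

lap = Laplace()
print("\nunit Laplace, MSE versus population size (slope ~ -2):")
for N in (16, 32, 64):
    mse = solve_noiseless(lap, N, N)[1].mse
    print(f"  N = {N:3d}: MSE = {mse:.6f},  N^2 * MSE = {N * N * mse:.3f}")

N = 64
readout, _ = solve_noiseless(lap, N, N)
x = np.array([0.1, 0.25, 0.5])
idx = (x * N).astype(int)
print("\nthresholds versus the 3 log(2x) companding law (central indices):")
for i, xi in zip(idx, x):
    print(f"  x = {xi:.2f}: numeric {readout.profile.thresholds[i - 1]:+.3f},"
          f"  3 log(2x) = {3 * math.log(2 * xi):+.3f}")
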