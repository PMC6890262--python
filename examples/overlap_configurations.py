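"""Numerically optimized threshold configurations with and without overlap.

Enumerates every ON/OFF label string for a small population, maximizes the
exact mutual information over thresholds for each, and compares the free
optimum (which never interleaves ON below OFF) against the best configuration
when overlap is enforced.
"""

from onoffcoding import PopulationSpec, max_information, optimize_thresholds

N, R = 3, 1.0
spec = PopulationSpec.mixture(N, N, R)

_, allow = optimize_thresholds(spec, "allow_overlap", seed=0)
_, enforce = optimize_thresholds(spec, "enforce_overlap", seed=0)

print(f"N = {N}, R = {R}")
print(f"closed form          : {max_information(N, R=R).bits:.3f} bits")
print(f"allow overlap        : {allow.bits:.3f} bits  "
      f"configs {allow.diagnostics['configurations']}")
print(f"enforce overlap      : {enforce.bits:.3f} bits  "
      f"configs {enforce.diagnostics['configurations']}")
print("\nThe free optimum is reached only by non-overlapping label strings;")
print("forcing an ON threshold below an OFF threshold costs information,")
print("and the best overlapping codes interleave a single ON/OFF pair.")
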