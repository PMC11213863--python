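"""A-priori sample-size computation for the behavioural regressions.

Fixed-effects multiple-regression F test, three predictors (sensory
condition, stimulus coherence, age), moderate effect size f^2 = 0.10,
alpha = .05, target power .95. The noncentrality convention is
lambda = f^2 * N.
"""

from msddm import PowerSpec, required_sample_size, power_at

spec = PowerSpec(n_predictors=3, f2=0.10, alpha=0.05, power=0.95)
n = required_sample_size(spec)
print(f"required minimum sample size: N = {n}")
print(f"power at N={n}:   {power_at(spec, n):.4f}")
print(f"power at N={n - 1}: {power_at(spec, n - 1):.4f}  (just misses)")

print("\npower curve:")
for N in (50, 100, 150, 176, 212):
    print(f"  N={N:3d}: power {power_at(spec, N):.3f}")
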