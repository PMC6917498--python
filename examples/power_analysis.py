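"""Power analysis for the unbalanced GeoPref-vs-TD comparison (n=16 vs 55).

Finds the minimum detectable standardized effect at 80% power and alpha=0.05
with the noncentral-t oracle, then checks it empirically with 100,000
simulated experiments.
"""

from geoconn import analytic_power, empirical_power, min_detectable_d

n1, n2, alpha = 16, 55, 0.05

d = min_detectable_d(n1, n2, alpha=alpha, target_power=0.80)
print(f"minimum detectable effect at 80% power: d = {d:.5f}")
print(f"analytic power at that d: {analytic_power(d, n1, n2, alpha):.4f}")

sim = empirical_power(d, n1, n2, alpha=alpha, n_experiments=100000, seed=1)
print(
    f"empirical power over {sim.n_experiments:,} simulated experiments: "
    f"{sim.power_hat:.4f} (binomial SE {sim.se_hat:.4f})"
)
print(
    "interpretation: with 16 GeoPref vs 55 TD subjects, only standardized "
    f"group differences of about d >= {d:.2f} are reliably detectable; the "
    "simulation should land within a few SEs of 0.80."
)
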