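"""Analytic MR power via the non-centrality parameter.

Binary outcome: NCP = n * r2 * ln(OR)^2 * K * (1 - K), with OR the causal
odds ratio per SD of exposure and K the case fraction. Continuous outcome:
NCP = n * r2 * beta^2 for a standardized effect beta.
"""

from curvemr import mr_power_binary, mr_power_continuous

print("binary outcome (diabetes), r2 = 4.9%, K = 0.242:")
for or_sd in (0.9, 0.8, 0.7, 0.6, 0.5):
    spec = mr_power_binary(4876, 0.049, or_sd, 0.242)
    print(f"  OR {or_sd:.1f} per SD -> power {spec.power:.3f}")

print("\ncontinuous outcome (fasting glucose), r2 = 4.9%:")
for beta in (0.05, 0.10, 0.15, 0.20):
    spec = mr_power_continuous(4876, 0.049, beta)
    print(f"  beta {beta:.2f} SD/SD -> power {spec.power:.3f}")

print("\nsample size needed for 80% power at OR 0.8 per SD:")
for n in (2000, 5000, 10_000, 20_000):
    spec = mr_power_binary(n, 0.049, 0.8, 0.242)
    print(f"  n = {n:6d} -> power {spec.power:.3f}")
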