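"""Estimate an unknown catalyst's nucleophilicity from calibration yields.

When a candidate base is missing from the reactivity-parameter databases,
its N can be back-estimated from a small batch screen: fit yield = a + b*N
on the catalysts with known N, then invert the line at the new catalyst's
observed yield.
"""

from reactbo import Catalyst, estimate_missing_nucleophilicity
from reactbo.descriptors import with_estimated_nucleophilicity

# calibration screen at one fixed set of conditions (synthetic yields that
# follow the near-linear yield-N trend of nucleophile-catalysed amidation)
known = [
    (Catalyst("pyridine-like", 12.9, molar_mass=79.1, cost_per_g=0.5, n_source="fixture"), 0.08),
    (Catalyst("guanidine-A", 20.8, molar_mass=115.2, cost_per_g=3.5, n_source="fixture"), 0.21),
    (Catalyst("amidine-B", 23.9, molar_mass=152.2, cost_per_g=8.0, n_source="fixture"), 0.33),
    (Catalyst("bicyclic-G", 26.0, molar_mass=139.2, cost_per_g=40.0, n_source="fixture"), 0.45),
]

unknown = Catalyst("new-base", 0.0, molar_mass=131.2, cost_per_g=5.0, n_source="fixture")
observed_yield = 0.30

n_hat = estimate_missing_nucleophilicity(known, observed_yield)
est = with_estimated_nucleophilicity(unknown, known, observed_yield)

print(f"estimated N for {unknown.name}: {n_hat:.2f} (source: {est.n_source})")
# The estimate places the new base on the same N scale as the calibration
# set, so it can join a chemistry-encoded optimization campaign directly.
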