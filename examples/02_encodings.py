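"""Three ways to hand a categorical catalyst choice to a continuous optimizer.

One-hot adds one dimension per catalyst; label encoding uses one dimension
with an arbitrary (seeded-random) order; chemistry encoding uses one
dimension whose coordinates are min-max normalized nucleophilicities, so
distances mean something chemically.
"""

import numpy as np

from reactbo import make_benchmark, make_encoder

bm = make_benchmark("amidation_sim")
space, cats = bm.space, bm.catalyst_set
print("catalysts:", dict(zip(cats.names, cats.nucleophilicities)))

for strategy in ("one_hot", "label", "chemistry"):
    enc = make_encoder(strategy, cats, seed=7)
    print(f"\n{strategy}: optimizer dimensionality {enc.dimensionality(space)}")
    print("  label coordinates per catalyst:")
    for name, vec in zip(cats.names, enc.label_values):
        print(f"    {name}: {np.round(vec, 3)}")

# Euclidean snapping: a continuous suggestion lands on the nearest catalyst
enc = make_encoder("chemistry", cats)
for suggestion in (0.05, 0.30, 0.95):
    snapped = cats[enc.snap(np.array([suggestion]))]
    print(f"suggestion {suggestion:.2f} -> {snapped.name} (N={snapped.nucleophilicity})")
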