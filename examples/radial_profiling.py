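"""Center-to-periphery radial profiling of simulated oocytes.

Simulates two groups of cells — a 'ring' group with signal concentrated
at normalized radius 0.5 and a uniform control — detects each nuclear
center from the DAPI channel, bins signal intensity by normalized
radius, aggregates cells within replicates, normalizes to the control,
and tests each bin (two-way ANOVA, Bonferroni).
"""

import numpy as np

from wormepi.radial import (
    aggregate_profiles,
    compare_profile_groups,
    detect_nucleus_center,
    normalize_to_control,
    radial_profile,
)
from wormepi.synthetic import ImageSpec, gen_image

profiles = []
i = 0
for cond, pattern in (("ring", "ring"), ("control", "uniform")):
    for rep in ("1", "2"):
        for _ in range(5):
            img, roi, truth = gen_image(
                ImageSpec(seed=100 + i, pattern=pattern, ring_r0=0.5),
                cell_id=f"{cond}_{rep}_{i}", condition=cond, replicate=rep,
            )
            center = detect_nucleus_center(img, roi)
            profiles.append(radial_profile(img, roi, center, n_bins=20))
            i += 1

curves = aggregate_profiles(profiles)
ring = curves[curves["condition"] == "ring"]
ctrl = curves[curves["condition"] == "control"]
rel = normalize_to_control(ring, ctrl)
peak = rel.loc[rel["relative"].idxmax()]
print(f"cells profiled: {len(profiles)} (10 per group, 2 replicates each)")
print(f"relative curve peaks at r = {peak['r']:.3f} "
      f"(planted ring at r0 = 0.5), fold = {peak['relative']:.2f}")

omnibus, per_bin = compare_profile_groups(profiles)
sig = per_bin[per_bin["significant"]]
print(f"bins with Bonferroni-adjusted p < 0.05: {sorted(sig['bin'])}")
print(f"(bin width 0.05; the planted ring spans bins ~8-11)")
print()
print(np.round(rel[["r", "relative"]].to_numpy(), 3))

# The control-normalized curve is ~1 away from the ring and rises where
# the signal was planted; per-bin flags concentrate in those bins.
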