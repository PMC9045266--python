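"""The evaluation statistics on a toy profile.

Shows L2 distance (both conventions), Bray-Curtis dissimilarity,
rarefaction of species richness and taxonomic entropy on small hand-made
inputs where the right answers are easy to see.
"""

import math

from operontax import (
    AbundanceVector,
    bray_curtis,
    l2_distance,
    rarefaction_curve,
    taxonomic_entropy,
)

est = AbundanceVector.from_mapping({"A": 60.0, "B": 40.0})
exp = AbundanceVector.from_mapping({"A": 50.0, "B": 50.0})
print(f"L2 (sum of squares):      {l2_distance(est, exp, mode='sum_sq'):.1f}")
print(f"L2 (root, default):       {l2_distance(est, exp):.3f}")
# (60-50)^2 + (40-50)^2 = 200; the root convention gives sqrt(200) = 14.142.

print(f"Bray-Curtis, identical:   {bray_curtis(est, est):.3f}")
print(f"Bray-Curtis, est vs exp:  {bray_curtis(est, exp):.3f}")
# sum|p-q| / sum(p+q) = 20/200 = 0.1.

labels = ["a"] * 50 + ["b"] * 30 + ["c"] * 20
print("rarefaction (depth -> mean richness, 95% band):")
for depth, mean, (lo, hi) in rarefaction_curve(labels, [1, 5, 20, 100], n_reps=200, seed=0):
    print(f"  {depth:4d} -> {mean:.2f}  [{lo:.1f}, {hi:.1f}]")
# At depth 1 exactly one species is seen; at full depth all 3, always.

print(f"entropy of those labels:  {taxonomic_entropy(labels):.3f} nats")
print(f"entropy of 3 even labels: {taxonomic_entropy(['x', 'y', 'z']):.3f} = ln 3 = {math.log(3):.3f}")
# Shannon entropy rewards both richness (more taxa) and evenness.
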