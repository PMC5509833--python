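"""Score EQ-5D-3L profiles with a tariff and transform bounded outcomes.

An EQ-5D-3L profile is five levels in {1,2,3}; a country tariff maps it to
a utility index with 1.0 = perfect health.  Beta regression needs outcomes
strictly inside (0, 1), so VAS is divided by 100 and "shrunk", and non-one
index values are min-max normalised before the same shrink.
"""

import numpy as np

from qolnorm import (
    TransformSpec,
    all_profiles,
    example_tariff,
    score_eq5d,
    shrink_transform,
    transform_eq5d,
)

tariff = example_tariff()  # synthetic Belgian-like value set shipped for demos

print("perfect health (1,1,1,1,1)    ->", score_eq5d((1, 1, 1, 1, 1), tariff))
print("some walking problems 21111   ->", round(score_eq5d((2, 1, 1, 1, 1), tariff), 3))
print("worst profile (3,3,3,3,3)     ->", round(score_eq5d((3, 3, 3, 3, 3), tariff), 3))
values = [score_eq5d(p, tariff) for p in all_profiles()]
print(f"range over all 243 profiles   -> [{min(values):.3f}, {max(values):.3f}]")
# the index spans [-0.074, 1]: states worse than death get a negative utility

spec = TransformSpec(n=1774, min_index=-0.074, max_index=0.817)
print("\nVAS 0/50/100 shrunk with N=1774 ->",
      np.round(shrink_transform(np.array([0.0, 50.0, 100.0]) / 100, 1774), 5))
index = np.array([1.0, 0.817, 0.5, -0.074])
z, is_one = transform_eq5d(index, spec)
print("EQ-5D", index, "->", np.round(z, 5), "(exact 1 keeps its point mass)")
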