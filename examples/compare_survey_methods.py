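"""Compare leaf-count distributions seen by trawling vs ROV imaging.

Trawl nets undersample small colonies and video analysts miss tiny terminal
leaves, so the two survey methods see shifted distributions. The comparison
reports the four bias-corrected moments of each sample and the relative
mean/skewness differences with the ROV sample as reference.
"""

import numpy as np

from seapen import (
    GeneratorConfig,
    apply_trawl_selectivity,
    compare_distributions,
    generate_colonies,
    simulate_rov_counts,
)

cfg = GeneratorConfig()
rng = np.random.default_rng(99)
population = generate_colonies(cfg, 4000, rng)

catch = apply_trawl_selectivity(population, cfg, rng)[:168]
rov = simulate_rov_counts(population[:207], cfg, rng)

trawl_counts = [max(c.leaves_left, c.leaves_right) for c in catch]
rov_counts = [o.leaf_count for o in rov]
comparison = compare_distributions(trawl_counts, rov_counts)

for name, s in (("trawl", comparison.summary_a), ("ROV", comparison.summary_b)):
    print(f"{name:>5}: m={s.m:<4d} mean={s.mean:6.2f} sd={s.sd_corrected:5.2f} "
          f"skew={s.skewness:6.2f} kurt={s.kurtosis:5.2f}")
print(f"relative mean difference     : {comparison.relative_mean_diff:.1%}")
print(f"relative skewness difference : {comparison.relative_skewness_diff:.1%}")
# The trawl mean sits ~10% above the ROV mean: selectivity removes small
# colonies from the catch while edge misses shrink the video counts.
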