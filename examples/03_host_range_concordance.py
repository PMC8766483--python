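"""Host-range concordance within phage species versus genera.

Generates phages in a two-level taxonomy where members of a species share a
template kill vector (small bit-flip noise) while species within a genus
kill disjoint hosts, then compares concordance (1 - scaled host range
divergence D_h) between the two taxonomic levels.
"""

import numpy as np

from phagenet import (
    HostRangeGenConfig,
    compare_levels,
    generate_host_range_groups,
    group_concordance,
)

cfg = HostRangeGenConfig(
    taxonomy={
        "G1": {"S1": 4, "S2": 3}, "G2": {"S3": 4, "S4": 3},
        "G3": {"S5": 3, "S6": 3}, "G4": {"S7": 3, "S8": 3},
    },
    n_hosts=80, noise=0.01, seed=11,
)
m, annotations = generate_host_range_groups(cfg)

species = group_concordance(m, annotations, level="species")
genus = group_concordance(m, annotations, level="genus")
for res in species + genus:
    print(f"{res.level:7s} {res.group_id}: n={res.n} concordance={res.concordance:.3f}")

sp = [r.concordance for r in species]
ge = [r.concordance for r in genus]
test = compare_levels(sp, ge)
print(f"\nmean concordance: species {np.mean(sp):.3f}, genus {np.mean(ge):.3f}")
print(f"Welch's t-test (two-sided): t={test.statistic:.2f} p={test.pvalue:.2e}")
print()
print("High species-level and low genus-level concordance with a small p-value")
print("reproduces the pattern that killing overlap tracks species membership.")
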