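"""Antibiotic-driven alpha-diversity depression and post-FMT recovery.

In the simulated trial the two antibiotic-pretreated arms have half their
baseline taxa depleted tenfold during treatment. Shannon diversity (nats)
drops at the during-antibiotics timepoint and recovers by week 10.
"""

from fmtengraft import SimConfig, filter_otus, simulate_trial
from fmtengraft.diversity import (compare_diversity, diversity_table,
                                  series_from_table)

table, meta, _, _ = simulate_trial(SimConfig(seed=42))
div = diversity_table(filter_otus(table), meta)
series = series_from_table(div)

for arm in ("FMT", "R-FMT", "CM-FMT", "placebo"):
    arm_series = [s for s in series if s.arm == arm]
    for a, b in (("baseline", "during_abx"), ("baseline", "week10")):
        rep = compare_diversity(arm_series, a, b)
        print(f"{arm:8s} {a} -> {b}: mean dH={rep['mean_difference']:+.3f}, "
              f"paired-t p={rep['p']:.4f} (n={rep['n_pairs']})")

# Negative mean dH with small p in the antibiotic arms during treatment;
# near-zero dH (no significant change) everywhere at week 10.
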