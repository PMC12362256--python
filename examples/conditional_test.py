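"""Conditional association test on a simulated spiked dataset.

Builds a two-group Dirichlet-multinomial community in which one family
receives extra Poisson reads in group 1, then asks — for the spiked family
and for an untouched control family — whether permuting that family's leaf
counts reduces the weighted-UniFrac PERMANOVA R^2.
"""

import numpy as np

from catmicro import (
    SimulationConfig,
    cat_test_many,
    make_base_composition,
    make_synthetic_tree,
    simulate_counts,
)
from catmicro.simulate import group_outcome, pick_family_by_share

phylo, taxonomy = make_synthetic_tree(m=200, seed=10)
base, skew = make_base_composition(200, seed=10, tax_tree=taxonomy)
spiked = pick_family_by_share(taxonomy, base, target_share=0.03)
control = pick_family_by_share(taxonomy, base, target_share=0.10)

config = SimulationConfig(
    base_proportions=base, n_per_group=31, depth=48_765, theta=62.0,
    spiked_taxon=spiked, lambda_=70.0, seed=11,
)
table, groups = simulate_counts(config, taxonomy)

results = cat_test_many(
    table, taxonomy, group_outcome(groups), [spiked, control],
    seed=12, metrics=("wunifrac",), phylo_tree=phylo, b=199,
)
print(results[["taxon", "n_leaves", "r2_original", "r2_perm_mean", "p_value"]].to_string(index=False))
print()
print(
    "The spiked family's counts carry the group difference: permuting them\n"
    "drops R^2 (r2_perm_mean << r2_original) and the empirical p-value is\n"
    "small. The control family is exchangeable across samples, so its\n"
    "permuted R^2 values straddle the original and the p-value is large."
)
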