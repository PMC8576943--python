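"""Exact maximum-parsimony tree over tumor regions.

Each variant is a binary presence/absence character; the matched normal
is the all-zero outgroup.  Branch-and-bound finds every minimum-length
topology; branch lengths count the variants assigned to each branch.
"""

import pandas as pd

from multiregion import phylo, simdata, variants

config = simdata.SimConfig(
    n_regions=5, n_clonal=25,
    tree_splits=[(0, 0.5, (0, 1)), (0, 0.4, (2, 3, 4)), (2, 0.25, (4,))],
    n_private=20, depth_mean=300.0, seed=19,
)
_, _, table = simdata.simulate_tumor(config)
table = variants.recover_variants(variants.apply_filters(table))

matrix = phylo.build_matrix(table)
print(f"{len(matrix.variant_patterns)} variants collapse to "
      f"{len(matrix.patterns)} unique presence patterns")

trees = phylo.max_parsimony(matrix)
best = trees[0]
print(f"parsimony score {best.score:.0f}, {len(trees)} co-optimal topology(ies)")
print("newick (branch lengths = assigned variant counts):")
print(" ", best.newick())
print(f"unresolved (homoplasious) variants: {len(best.unresolved)}")
# Regions sharing a subclone cluster together; the trunk to the normal
# carries the truncal mutations.

# CCF ordering constraints between clone clusters
ccf = pd.DataFrame(
    {"R1": [1.0, 0.5, 0.0], "R2": [1.0, 0.5, 0.0], "R3": [1.0, 0.0, 0.4]},
    index=["trunk", "cloneA", "cloneB"],
)
rel = phylo.ccf_order_check(ccf)
print("admissible ancestral pairs:", rel["ancestral"])
print("crossing (no lineage order):", rel["crossing"])
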