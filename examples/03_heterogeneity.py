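"""Intratumoral heterogeneity: sharing spectrum and miss rates.

How many regions does each mutation occupy, and how much of the tumor's
mutational catalog does a single biopsy miss?
"""

import pandas as pd

from multiregion import heterogeneity, simdata, variants

config = simdata.SimConfig(
    n_regions=5, n_clonal=30,
    tree_splits=[(0, 0.5, (0, 1)), (0, 0.4, (2, 3, 4)), (2, 0.2, (3,))],
    n_private=25, seed=13,
)
_, _, table = simdata.simulate_tumor(config)
table = variants.recover_variants(variants.apply_filters(table))

spectrum = heterogeneity.sharing_spectrum(table)
print("occupancy counts (k = 1..n regions):", [int(k) for k in spectrum.counts])
print("percentages:", spectrum.percentages())
print(f"ubiquitous fraction: {100 * spectrum.ubiquitous_fraction:.1f}%")

miss = heterogeneity.single_sample_miss_rate(table)
print(f"single-sample miss rate: {100 * miss['min']:.1f}-{100 * miss['max']:.1f}%")
# A single biopsy misses this share of the patient's detected mutations;
# the spread across regions is itself a heterogeneity readout.

cnv = pd.DataFrame(
    [{"gene": "MDM2", "sample": f"R{i}", "cn_total": 10, "cn_major": 8, "cn_minor": 2}
     for i in range(1, 6)]
    + [{"gene": "CD274", "sample": f"R{i}", "cn_total": 8 if i <= 2 else 2,
        "cn_major": 6 if i <= 2 else 1, "cn_minor": 2 if i <= 2 else 1}
       for i in range(1, 6)]
)
_, summary = heterogeneity.classify_cnv(cnv)
print("CNV summary:", {k: summary[k] for k in
                       ("genes_with_cnv", "genes_homogeneous", "genes_heterogeneous")})
# MDM2 is amplified in all regions (homogeneous); CD274 in only 2/5
# (heterogeneous) - the single-sample problem applies to CNVs too.
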