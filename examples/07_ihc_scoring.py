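"""Immunohistochemistry H-scores and p53 quartile grouping."""

import pandas as pd

from multiregion import ihc

profiles = pd.DataFrame(
    [
        {"case": 1, "marker": "p53", "pct0": 0, "pct1": 0, "pct2": 0, "pct3": 100},
        {"case": 2, "marker": "p53", "pct0": 90, "pct1": 10, "pct2": 0, "pct3": 0},
        {"case": 3, "marker": "p53", "pct0": 20, "pct1": 40, "pct2": 30, "pct3": 10},
        {"case": 1, "marker": "SMAD4", "pct0": 100, "pct1": 0, "pct2": 0, "pct3": 0},
    ]
)
print(ihc.score_table(profiles).to_string(index=False))
# H = 0*pct0 + 1*pct1 + 2*pct2 + 3*pct3 in [0, 300].  For p53, the outer
# quartiles (H <= 15 or H >= 189: null or overexpressed staining) form
# the "Q1/Q4" group expected of TP53-mutant tumors; case 3 (H = 130)
# falls in the inner "Q2/Q3" group.
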