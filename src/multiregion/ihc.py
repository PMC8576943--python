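"""Immunohistochemistry H-score computation and p53 quartile grouping.

The H-score is a semi-quantitative 0-300 summary of a stained tumor
section: each tumor cell is binned by staining intensity (0, 1+, 2+, 3+)
and the score is the intensity-weighted sum of the cell percentages,

    H = 0*pct0 + 1*pct1 + 2*pct2 + 3*pct3 .

For p53, the outer quartiles (very low or very high expression) are the
pattern expected of TP53-mutant tumors and are pooled into one group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from multiregion.errors import ValidationError

#: p53 H-score quartile boundaries: Q1 <= 15, Q2 = 16-91, Q3 = 92-188, Q4 >= 189.
P53_Q1_MAX = 15
P53_Q4_MIN = 189


@dataclass(frozen=True)
class StainingProfile:
    """Percentages of tumor cells at staining intensities 0, 1+, 2+, 3+.

    Percentages must be non-negative and sum to 100 (all tumor cells are
    assigned an intensity).
    """

    pct0: float
    pct1: float
    pct2: float
    pct3: float

    def validate(self) -> None:
        pcts = (self.pct0, self.pct1, self.pct2, self.pct3)
        if any(p < 0 for p in pcts):
            raise ValidationError(f"negative staining percentage in {pcts}")
        if abs(sum(pcts) - 100.0) > 1e-9:
            raise ValidationError(
                f"staining percentages must sum to 100, got {sum(pcts)}"
            )


def h_score(profile: StainingProfile) -> float:
    """Intensity-weighted staining score in [0, 300]."""
    profile.validate()
    return 0 * profile.pct0 + 1 * profile.pct1 + 2 * profile.pct2 + 3 * profile.pct3


def p53_quartile_group(h: float) -> str:
    """Pool outer vs inner H-score quartiles: ``"Q1/Q4"`` or ``"Q2/Q3"``.

    Outer quartiles (h <= 15 or h >= 189) flag presumptive TP53-mutant
    staining patterns (null or overexpressed).
    """
    if not 0 <= h <= 300:
        raise ValidationError(f"H-score {h} outside [0, 300]")
    if h <= P53_Q1_MAX or h >= P53_Q4_MIN:
        return "Q1/Q4"
    return "Q2/Q3"


def score_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Score a table of staining profiles.

    Parameters
    ----------
    profiles : DataFrame with columns case, marker, pct0, pct1, pct2, pct3.

    Returns
    -------
    DataFrame with columns case, marker, h_score, group (group only for
    p53 rows; other markers get an empty string).
    """
    rows = []
    for rec in profiles.itertuples(index=False):
        h = h_score(StainingProfile(rec.pct0, rec.pct1, rec.pct2, rec.pct3))
        group = p53_quartile_group(h) if str(rec.marker).lower() == "p53" else ""
        rows.append({"case": rec.case, "marker": rec.marker, "h_score": h, "group": group})
    return pd.DataFrame(rows, columns=["case", "marker", "h_score", "group"])


def read_profiles(path) -> pd.DataFrame:
    """Read a staining-profile TSV (case, marker, pct0, pct1, pct2, pct3)."""
    return pd.read_csv(path, sep="\t")


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False)
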