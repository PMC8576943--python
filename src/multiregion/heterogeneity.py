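"""Intratumoral heterogeneity statistics over multiregional variant tables.

Sharing spectra (how many regions each variant occupies), single-sample
miss rates, primary-vs-metastasis set comparisons, multi-hit genes
(parallel-evolution candidates), and copy-number heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from multiregion.errors import ValidationError
from multiregion.variants import NONSYNONYMOUS_EFFECTS, VariantTable


@dataclass
class SharingSpectrum:
    """counts[k] = number of variants present in exactly k of n samples."""

    n_samples: int
    counts: np.ndarray  # length n_samples, index 0 <-> k=1

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.n_samples,):
            raise ValidationError("counts must have one entry per k = 1..n")
        if (self.counts < 0).any():
            raise ValidationError("spectrum counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count(self, k: int) -> int:
        return int(self.counts[k - 1])

    def fraction(self, k: int) -> float | None:
        """Fraction of variants in exactly k samples (None when total 0)."""
        if self.total == 0:
            return None
        return self.count(k) / self.total

    @property
    def ubiquitous_fraction(self) -> float | None:
        """Fraction of variants present in all n samples."""
        return self.fraction(self.n_samples)

    @property
    def not_ubiquitous_fraction(self) -> float | None:
        """Fraction of variants missing from at least one sample."""
        f = self.ubiquitous_fraction
        return None if f is None else 1.0 - f

    def percentages(self, ndigits: int = 1) -> dict[int, float] | None:
        if self.total == 0:
            return None
        return {k: round(100.0 * self.count(k) / self.total, ndigits)
                for k in range(1, self.n_samples + 1)}

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "SharingSpectrum":
        return cls(n_samples=len(counts), counts=np.asarray(counts))


def sharing_spectrum(
    table: VariantTable, effect_class: str | None = "nonsynonymous"
) -> SharingSpectrum:
    """Occupancy spectrum of post-recovery presence over tumor samples."""
    presence = table.presence_matrix(effect_class=effect_class)
    n = presence.shape[1]
    occ = presence.sum(axis=1).to_numpy()
    occ = occ[occ > 0]
    counts = np.bincount(occ, minlength=n + 1)[1:]
    return SharingSpectrum(n_samples=n, counts=counts)


def single_sample_miss_rate(
    table: VariantTable, effect_class: str | None = "nonsynonymous"
) -> dict:
    """How much of the patient's variant catalog a single sample misses.

    Returns per-sample miss rates (1 - detected/union), the patient-level
    not-ubiquitous fraction, and the min/max over samples.  ``None`` when
    the patient has no passing variants.
    """
    presence = table.presence_matrix(effect_class=effect_class)
    detected_any = presence.any(axis=1)
    union = int(detected_any.sum())
    if union == 0:
        return {"per_sample": {}, "not_ubiquitous": None, "min": None, "max": None}
    per_sample = {
        s: 1.0 - presence[s].sum() / union for s in presence.columns
    }
    spectrum = sharing_spectrum(table, effect_class)
    rates = list(per_sample.values())
    return {
        "per_sample": per_sample,
        "not_ubiquitous": spectrum.not_ubiquitous_fraction,
        "min": min(rates),
        "max": max(rates),
    }


def compare_sets(
    table: VariantTable,
    group_a: Iterable[str],
    group_b: Iterable[str],
    effect_class: str | None = "nonsynonymous",
) -> tuple[int, int, int]:
    """(private to A, private to B, shared) variant counts between two
    disjoint sample groups (e.g. primary vs lymph-node metastases)."""
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise ValidationError(f"groups overlap: {group_a & group_b}")
    presence = table.presence_matrix(effect_class=effect_class)
    missing = (group_a | group_b) - set(presence.columns)
    if missing:
        raise ValidationError(f"unknown samples: {missing}")
    in_a = presence[list(group_a)].any(axis=1)
    in_b = presence[list(group_b)].any(axis=1)
    return int((in_a & ~in_b).sum()), int((in_b & ~in_a).sum()), int((in_a & in_b).sum())


def multihit_genes(table: VariantTable) -> pd.DataFrame:
    """Genes carrying >= 2 distinct non-synonymous variants in this patient.

    Distinctness is keyed on (chrom, pos, ref, alt).  ``disjoint_pattern``
    flags parallel-evolution candidates: the gene's variants occupy
    pairwise-disjoint sample sets.
    """
    presence = table.presence_matrix(effect_class="nonsynonymous")
    detected = presence.index[presence.any(axis=1)]
    meta = table.variants.loc[detected, ["chrom", "pos", "ref", "alt", "gene"]]
    rows = []
    for gene, grp in meta.groupby("gene"):
        distinct = grp.drop_duplicates(["chrom", "pos", "ref", "alt"])
        if len(distinct) < 2:
            continue
        sets = [frozenset(presence.columns[presence.loc[v]]) for v in distinct.index]
        disjoint = all(
            not (sets[i] & sets[j]) for i in range(len(sets)) for j in range(i + 1, len(sets))
        )
        rows.append({"gene": gene, "n_variants": len(distinct), "disjoint_pattern": disjoint})
    return pd.DataFrame(rows, columns=["gene", "n_variants", "disjoint_pattern"])


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------

DELETION_TOTAL_CN = 0
AMPLIFICATION_MIN_CN = 6


def classify_cnv(cnv: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Classify per-gene-per-sample copy number and summarize heterogeneity.

    Parameters
    ----------
    cnv : DataFrame with columns gene, sample, cn_total, cn_major, cn_minor.

    Returns
    -------
    (calls, summary): calls adds a ``cnv_class`` column (deletion iff
    total CN 0, amplification iff total CN >= 6, else neutral); summary
    counts genes with any CNV and genes whose non-neutral class is the
    same in every sample (homogeneous).
    """
    if (cnv[["cn_total", "cn_major", "cn_minor"]] < 0).to_numpy().any():
        raise ValidationError("copy numbers must be non-negative")
    calls = cnv.copy()
    total = calls["cn_total"].to_numpy()
    cls = np.where(
        total == DELETION_TOTAL_CN,
        "deletion",
        np.where(total >= AMPLIFICATION_MIN_CN, "amplification", "neutral"),
    )
    calls["cnv_class"] = cls

    genes_with_cnv, genes_homogeneous = [], []
    for gene, grp in calls.groupby("gene"):
        classes = set(grp["cnv_class"])
        if classes == {"neutral"}:
            continue
        genes_with_cnv.append(gene)
        if len(classes) == 1:
            genes_homogeneous.append(gene)
    summary = {
        "genes_with_cnv": len(genes_with_cnv),
        "genes_homogeneous": len(genes_homogeneous),
        "genes_heterogeneous": len(genes_with_cnv) - len(genes_homogeneous),
        "cnv_genes": sorted(genes_with_cnv),
        "homogeneous_genes": sorted(genes_homogeneous),
    }
    return calls, summary


def read_cnv(path) -> pd.DataFrame:
    """Read a CNV TSV (gene, sample, cn_total, cn_major, cn_minor)."""
    return pd.read_csv(path, sep="\t")
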