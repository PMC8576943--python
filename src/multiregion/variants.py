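"""Multi-sample somatic variant tables: data model, filtering, recovery, I/O.

A :class:`VariantTable` holds one patient's somatic variants across tumor
regions (plus the matched normal), with per-sample read support and the
annotation flags that drive filtering.  Filtering follows a fixed rule
chain (allele frequency, depth, alt-read support, strand bias, blaclisted
regions, homopolymer context, population frequency, coding effect, and a
cancer-gene-census rescue for variants unknown to somatic databases),
then a per-patient recovery step re-admits sub-threshold calls of variants
that pass in at least one other region of the same patient.

Presence of a variant in a sample is a *filter state*, not raw AF > 0:
downstream heterogeneity and clonality statistics count a variant in a
sample only if it passes (or was recovered) there.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from multiregion.errors import ConfigurationError, ValidationError

#: Coding effects counted as non-synonymous throughout the package.
NONSYNONYMOUS_EFFECTS = frozenset({"missense", "nonsense", "frameshift"})

EFFECTS = frozenset({"synonymous", "missense", "nonsense", "frameshift", "other"})
TISSUES = frozenset({"primary", "lymph_node", "normal"})

#: Order in which filter rules are evaluated and reported.
RULE_ORDER = (
    "min_af",
    "min_depth",
    "min_alt_reads",
    "strand_bias",
    "blacklist",
    "homopolymer",
    "population_af",
    "effect",
    "census",
)

_VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "homopolymer",
    "strand_bias",
    "blacklist",
    "population_af",
    "known_somatic",
    "census_gene",
]

_CALL_COLUMNS = ["variant_id", "sample_id", "depth", "alt_reads", "af", "present", "failed"]


@dataclass
class FilterRules:
    """Thresholds of the somatic-variant filter chain.

    Defaults mirror a standard multiregional exome workflow: AF >= 5%,
    total depth >= 10 in tumor or matched normal, >= 2 alt reads, AF > 10%
    in homopolymer context, population AF < 1%, and (optionally) rescue of
    database-unknown variants only within cancer-census genes.
    """

    min_af: float = 0.05
    min_depth: int = 10
    min_alt_reads: int = 2
    homopolymer_min_af: float = 0.10
    max_population_af: float = 0.01
    require_nonsynonymous: bool = True
    census_rescue: bool = True

    def validate(self) -> None:
        if not 0 <= self.min_af <= 1:
            raise ConfigurationError(f"min_af {self.min_af} outside [0, 1]")
        if not 0 <= self.homopolymer_min_af <= 1:
            raise ConfigurationError("homopolymer_min_af outside [0, 1]")
        if not 0 <= self.max_population_af <= 1:
            raise ConfigurationError("max_population_af outside [0, 1]")
        if self.min_depth < 0 or self.min_alt_reads < 0:
            raise ConfigurationError("depth thresholds must be non-negative")

    @classmethod
    def from_json(cls, path) -> "FilterRules":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


@dataclass
class VariantTable:
    """One patient's somatic variants across samples.

    Attributes
    ----------
    patient : str
    samples : DataFrame indexed by sample_id with columns ``purity`` and
        ``tissue`` (primary | lymph_node | normal).
    variants : DataFrame indexed by variant_id with site-level annotation
        (chrom, pos, ref, alt, gene, effect, flags, population_af, ...).
    calls : long DataFrame, one row per variant x sample, with depth,
        alt_reads, af, and filter state (``present`` bool, ``failed``
        semicolon-joined failing rules).
    filter_log : DataFrame of removals (variant_id, sample_id, rule).
    """

    patient: str
    samples: pd.DataFrame
    variants: pd.DataFrame
    calls: pd.DataFrame
    filter_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "sample_id", "rule"])
    )
    filtered: bool = False

    def validate(self) -> None:
        if self.samples.index.duplicated().any():
            raise ValidationError("duplicate sample ids")
        bad = set(self.samples["tissue"]) - TISSUES
        if bad:
            raise ValidationError(f"unknown tissue labels: {bad}")
        unknown = set(self.calls["sample_id"]) - set(self.samples.index)
        if unknown:
            raise ValidationError(f"calls reference unknown samples: {unknown}")
        unknown_v = set(self.calls["variant_id"]) - set(self.variants.index)
        if unknown_v:
            raise ValidationError(f"calls reference unknown variants: {unknown_v}")
        if (self.variants["pos"] < 1).any():
            raise ValidationError("positions must be 1-based (>= 1)")
        c = self.calls
        if ((c["alt_reads"] > c["depth"]) | (c["alt_reads"] < 0)).any():
            raise ValidationError("alt_reads must satisfy 0 <= alt_reads <= depth")

    # -- convenience -----------------------------------------------------
    @property
    def tumor_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["tissue"] != "normal"])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["tissue"] == "normal"])

    def presence_matrix(self, effect_class: str | None = None) -> pd.DataFrame:
        """Boolean variants x tumor-samples matrix of post-filter presence.

        ``effect_class`` restricts rows: "nonsynonymous", "synonymous",
        or None for all variants.
        """
        if not self.filtered:
            raise ValidationError("presence requires apply_filters() first")
        wide = (
            self.calls.pivot(index="variant_id", columns="sample_id", values="present")
            .reindex(index=self.variants.index, columns=self.tumor_samples)
            .fillna(False)
            .astype(bool)
        )
        if effect_class == "nonsynonymous":
            keep = self.variants["effect"].isin(NONSYNONYMOUS_EFFECTS)
            wide = wide.loc[keep[keep].index]
        elif effect_class == "synonymous":
            wide = wide.loc[self.variants.index[self.variants["effect"] == "synonymous"]]
        elif effect_class is not None:
            raise ConfigurationError(f"unknown effect_class {effect_class!r}")
        return wide

    def copy(self) -> "VariantTable":
        return VariantTable(
            patient=self.patient,
            samples=self.samples.copy(),
            variants=self.variants.copy(),
            calls=self.calls.copy(),
            filter_log=self.filter_log.copy(),
            filtered=self.filtered,
        )


def variant_id(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


def make_table(
    patient: str,
    samples: pd.DataFrame,
    variants: pd.DataFrame,
    calls: pd.DataFrame,
) -> VariantTable:
    """Assemble and validate a VariantTable; AF is recomputed from counts."""
    calls = calls.copy()
    if "af" not in calls:
        calls["af"] = 0.0
    depth = calls["depth"].to_numpy(dtype=float)
    alt = calls["alt_reads"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    calls["af"] = af
    if "present" not in calls:
        calls["present"] = False
    if "failed" not in calls:
        calls["failed"] = ""
    table = VariantTable(patient=patient, samples=samples, variants=variants, calls=calls)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Filtering and recovery
# ---------------------------------------------------------------------------

def apply_filters(table: VariantTable, rules: FilterRules | None = None) -> VariantTable:
    """Apply the somatic filter chain; returns a new table with filter state.

    A call is present in a tumor sample iff it passes every rule there.
    ``failed`` records *all* failing rules (in :data:`RULE_ORDER`); the
    filter log records the first.  Normal-sample rows are never "present".
    """
    rules = rules or FilterRules()
    rules.validate()
    table.validate()
    out = table.copy()

    calls = out.calls.merge(
        out.variants.reset_index(names="variant_id"), on="variant_id", how="left"
    ).merge(
        out.samples.reset_index(names="sample_id")[["sample_id", "tissue"]],
        on="sample_id",
        how="left",
    )

    # Matched-normal depth per variant (max over normal columns).
    norm = calls[calls["tissue"] == "normal"].groupby("variant_id")["depth"].max()
    normal_depth = calls["variant_id"].map(norm).fillna(0).to_numpy(dtype=float)

    af = calls["af"].to_numpy(dtype=float)
    depth = calls["depth"].to_numpy(dtype=float)
    alt = calls["alt_reads"].to_numpy(dtype=float)
    is_tumor = (calls["tissue"] != "normal").to_numpy()

    fails = {
        "min_af": af < rules.min_af,
        "min_depth": (depth < rules.min_depth) & (normal_depth < rules.min_depth),
        "min_alt_reads": alt < rules.min_alt_reads,
        "strand_bias": calls["strand_bias"].to_numpy(dtype=bool),
        "blacklist": calls["blacklist"].to_numpy(dtype=bool),
        "homopolymer": calls["homopolymer"].to_numpy(dtype=bool)
        & ~(af > rules.homopolymer_min_af),
        "population_af": ~(calls["population_af"].to_numpy(dtype=float) < rules.max_population_af),
        "effect": (
            ~calls["effect"].isin(NONSYNONYMOUS_EFFECTS).to_numpy()
            if rules.require_nonsynonymous
            else np.zeros(len(calls), dtype=bool)
        ),
        "census": (
            ~(
                calls["known_somatic"].to_numpy(dtype=bool)
                | calls["census_gene"].to_numpy(dtype=bool)
            )
            if rules.census_rescue
            else np.zeros(len(calls), dtype=bool)
        ),
    }

    failed_strs = np.array([""] * len(calls), dtype=object)
    any_fail = np.zeros(len(calls), dtype=bool)
    for rule in RULE_ORDER:
        mask = fails[rule]
        failed_strs[mask] = np.where(
            failed_strs[mask] == "", rule, failed_strs[mask] + ";" + rule
        )
        any_fail |= mask

    present = is_tumor & ~any_fail
    out.calls["present"] = present
    out.calls["failed"] = failed_strs

    removed = is_tumor & any_fail
    first_rule = [s.split(";")[0] if s else "" for s in failed_strs]
    out.filter_log = pd.DataFrame(
        {
            "variant_id": calls.loc[removed, "variant_id"].to_numpy(),
            "sample_id": calls.loc[removed, "sample_id"].to_numpy(),
            "rule": np.asarray(first_rule, dtype=object)[removed],
        }
    )
    out.filtered = True
    return out


def recover_variants(table: VariantTable, min_af: float = 0.05) -> VariantTable:
    """Per-patient cross-sample recovery of sub-threshold calls.

    A variant passing in at least one tumor sample at AF >= ``min_af``
    (the anchor) is re-marked present in same-patient tumor samples where
    it was removed *solely* for low AF; every other rule still binds.
    Never removes calls; idempotent.
    """
    if not table.filtered:
        raise ValidationError("recover_variants requires apply_filters() first")
    out = table.copy()
    calls = out.calls
    tumor = calls["sample_id"].isin(out.tumor_samples)

    anchored = set(
        calls.loc[tumor & calls["present"] & (calls["af"] >= min_af), "variant_id"]
    )
    recoverable = (
        tumor
        & ~calls["present"]
        & (calls["failed"] == "min_af")
        & calls["variant_id"].isin(anchored)
    )
    out.calls.loc[recoverable, "present"] = True
    if recoverable.any():
        rec = calls.loc[recoverable, ["variant_id", "sample_id"]].copy()
        rec["rule"] = "recovered:min_af"
        out.filter_log = pd.concat([out.filter_log, rec], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def tmb(table: VariantTable, panel_size_mb: float) -> pd.Series:
    """Tumor mutational burden: passing non-synonymous variants per Mb,
    per tumor sample."""
    if panel_size_mb <= 0:
        raise ConfigurationError(f"panel_size_mb must be positive, got {panel_size_mb}")
    presence = table.presence_matrix(effect_class="nonsynonymous")
    return presence.sum(axis=0).astype(float) / panel_size_mb


def classify_msi(score_percent: float) -> str:
    """Classify a microsatellite-instability score (percent of unstable
    sites) into MSS (< 10), MSI-L ([10, 30]) or MSI-H (> 30)."""
    if not 0 <= score_percent <= 100:
        raise ValidationError(f"MSI score {score_percent} outside [0, 100]")
    if score_percent < 10:
        return "MSS"
    if score_percent > 30:
        return "MSI-H"
    return "MSI-L"


# ---------------------------------------------------------------------------
# VCF I/O (multi-sample VCF v4.2; FORMAT DP/AD/AF)
# ---------------------------------------------------------------------------

_INFO_FIELDS = [
    ("GENE", "1", "String", "Gene symbol"),
    ("EFFECT", "1", "String", "Coding effect"),
    ("HP", "0", "Flag", "Homopolymer context"),
    ("SBF", "0", "Flag", "Strand bias"),
    ("BL", "0", "Flag", "Blacklisted region"),
    ("PAF", "1", "Float", "Population allele frequency"),
    ("KS", "0", "Flag", "Known somatic (COSMIC/ICGC-style)"),
    ("CG", "0", "Flag", "Cancer gene census member"),
]


def write_vcf(table: VariantTable, path, seed: int | None = None) -> None:
    """Write a multi-sample VCF v4.2 with per-sample DP/AD/AF."""
    header = pysam.VariantHeader()
    for chrom in pd.unique(table.variants["chrom"].astype(str)):
        header.contigs.add(chrom)
    for name, num, typ, desc in _INFO_FIELDS:
        header.info.add(name, num, typ, desc)
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("AF", 1, "Float", "Allele frequency")
    header.add_line(f"##patient={table.patient}")
    if seed is not None:
        header.add_line(f"##simulation_seed={seed}")
    for sid, row in table.samples.iterrows():
        header.add_line(
            f'##SAMPLE=<ID={sid},Purity={row["purity"]:.6g},Tissue={row["tissue"]}>'
        )
        header.add_sample(str(sid))

    by_sample = {
        sid: grp.set_index("variant_id")
        for sid, grp in table.calls.groupby("sample_id")
    }
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        order = table.variants.sort_values(["chrom", "pos", "ref", "alt"]).index
        for vid in order:
            v = table.variants.loc[vid]
            rec = vcf.new_record(
                contig=str(v["chrom"]),
                start=int(v["pos"]) - 1,
                stop=int(v["pos"]) - 1 + len(str(v["ref"])),
                alleles=(str(v["ref"]), str(v["alt"])),
            )
            rec.id = vid
            rec.info["GENE"] = str(v["gene"])
            rec.info["EFFECT"] = str(v["effect"])
            rec.info["PAF"] = float(v["population_af"])
            for flag, col in (("HP", "homopolymer"), ("SBF", "strand_bias"),
                              ("BL", "blacklist"), ("KS", "known_somatic"),
                              ("CG", "census_gene")):
                if bool(v[col]):
                    rec.info[flag] = True
            for sid in table.samples.index:
                call = by_sample.get(sid)
                if call is not None and vid in call.index:
                    c = call.loc[vid]
                    dp = int(c["depth"])
                    ad_alt = int(c["alt_reads"])
                    rec.samples[str(sid)]["DP"] = dp
                    rec.samples[str(sid)]["AD"] = (dp - ad_alt, ad_alt)
                    rec.samples[str(sid)]["AF"] = float(c["af"])
                else:
                    rec.samples[str(sid)]["DP"] = 0
                    rec.samples[str(sid)]["AD"] = (0, 0)
                    rec.samples[str(sid)]["AF"] = 0.0
            vcf.write(rec)


_SAMPLE_LINE = re.compile(r"##SAMPLE=<ID=([^,>]+),Purity=([^,>]+),Tissue=([^,>]+)>")


def read_vcf(path) -> VariantTable:
    """Read a multi-sample VCF written by :func:`write_vcf` (or compatible).

    AF is recomputed from AD/DP (exact integers) so the round trip is
    lossless; a missing FORMAT AF is therefore also tolerated.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValidationError(f"malformed VCF {path}: {exc}") from exc

    patient = "unknown"
    meta: dict[str, tuple[float, str]] = {}
    for line in str(vcf.header).splitlines():
        if line.startswith("##patient="):
            patient = line.split("=", 1)[1]
        m = _SAMPLE_LINE.match(line)
        if m:
            meta[m.group(1)] = (float(m.group(2)), m.group(3))

    sample_ids = list(vcf.header.samples)
    samples = pd.DataFrame(
        {
            "purity": [meta.get(s, (1.0, "primary"))[0] for s in sample_ids],
            "tissue": [meta.get(s, (1.0, "primary"))[1] for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    vrows, crows = [], []
    for lineno, rec in enumerate(vcf, start=1):
        try:
            ref, alt = rec.alleles[0], rec.alleles[1]
            vid = rec.id or variant_id(rec.contig, rec.pos, ref, alt)
            vrows.append(
                {
                    "variant_id": vid,
                    "chrom": rec.contig,
                    "pos": rec.pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": rec.info.get("GENE", ""),
                    "effect": rec.info.get("EFFECT", "other"),
                    "homopolymer": "HP" in rec.info,
                    "strand_bias": "SBF" in rec.info,
                    "blacklist": "BL" in rec.info,
                    "population_af": float(rec.info.get("PAF", 0.0)),
                    "known_somatic": "KS" in rec.info,
                    "census_gene": "CG" in rec.info,
                }
            )
            for sid in sample_ids:
                fmt = rec.samples[sid]
                dp = int(fmt.get("DP") or 0)
                ad = fmt.get("AD")
                alt_reads = int(ad[1]) if ad is not None and ad[1] is not None else 0
                crows.append(
                    {
                        "variant_id": vid,
                        "sample_id": sid,
                        "depth": dp,
                        "alt_reads": alt_reads,
                    }
                )
        except (KeyError, IndexError, TypeError) as exc:
            raise ValidationError(f"malformed VCF record at line ~{lineno}: {exc}") from exc

    variants = (
        pd.DataFrame(vrows, columns=["variant_id"] + _VARIANT_COLUMNS)
        .set_index("variant_id")
    )
    calls = pd.DataFrame(crows, columns=["variant_id", "sample_id", "depth", "alt_reads"])
    return make_table(patient, samples, variants, calls)


# ---------------------------------------------------------------------------
# Flat TSV mirror (one row per variant x sample)
# ---------------------------------------------------------------------------

def to_tsv(table: VariantTable, path) -> None:
    long = table.calls.merge(
        table.variants.reset_index(names="variant_id"), on="variant_id"
    )
    long.insert(0, "patient", table.patient)
    long = long.merge(
        table.samples.reset_index(names="sample_id"), on="sample_id"
    )
    long.to_csv(path, sep="\t", index=False)


def from_tsv(path) -> VariantTable:
    long = pd.read_csv(path, sep="\t")
    patient = str(long["patient"].iloc[0]) if len(long) else "unknown"
    samples = (
        long[["sample_id", "purity", "tissue"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
    )
    variants = (
        long[["variant_id"] + _VARIANT_COLUMNS]
        .drop_duplicates("variant_id")
        .set_index("variant_id")
    )
    calls = long[[c for c in _CALL_COLUMNS if c in long.columns]].copy()
    table = make_table(patient, samples, variants, calls)
    if "present" in long.columns:
        table.calls["present"] = long["present"].to_numpy(dtype=bool)
        table.calls["failed"] = long.get("failed", pd.Series([""] * len(long))).fillna("")
        table.filtered = True
    return table
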