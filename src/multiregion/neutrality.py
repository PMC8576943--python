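"""Test of neutral tumor evolution from variant-allele-frequency spectra.

Under neutral growth the cumulative number of subclonal mutations with
frequency >= f grows linearly in 1/f,

    M(f) = mu_eff * (1/f - 1/f_max),

with slope mu_eff = mu/beta, the effective mutation rate.  A sample's VAF
set is compared with this expectation inside a fit window below the
clonal peak (default [0.1, 0.25]): a through-origin least-squares fit of
M(f) against 1/f - 1/f_upper yields mu_eff_hat and an R^2; agreement is
called *neutral* when R^2 >= 0.98.  The Kolmogorov distance between the
normalized empirical and theoretical cumulative curves (both forced to
[0, 1] over the window, evaluated at the observed VAFs) is reported as a
descriptive statistic.

VAFs enter uncorrected for purity (purity scales all frequencies of a
sample alike); variants that likely underwent gene doubling (estimated
multiplicity >= 2) are excluded; synonymous and non-synonymous mutations
are both included.  A pooled analysis uses each variant's mean AF over
all tumor samples of the patient (zeros included), mitigating spatial
sampling bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from multiregion.errors import ConfigurationError
from multiregion.variants import VariantTable


@dataclass
class NeutralityConfig:
    f_lower: float = 0.1
    f_upper: float = 0.25
    r2_threshold: float = 0.98
    min_mutations: int = 12
    #: purity correction is deliberately not applied (see module docstring)
    use_purity_correction: bool = False

    def validate(self) -> None:
        if not 0 < self.f_lower < self.f_upper <= 1:
            raise ConfigurationError(
                f"require 0 < f_lower < f_upper <= 1, got ({self.f_lower}, {self.f_upper})"
            )
        if self.use_purity_correction:
            raise ConfigurationError("purity correction is not supported by this test")


@dataclass
class NeutralityResult:
    mu_eff_hat: float | None
    r2: float | None
    ks_distance: float | None
    n_in_window: int
    verdict: str  # neutral | non_neutral | insufficient


def prepare_vafs(
    table: VariantTable,
    sample: str | None = None,
    multiplicities: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Collect the VAFs entering the neutrality test.

    Passing (post-recovery) variants of any coding effect are included;
    variants with estimated multiplicity >= 2 (``multiplicities`` keyed by
    variant_id, e.g. from the CCF step or simulation truth) are excluded
    as likely gene-doubled.  ``sample=None`` ("pooled") returns per-variant
    mean AF over all tumor samples, zeros included for absent calls.
    """
    presence = table.presence_matrix(effect_class=None)
    keep = presence.index[presence.any(axis=1)]
    if multiplicities:
        keep = [v for v in keep if multiplicities.get(v, 1) < 2]
    tumor = table.tumor_samples
    af = (
        table.calls.pivot(index="variant_id", columns="sample_id", values="af")
        .reindex(index=keep, columns=tumor)
        .fillna(0.0)
    )
    pres = presence.loc[keep, tumor]
    af = af.where(pres, 0.0)  # absent calls contribute zero frequency
    if sample is None:
        return af.mean(axis=1).to_numpy(dtype=float)
    if sample not in tumor:
        raise ConfigurationError(f"unknown tumor sample {sample!r}")
    vals = af[sample].to_numpy(dtype=float)
    return vals[pres[sample].to_numpy(dtype=bool)]


def cumulative_m(vafs: Iterable[float], f: float) -> int:
    """M(f): number of VAFs >= f."""
    v = np.asarray(list(vafs) if not isinstance(vafs, np.ndarray) else vafs, dtype=float)
    return int((v >= f).sum())


def fit_neutral_model(
    vafs: Iterable[float], config: NeutralityConfig | None = None
) -> NeutralityResult:
    """Fit M(f) = mu_eff * (1/f - 1/f_upper) inside the window and score it.

    Evaluation points are the observed VAFs inside [f_lower, f_upper].
    R^2 is computed about the mean of M, so a flat M (no frequency
    structure) scores 0.  Fewer than ``min_mutations`` in-window points
    yield verdict "insufficient" with numeric fields None.
    """
    config = config or NeutralityConfig()
    config.validate()
    v = np.sort(np.asarray(list(vafs), dtype=float))
    w = v[(v >= config.f_lower) & (v <= config.f_upper)]
    n = w.size
    if n < config.min_mutations:
        return NeutralityResult(None, None, None, n, "insufficient")

    # M(f) at each observed in-window frequency, counted within the window
    m = n - np.searchsorted(w, w, side="left")
    x = 1.0 / w - 1.0 / config.f_upper
    slope = float(np.sum(x * m) / np.sum(x * x))
    pred = slope * x
    ss_res = float(np.sum((m - pred) ** 2))
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    r2 = max(0.0, 1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0

    x_lower = 1.0 / config.f_lower - 1.0 / config.f_upper
    emp = m / float(n)
    theo = x / x_lower
    ks = float(np.max(np.abs(emp - theo)))

    verdict = "neutral" if r2 >= config.r2_threshold else "non_neutral"
    return NeutralityResult(slope, r2, ks, n, verdict)


def neutrality_panel(
    table: VariantTable,
    config: NeutralityConfig | None = None,
    multiplicities: Mapping[str, int] | None = None,
    exclude_samples: Iterable[str] = (),
) -> dict:
    """Per-sample + pooled neutrality results and across-sample summary.

    ``exclude_samples`` drops samples from the panel (e.g. a hypermutated
    sample whose clonal peak covers the whole frequency window).  The
    summary reports mean and standard deviation of the Kolmogorov
    distance across assessable samples.
    """
    config = config or NeutralityConfig()
    excluded = set(exclude_samples)
    per_sample: dict[str, NeutralityResult] = {}
    for s in table.tumor_samples:
        if s in excluded:
            continue
        per_sample[s] = fit_neutral_model(
            prepare_vafs(table, sample=s, multiplicities=multiplicities), config
        )
    pooled = fit_neutral_model(
        prepare_vafs(table, sample=None, multiplicities=multiplicities), config
    )
    ks = [r.ks_distance for r in per_sample.values() if r.ks_distance is not None]
    summary = {
        "ks_mean": float(np.mean(ks)) if ks else None,
        "ks_sd": float(np.std(ks, ddof=0)) if ks else None,
        "n_assessable": len(ks),
    }
    return {"per_sample": per_sample, "pooled": pooled, "summary": summary}


def results_frame(panel: dict, patient: str) -> pd.DataFrame:
    """Flatten a neutrality panel into a tidy results table."""
    rows = []
    items = list(panel["per_sample"].items()) + [("pooled", panel["pooled"])]
    for name, r in items:
        rows.append(
            {
                "patient": patient,
                "sample": name,
                "n_in_window": r.n_in_window,
                "mu_eff_hat": r.mu_eff_hat,
                "r2": r.r2,
                "ks_distance": r.ks_distance,
                "verdict": r.verdict,
            }
        )
    return pd.DataFrame(rows)
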