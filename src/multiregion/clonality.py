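"""Cancer-cell-fraction clonality and tumor-sampling requirements.

The cancer cell fraction (CCF) of a variant is its variant allele
fraction rescaled for tumor purity rho and local copy number:

    CCF = VAF * (rho*CN_t + (1-rho)*CN_n) / (rho * m)

with mutation multiplicity m estimated as the nearest integer of
VAF*(rho*CN_t + (1-rho)*CN_n)/rho, clamped to [1, CN_t].  A variant is
called *subclonal* when the upper bound of the exact (Clopper-Pearson)
95% binomial confidence interval on the VAF, mapped through the same
linear transform, falls below 0.95.

Per-patient clonality pools read counts over all tumor samples into a
virtual single sample (zeros included for covered-but-absent regions);
comparing per-sample and per-patient calls exposes the "clonal illusion":
variants that look clonal in some region but are subclonal tumor-wide.

The sampling-requirement model summarizes how fast additional regional
samples pin down the truly clonal set.  The apparent-clonal curve C(n)
(mean number of variants shared by n random regions) is fit with

    C(n) = c_inf + (C(1) - c_inf) * g**(n-1),       0 < g < 1,

where g is the tumor's *balance factor*; the probability of correct
clonal identification with n samples is modeled as P(n) = 1 - g**n, so
n = ceil(ln(1-p) / ln(g)) samples reach target probability p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from statsmodels.stats.proportion import proportion_confint

from multiregion.errors import ConfigurationError, ValidationError
from multiregion.variants import VariantTable

CCF_CAP = 1.5
SUBCLONAL_CI_THRESHOLD = 0.95


@dataclass(frozen=True)
class CCFEstimate:
    vaf: float
    multiplicity: int
    ccf: float
    ci_low: float
    ci_high: float
    status: str  # clonal | subclonal | not_assessable


@dataclass
class BalanceFit:
    g: float
    c_inf: float
    curve: np.ndarray
    residual: float


def compute_ccf(
    alt_reads: int,
    depth: int,
    purity: float,
    cn_tumor: float,
    cn_normal: float = 2.0,
) -> CCFEstimate:
    """CCF point estimate with exact-binomial 95% CI and clonality call.

    depth = 0 yields status "not_assessable" (no exception).
    """
    if depth == 0:
        return CCFEstimate(float("nan"), 1, float("nan"), float("nan"),
                           float("nan"), "not_assessable")
    if depth < 0 or alt_reads < 0 or alt_reads > depth:
        raise ValidationError(f"invalid read counts alt={alt_reads}, depth={depth}")
    if not 0 < purity <= 1:
        raise ConfigurationError(f"purity {purity} outside (0, 1]")
    if cn_tumor < 1:
        raise ConfigurationError(f"tumor copy number {cn_tumor} must be >= 1")

    vaf = alt_reads / depth
    adjusted = purity * cn_tumor + (1.0 - purity) * cn_normal
    m = int(np.clip(round(vaf * adjusted / purity), 1, max(1, round(cn_tumor))))
    scale = adjusted / (purity * m)

    lo, hi = proportion_confint(alt_reads, depth, alpha=0.05, method="beta")
    ccf = min(vaf * scale, CCF_CAP)
    ci_low = min(float(lo) * scale, CCF_CAP)
    ci_high = min(float(hi) * scale, CCF_CAP)
    status = "subclonal" if ci_high < SUBCLONAL_CI_THRESHOLD else "clonal"
    return CCFEstimate(vaf, m, ccf, ci_low, ci_high, status)


def _cn_lookup(cn_map, variant_id: str, sample_id: str, default: float = 2.0) -> float:
    if cn_map is None:
        return default
    if isinstance(cn_map, Mapping):
        return float(cn_map.get((variant_id, sample_id), cn_map.get(variant_id, default)))
    return float(cn_map)


def per_sample_clonality(
    table: VariantTable, cn_map=None, only_present: bool = True
) -> pd.DataFrame:
    """CCF and clonality call per (variant, tumor sample).

    cn_map: scalar, or mapping keyed by (variant_id, sample_id) or
    variant_id, giving the tumor total copy number (default 2).
    """
    purity = table.samples["purity"]
    rows = []
    tumor = set(table.tumor_samples)
    calls = table.calls[table.calls["sample_id"].isin(tumor)]
    if only_present:
        calls = calls[calls["present"]]
    for rec in calls.itertuples(index=False):
        est = compute_ccf(
            int(rec.alt_reads),
            int(rec.depth),
            float(purity[rec.sample_id]),
            _cn_lookup(cn_map, rec.variant_id, rec.sample_id),
        )
        rows.append(
            {
                "variant_id": rec.variant_id,
                "sample_id": rec.sample_id,
                "vaf": est.vaf,
                "multiplicity": est.multiplicity,
                "ccf": est.ccf,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "status": est.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "sample_id", "vaf", "multiplicity", "ccf",
                 "ci_low", "ci_high", "status"],
    )


def per_patient_clonality(table: VariantTable, cn_map=None) -> pd.DataFrame:
    """Pooled ("virtual single sample") clonality per variant.

    Read counts are summed over all tumor samples (zeros included for
    covered-but-absent samples); purity and copy number enter as
    depth-weighted means.  Variants with no coverage anywhere are
    "not_assessable".
    """
    purity = table.samples["purity"]
    tumor = set(table.tumor_samples)
    calls = table.calls[table.calls["sample_id"].isin(tumor)]
    rows = []
    for vid, grp in calls.groupby("variant_id", sort=True):
        depth = grp["depth"].to_numpy(dtype=float)
        alt = int(grp["alt_reads"].sum())
        total_depth = int(depth.sum())
        if total_depth == 0:
            est = CCFEstimate(float("nan"), 1, float("nan"), float("nan"),
                              float("nan"), "not_assessable")
        else:
            w = depth / depth.sum()
            rho = float(np.sum(w * purity[grp["sample_id"]].to_numpy(dtype=float)))
            cn = float(
                np.sum(w * [_cn_lookup(cn_map, vid, s) for s in grp["sample_id"]])
            )
            est = compute_ccf(alt, total_depth, rho, cn)
        rows.append(
            {
                "variant_id": vid,
                "vaf": est.vaf,
                "multiplicity": est.multiplicity,
                "ccf": est.ccf,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "status": est.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "vaf", "multiplicity", "ccf", "ci_low", "ci_high", "status"],
    )


def clonality_percentages(statuses: Iterable[str], ndigits: int = 1) -> dict:
    """Percent clonal / subclonal / not_assessable among a set of calls."""
    s = pd.Series(list(statuses))
    total = len(s)
    out = {"total": total}
    for status in ("clonal", "subclonal", "not_assessable"):
        n = int((s == status).sum())
        out[status] = n
        out[f"{status}_pct"] = round(100.0 * n / total, ndigits) if total else None
    return out


def clonal_illusion_report(
    per_sample: pd.DataFrame, per_patient: pd.DataFrame
) -> pd.DataFrame:
    """Variants called clonal in >= 1 sample yet subclonal patient-wide.

    Both inputs must describe the same variant universe (per_sample may
    legitimately lack rows for variants absent everywhere).
    """
    extra = set(per_sample["variant_id"]) - set(per_patient["variant_id"])
    if extra:
        raise ValidationError(f"per-sample variants missing from per-patient: {extra}")
    pooled = per_patient.set_index("variant_id")["status"]
    rows = []
    for vid, grp in per_sample.groupby("variant_id"):
        clonal_in = sorted(grp.loc[grp["status"] == "clonal", "sample_id"])
        if clonal_in and pooled.get(vid) == "subclonal":
            rows.append({"variant_id": vid, "clonal_in_samples": clonal_in})
    return pd.DataFrame(rows, columns=["variant_id", "clonal_in_samples"])


# ---------------------------------------------------------------------------
# Apparent-clonal curve, balance factor, samples needed
# ---------------------------------------------------------------------------

EXHAUSTIVE_SUBSET_LIMIT = 200


def apparent_clonal_curve(
    presence, n_subsets: int = 100, rng: np.random.Generator | None = None
) -> np.ndarray:
    """C(n): mean count of variants shared by every member of a random
    size-n sample subset, for n = 1..n_samples.

    ``presence`` is a boolean variants x samples DataFrame/array or a
    filtered :class:`~multiregion.variants.VariantTable`.  Exhaustive over
    subsets when <= 200 exist, Monte Carlo (``n_subsets`` draws) beyond.
    """
    if isinstance(presence, VariantTable):
        presence = presence.presence_matrix(effect_class="nonsynonymous")
    mat = np.asarray(presence, dtype=bool)
    n_samples = mat.shape[1]
    if n_samples < 2:
        raise ValidationError("apparent-clonal curve needs >= 2 samples")
    if rng is None:
        rng = np.random.default_rng(0)

    curve = np.empty(n_samples)
    cols = np.arange(n_samples)
    for n in range(1, n_samples + 1):
        if math.comb(n_samples, n) <= EXHAUSTIVE_SUBSET_LIMIT:
            subsets = list(combinations(cols, n))
        else:
            subsets = [
                rng.choice(cols, size=n, replace=False) for _ in range(n_subsets)
            ]
        counts = [mat[:, list(sub)].all(axis=1).sum() for sub in subsets]
        curve[n - 1] = float(np.mean(counts))
    return curve


def fit_balance_factor(curve) -> BalanceFit:
    """Least-squares fit of C(n) = c_inf + (C(1) - c_inf) * g**(n-1).

    Constraints 0 < g < 1 and 0 <= c_inf <= C(1).  A constant curve is
    degenerate (any g fits); it returns g at the lower boundary with
    c_inf = C(1).
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size < 3:
        raise ValidationError("balance-factor fit needs >= 3 curve points")
    c1 = curve[0]
    n = np.arange(1, curve.size + 1)
    eps = 1e-6

    if np.allclose(curve, c1):
        return BalanceFit(g=eps, c_inf=c1, curve=curve, residual=0.0)

    def residuals(theta):
        g, c_inf = theta
        return c_inf + (c1 - c_inf) * g ** (n - 1) - curve

    best = None
    for g0 in (0.2, 0.5, 0.8):
        sol = least_squares(
            residuals,
            x0=[g0, max(curve[-1], 0.0)],
            bounds=([eps, 0.0], [1.0 - eps, max(c1, eps)]),
        )
        if best is None or sol.cost < best.cost:
            best = sol
    g, c_inf = best.x
    return BalanceFit(g=float(g), c_inf=float(c_inf), curve=curve,
                      residual=float(np.sqrt(2 * best.cost)))


def p_correct(g: float, n: int) -> float:
    """Probability of correct clonal identification with n samples."""
    if not 0 < g < 1:
        raise ConfigurationError(f"balance factor g {g} outside (0, 1)")
    return 1.0 - g ** n


def samples_needed(g: float, p_target: float) -> tuple[int, float]:
    """Minimal n with 1 - g**n >= p_target, and the achieved probability."""
    if not 0 < g < 1:
        raise ConfigurationError(f"balance factor g {g} outside (0, 1)")
    if not 0 < p_target < 1:
        raise ConfigurationError(f"p_target {p_target} outside (0, 1)")
    n = max(1, math.ceil(math.log(1.0 - p_target) / math.log(g)))
    # guard against float edge cases at the ceiling boundary
    while 1.0 - g ** n < p_target:
        n += 1
    while n > 1 and 1.0 - g ** (n - 1) >= p_target:
        n -= 1
    return n, p_correct(g, n)
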