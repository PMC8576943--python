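import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from multiregion import clonality as c
from multiregion import simdata as s
from multiregion import variants as v
from multiregion.errors import ConfigurationError, ValidationError

from conftest import build_table


class TestComputeCcf:
    def test_pure_diploid_heterozygous(self):
        est = c.compute_ccf(50, 100, purity=1.0, cn_tumor=2)
        assert est.vaf == 0.5
        assert est.multiplicity == 1
        assert est.ccf == pytest.approx(1.0)

    def test_purity_adjustment(self):
        est = c.compute_ccf(30, 100, purity=0.8, cn_tumor=2)
        assert est.multiplicity == 1
        assert est.ccf == pytest.approx(0.3 * 2 / 0.8)

    def test_ci_matches_exact_binomial_oracle(self):
        # independent exact Clopper-Pearson from scipy.binomtest
        for alt, depth, rho in [(30, 100, 0.8), (5, 40, 1.0), (90, 100, 0.6)]:
            est = c.compute_ccf(alt, depth, purity=rho, cn_tumor=2)
            oracle = binomtest(alt, depth).proportion_ci(confidence_level=0.95,
                                                        method="exact")
            scale = (rho * 2 + (1 - rho) * 2) / (rho * est.multiplicity)
            assert est.ci_low == pytest.approx(min(oracle.low * scale, c.CCF_CAP))
            assert est.ci_high == pytest.approx(min(oracle.high * scale, c.CCF_CAP))
            expected = "subclonal" if min(oracle.high * scale, c.CCF_CAP) < 0.95 else "clonal"
            assert est.status == expected

    def test_zero_depth_not_assessable(self):
        assert c.compute_ccf(0, 0, 1.0, 2).status == "not_assessable"

    def test_monotone_in_alt_reads_and_scale_invariant(self):
        # monotone within a fixed-multiplicity regime (the nearest-integer
        # multiplicity estimator resets the scale when it jumps)
        ccfs = [c.compute_ccf(a, 100, 1.0, 2).ccf for a in range(1, 60, 5)]
        assert all(x <= y + 1e-12 for x, y in zip(ccfs, ccfs[1:]))
        small = c.compute_ccf(30, 100, 0.8, 2)
        big = c.compute_ccf(300, 1000, 0.8, 2)
        assert big.ccf == pytest.approx(small.ccf)
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)


class TestPerPatient:
    def _table(self, calls):
        return v.recover_variants(v.apply_filters(build_table(calls)))

    def test_pooling_halves_subclonal_vaf(self):
        t = self._table({"v": {"calls": {"A": (100, 30), "B": (100, 0)}}})
        pooled = c.per_patient_clonality(t).set_index("variant_id").loc["v"]
        assert pooled["vaf"] == pytest.approx(0.15)
        assert pooled["ccf"] == pytest.approx(0.30)
        assert pooled["status"] == "subclonal"

    def test_symmetric_pooling_is_clonal(self):
        t = self._table({"v": {"calls": {"A": (100, 50), "B": (100, 50)}}})
        pooled = c.per_patient_clonality(t).set_index("variant_id").loc["v"]
        assert pooled["ccf"] == pytest.approx(1.0)
        assert pooled["status"] == "clonal"

    def test_single_sample_patient_equals_per_sample(self):
        spec = {"v": {"calls": {"A": (200, 80)}}}
        meta = {"A": (0.9, "primary"), "N": (1.0, "normal")}
        t = v.recover_variants(v.apply_filters(build_table(spec, meta)))
        per_sample = c.per_sample_clonality(t).iloc[0]
        pooled = c.per_patient_clonality(t).iloc[0]
        for col in ("vaf", "ccf", "ci_low", "ci_high", "status"):
            assert per_sample[col] == pooled[col]

    def test_no_coverage_anywhere_not_assessable(self):
        spec = {"v": {"calls": {"A": (0, 0), "B": (0, 0)}}}
        t = self._table(spec)
        pooled = c.per_patient_clonality(t).iloc[0]
        assert pooled["status"] == "not_assessable"


class TestClonalIllusion:
    def test_branch_confined_clonal_variant_flagged(self):
        # clonal within region A (CCF ~ 1) but absent from region B
        spec = {
            "trunk": {"calls": {"A": (400, 200), "B": (400, 200)}},
            "branch": {"calls": {"A": (400, 200), "B": (400, 0)}},
        }
        t = v.recover_variants(v.apply_filters(build_table(spec)))
        report = c.clonal_illusion_report(
            c.per_sample_clonality(t), c.per_patient_clonality(t)
        )
        assert list(report["variant_id"]) == ["branch"]
        assert report.iloc[0]["clonal_in_samples"] == ["A"]

    def test_truncal_simulated_variants_not_flagged(self, filtered_branched):
        truth, table = filtered_branched
        report = c.clonal_illusion_report(
            c.per_sample_clonality(table), c.per_patient_clonality(table)
        )
        flagged = set(report["variant_id"])
        truncal = {vid for vid, r in truth.records.items() if r.truly_clonal}
        assert not (flagged & truncal)

    def test_empty_inputs_give_empty_report(self):
        empty_ps = pd.DataFrame(columns=["variant_id", "sample_id", "status"])
        empty_pp = pd.DataFrame(columns=["variant_id", "status"])
        assert len(c.clonal_illusion_report(empty_ps, empty_pp)) == 0

    def test_mismatched_variant_sets_rejected(self):
        ps = pd.DataFrame([{"variant_id": "v", "sample_id": "A", "status": "clonal"}])
        pp = pd.DataFrame(columns=["variant_id", "status"])
        with pytest.raises(ValidationError):
            c.clonal_illusion_report(ps, pp)

    def test_per_patient_never_demotes_simulated_truncal_calls(self, filtered_branched):
        # pooled status of a truncal variant is clonal whenever the
        # per-sample evidence is unanimous
        truth, table = filtered_branched
        ps = c.per_sample_clonality(table)
        pp = c.per_patient_clonality(table).set_index("variant_id")
        for vid, rec in truth.records.items():
            if not rec.truly_clonal:
                continue
            statuses = set(ps.loc[ps["variant_id"] == vid, "status"])
            if statuses == {"clonal"}:
                assert pp.loc[vid, "status"] == "clonal"


class TestApparentClonalCurve:
    def test_truncal_plus_disjoint_privates(self):
        # every pair of samples shares exactly the truncal set
        data = np.zeros((10 + 6, 3), dtype=bool)
        data[:10] = True
        for i in range(6):
            data[10 + i, i % 3] = True
        curve = c.apparent_clonal_curve(pd.DataFrame(data, columns=list("ABC")))
        assert curve[0] == pytest.approx(10 + 2)
        assert curve[1] == pytest.approx(10)
        assert curve[2] == pytest.approx(10)

    def test_identical_samples_constant_curve(self):
        data = np.ones((7, 4), dtype=bool)
        curve = c.apparent_clonal_curve(pd.DataFrame(data, columns=list("ABCD")))
        assert np.allclose(curve, 7)

    def test_non_increasing_on_random_fixtures(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            mat = rng.uniform(size=(50, 6)) < rng.uniform(0.2, 0.9)
            curve = c.apparent_clonal_curve(pd.DataFrame(mat), rng=rng)
            assert all(a >= b - 1e-9 for a, b in zip(curve, curve[1:]))

    def test_requires_two_samples(self):
        with pytest.raises(ValidationError):
            c.apparent_clonal_curve(pd.DataFrame(np.ones((3, 1), dtype=bool)))


class TestBalanceFit:
    def test_exact_geometric_curve_inverted(self):
        n = np.arange(1, 9)
        curve = 100 + 50 * 0.5 ** (n - 1)
        fit = c.fit_balance_factor(curve)
        assert fit.g == pytest.approx(0.5, abs=1e-6)
        assert fit.c_inf == pytest.approx(100, abs=1e-4)

    def test_constant_curve_degenerates_to_boundary(self):
        fit = c.fit_balance_factor(np.full(6, 42.0))
        assert fit.g <= 1e-6
        assert fit.c_inf == pytest.approx(42.0)

    def test_underdetermined_curve_rejected(self):
        with pytest.raises(ValidationError):
            c.fit_balance_factor([10.0, 5.0])

    def test_recovery_within_tenth_on_simulated_tumors(self):
        # median over 20 seeds of the fitted g on i.i.d.-membership tumors
        for g_true in (0.3, 0.6):
            fits = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                pres = s.simulate_balanced_presence(8, 30, 300, g_true, rng)
                curve = c.apparent_clonal_curve(pres, rng=rng)
                fits.append(c.fit_balance_factor(curve).g)
            assert abs(np.median(fits) - g_true) <= 0.1


class TestSamplesNeeded:
    def test_vanishing_g_needs_single_sample(self):
        n, p = c.samples_needed(1e-9, 0.9)
        assert n == 1 and p > 0.9999

    def test_moderate_balance_factor(self):
        # g = 0.56 reaches 90% already at n = 4 under this model
        n, p = c.samples_needed(0.56, 0.90)
        assert n == 4
        assert c.p_correct(0.56, 4) == pytest.approx(1 - 0.56**4)
        assert c.p_correct(0.56, 5) == pytest.approx(0.94493, abs=1e-4)

    def test_low_balance_factor(self):
        n, _ = c.samples_needed(0.2, 0.98)
        assert n == 3  # ln 0.02 / ln 0.2 = 2.43

    def test_boundary_g_rejected(self):
        for g in (0.0, 1.0, -0.1):
            with pytest.raises(ConfigurationError):
                c.samples_needed(g, 0.9)

    def test_p_correct_monotone_and_n_monotone(self):
        ps = [c.p_correct(0.5, n) for n in range(1, 10)]
        assert all(a < b for a, b in zip(ps, ps[1:]))
        ns = [c.samples_needed(g, 0.9)[0] for g in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a <= b for a, b in zip(ns, ns[1:]))
        ns_p = [c.samples_needed(0.5, p)[0] for p in (0.5, 0.8, 0.9, 0.99)]
        assert all(a <= b for a, b in zip(ns_p, ns_p[1:]))
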