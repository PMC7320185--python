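"""SMR statistic, Wald ratio, HEIDI, FDR and the decision rule.

Each statistic is checked against the independent oracle the design calls
for: numerical integration of the chi-square density for SMR p-values, a
brute-force step-up construction for BH-FDR, and Monte-Carlo sampling of the
chi-square mixture for the HEIDI tail.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from smrcoloc.ld import LDView
from smrcoloc.smr import (
    HEIDIResult,
    SMRResult,
    UndefinedStatistic,
    bh_fdr,
    classify_probe,
    heidi_test,
    mixture_chi2_sf,
    smr_statistic,
    wald_ratio,
)


def chi2_upper_tail_by_integration(t: float) -> float:
    """Oracle: integrate the 1-df chi-square density from t to infinity."""
    val, _ = integrate.quad(lambda x: stats.chi2.pdf(x, df=1), t, np.inf)
    return val


class TestSmrStatistic:
    def test_equal_z_gives_half_square(self):
        t, _ = smr_statistic(4.0, 4.0)
        assert t == pytest.approx(8.0)

    def test_limit_as_one_z_dominates(self):
        t, _ = smr_statistic(3.0, 1e9)
        assert t == pytest.approx(9.0, rel=1e-12)

    def test_value_and_p_against_integration_oracle(self):
        t, p = smr_statistic(5.0, 4.0)
        assert t == pytest.approx(400.0 / 41.0)
        assert abs(p - chi2_upper_tail_by_integration(t)) < 1e-10

    def test_both_zero_is_undefined(self):
        with pytest.raises(UndefinedStatistic):
            smr_statistic(0.0, 0.0)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetric_and_bounded_by_min_square(self, zg, ze):
        if zg**2 + ze**2 == 0:  # undefined corner (incl. underflow)
            return
        t, _ = smr_statistic(zg, ze)
        t_swap, _ = smr_statistic(ze, zg)
        assert t == pytest.approx(t_swap, rel=1e-12, abs=1e-12)
        assert t <= min(zg**2, ze**2) + 1e-9


class TestWaldRatio:
    def test_simple_ratio(self):
        b, _ = wald_ratio(0.1, 0.02, 0.2, 0.04)
        assert b == pytest.approx(0.5)

    def test_sign_flips_with_eqtl_effect(self):
        b_pos, _ = wald_ratio(0.1, 0.02, 0.2, 0.04)
        b_neg, _ = wald_ratio(0.1, 0.02, -0.2, 0.04)
        assert b_neg == pytest.approx(-b_pos)

    def test_delta_method_se(self):
        # both z = 5 -> se = 0.5 * sqrt(2/25)
        _, se = wald_ratio(0.1, 0.02, 0.2, 0.04)
        assert se == pytest.approx(0.5 * np.sqrt(2.0 / 25.0), rel=1e-12)

    def test_zero_eqtl_effect_is_undefined(self):
        with pytest.raises(UndefinedStatistic):
            wald_ratio(0.1, 0.02, 0.0, 0.04)


def brute_force_bh(p):
    """Step-up definition applied literally: q_(i) = min over j>=i of
    min(1, m*p_(j)/j) on the sorted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        q_sorted[rank - 1] = min(
            min(1.0, m * p[jdx] / j)
            for j, jdx in enumerate(order[rank - 1:], start=rank)
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBhFdr:
    def test_textbook_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_value_unchanged(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    def test_ceiling_at_one(self):
        assert bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_exhaustive_agreement_with_step_up_oracle(self, rng):
        for n in range(1, 13):
            for _ in range(25):
                p = rng.uniform(1e-6, 1.0, size=n)
                assert bh_fdr(p) == pytest.approx(brute_force_bh(p), rel=1e-12)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(0, 1, 30)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestMixtureTail:
    @pytest.mark.parametrize(
        "lam,x",
        [
            ([3.5, 2.2, 0.8, 0.6, 0.4], 8.0),
            ([1.0, 1.0, 1.0, 1.0, 1.0, 1.0], 20.0),
            ([2.0, 1.5, 1.0, 0.5, 0.3, 0.2, 0.1], 2.0),
        ],
    )
    def test_within_three_mc_standard_errors(self, lam, x):
        lam = np.array(lam)
        p, method = mixture_chi2_sf(x, lam)
        rng = np.random.default_rng(12345)
        draws = rng.standard_normal((200_000, lam.size)) ** 2 @ lam
        p_mc = float((draws >= x).mean())
        se = np.sqrt(p_mc * (1 - p_mc) / draws.size)
        assert abs(p - p_mc) <= 3 * se

    def test_single_weight_reduces_to_chi2(self):
        p, _ = mixture_chi2_sf(3.84, np.array([1.0]))
        assert p == pytest.approx(stats.chi2.sf(3.84, 1), abs=1e-6)

    def test_degenerate_inputs(self):
        assert mixture_chi2_sf(0.0, np.array([1.0]))[0] == 1.0
        assert mixture_chi2_sf(5.0, np.array([]))[0] == 1.0


def build_heidi_inputs(n_snps, rho, zg_top=8.0, ze_top=10.0, hetero=0.0, seed=0):
    """Harmonized records + LD for a synthetic HEIDI configuration.

    ``hetero`` shifts the GWAS effects of non-top SNPs away from the shared
    Wald ratio, creating heterogeneity.
    """
    rng = np.random.default_rng(seed)
    idx = np.arange(n_snps)
    r = rho ** np.abs(np.subtract.outer(idx, idx))
    rsids = [f"rs{i + 1}" for i in idx]
    ze = ze_top * r[0]
    zg = zg_top * r[0] + hetero * np.where(idx > 0, rng.standard_normal(n_snps), 0)
    se_g, se_e = 0.01, 0.05
    rec = pd.DataFrame(
        {
            "rsid": rsids,
            "pos": 100 + idx,
            "b_gwas": zg * se_g, "se_gwas": se_g, "z_gwas": zg,
            "p_gwas": 2 * stats.norm.sf(np.abs(zg)),
            "b_eqtl": ze * se_e, "se_eqtl": se_e, "z_eqtl": ze,
            "maf_gwas": 0.3, "maf_eqtl": 0.3,
        }
    )
    return rec, LDView(rsids, r)


class TestHeidi:
    def test_perfect_homogeneity_gives_p_one(self):
        # all SNPs in perfect LD with identical statistics: d == 0
        rec, _ = build_heidi_inputs(5, rho=0.999)
        rsids = list(rec["rsid"])
        ld = LDView(rsids, np.ones((5, 5)))
        rec = rec.assign(
            b_gwas=0.08, z_gwas=8.0, b_eqtl=0.5, z_eqtl=10.0
        )
        res = heidi_test(rec, ld, "rs1", r2_window=(0.0, 1.0))
        assert res.status == "tested"
        assert res.p_heidi == 1.0

    def test_cap_at_twenty_candidates(self):
        rec, ld = build_heidi_inputs(22, rho=0.7)
        res = heidi_test(rec, ld, "rs1", r2_window=(0.0, 1.0))
        assert res.snps_used == 20

    def test_too_few_candidates_skips(self):
        rec, ld = build_heidi_inputs(3, rho=0.7)
        res = heidi_test(rec, ld, "rs1", r2_window=(0.0, 1.0))
        assert res.status == "skipped_too_few_snps"
        assert res.p_heidi is None

    def test_r2_window_excludes_near_perfect_and_weak_ld(self):
        rec, ld = build_heidi_inputs(10, rho=0.8)
        res = heidi_test(rec, ld, "rs1", r2_window=(0.05, 0.9))
        r2 = np.array([ld.r2_of(f"rs{i + 1}", "rs1") for i in range(1, 10)])
        assert res.snps_used == int(((r2 >= 0.05) & (r2 <= 0.9)).sum())

    def test_p_value_against_mixture_mc_oracle(self):
        rec, ld = build_heidi_inputs(8, rho=0.75, hetero=1.5, seed=4)
        res = heidi_test(rec, ld, "rs1", r2_window=(0.0, 1.0))
        assert res.status == "tested" and res.eigenvalues is not None
        rng = np.random.default_rng(99)
        draws = rng.standard_normal((200_000, res.eigenvalues.size)) ** 2 @ res.eigenvalues
        p_mc = float((draws >= res.stat).mean())
        se = max(np.sqrt(p_mc * (1 - p_mc) / draws.size), 1e-6)
        assert abs(res.p_heidi - p_mc) <= 3 * se

    def test_heterogeneity_lowers_p(self):
        rec0, ld = build_heidi_inputs(10, rho=0.75, hetero=0.0)
        rec1, _ = build_heidi_inputs(10, rho=0.75, hetero=4.0, seed=2)
        p0 = heidi_test(rec0, ld, "rs1", r2_window=(0.0, 1.0)).p_heidi
        p1 = heidi_test(rec1, ld, "rs1", r2_window=(0.0, 1.0)).p_heidi
        assert p1 < p0


class TestClassifyProbe:
    def make(self, q, p_heidi, status="tested", n=5):
        smr = SMRResult("p1", "G", "blood", "rs1", 0.1, 0.02, 30.0, 1e-7, q_fdr=q)
        heidi = HEIDIResult("p1", "blood", n, p_heidi, status)
        return smr, heidi

    @pytest.mark.parametrize(
        "q,p_heidi,status,expected",
        [
            (0.01, 0.5, "tested", "pass"),
            (0.01, 0.001, "tested", "pass"),        # boundary: >= is a pass
            (0.01, 0.0005, "tested", "fail_heidi"),
            (0.2, 0.5, "tested", "fail_smr"),
            (0.05, 0.5, "tested", "fail_smr"),      # boundary: FDR < 0.05 strict
            (0.01, None, "skipped_too_few_snps", "untested_heidi"),
        ],
    )
    def test_decision_rule(self, q, p_heidi, status, expected):
        smr, heidi = self.make(q, p_heidi, status)
        assert classify_probe(smr, heidi) == expected

    def test_mismatched_probe_ids_raise(self):
        smr, heidi = self.make(0.01, 0.5)
        heidi.probe_id = "other"
        with pytest.raises(ValueError, match="mismatch"):
            classify_probe(smr, heidi)
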