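"""LV volumes/EF and the agreement statistics (Bland-Altman, Welch,
Wilcoxon signed-rank)."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spiralcine.lv_function import (AnalysisError, SegmentationMasks,
                                    bland_altman, compute_volumes,
                                    functional_report, limits_of_agreement,
                                    report_from_volumes, segment_blood_pool,
                                    select_ed_es, welch_t_test,
                                    wilcoxon_signed_rank)
from spiralcine.phantom import PhantomConfig, make_lv_phantom


def _masks_from_counts(endo_counts, voxel_mm=(8.0, 2.47, 2.47)):
    n_ph = len(endo_counts)
    endo = np.zeros((n_ph, 4, 32, 32), bool)
    epi = np.zeros_like(endo)
    for p, c in enumerate(endo_counts):
        flat = endo[p].reshape(-1)
        flat[:c] = True
        epi_flat = epi[p].reshape(-1)
        epi_flat[: c + 100] = True
    return SegmentationMasks(endo=endo, epi=epi, voxel_mm=voxel_mm)


class TestVolumes:
    def test_thousand_voxels(self):
        masks = _masks_from_counts([1000, 500])
        blood, myo = compute_volumes(masks, 0)
        assert blood == pytest.approx(48.8, abs=0.05)  # 1000 x 48.81 mm^3
        assert myo == pytest.approx(100 * 2.47 * 2.47 * 8 / 1000, rel=1e-9)

    def test_empty_mask_zero_volume(self):
        masks = _masks_from_counts([0, 10])
        blood, _ = compute_volumes(masks, 0)
        assert blood == 0.0

    def test_rasterized_half_ellipsoid_close_to_closed_form(self):
        cfg = PhantomConfig(supersample=1)
        vol, vb, _ = make_lv_phantom(cfg, 0.0)
        endo = (vol > 0.675)[None]
        epi = (vol > 0.25)[None]
        masks = SegmentationMasks(endo=endo, epi=epi, voxel_mm=cfg.voxel_mm)
        blood, _ = compute_volumes(masks, 0)
        assert blood == pytest.approx(vb, rel=0.02)

    def test_endo_outside_epi_rejected(self):
        endo = np.ones((1, 2, 4, 4), bool)
        epi = np.zeros_like(endo)
        with pytest.raises(AnalysisError, match="inside"):
            SegmentationMasks(endo=endo, epi=epi, voxel_mm=(8, 2, 2))


class TestEdEsSelection:
    def test_contract_recover_series(self):
        v = np.array([100, 80, 55, 40, 37, 45, 70, 95])
        assert select_ed_es(v) == (0, 4)

    def test_constant_series_tie_rule(self):
        assert select_ed_es(np.ones(5)) == (0, 0)

    def test_needs_two_phases(self):
        with pytest.raises(AnalysisError):
            select_ed_es(np.array([1.0]))


class TestFunctionalReport:
    def test_ef_formula(self):
        fr = report_from_volumes(np.array([100.0, 37.0]),
                                 np.array([100.0, 120.0]))
        assert fr.ef_pct == pytest.approx(63.0)
        assert fr.sv_ml == pytest.approx(63.0)
        assert fr.edm_g == pytest.approx(105.0)  # 100 mL x 1.05 g/mL

    def test_no_motion_zero_ef(self):
        fr = report_from_volumes(np.array([50.0, 50.0]),
                                 np.array([30.0, 30.0]))
        assert fr.ef_pct == 0.0

    def test_zero_edv_rejected(self):
        with pytest.raises(AnalysisError):
            report_from_volumes(np.zeros(3), np.zeros(3))

    def test_from_masks(self):
        masks = _masks_from_counts([1000, 370])
        fr = functional_report(masks)
        assert fr.ef_pct == pytest.approx(63.0)


class TestSegmentBloodPool:
    def test_bright_region_segmented(self):
        vol = np.full((2, 2, 16, 16), 0.1)
        vol[:, :, 4:10, 4:10] = 1.0
        mask = segment_blood_pool(vol)
        assert mask[0, 0, 5, 5]
        assert not mask[0, 0, 0, 0]
        assert mask.sum() == 2 * 2 * 36

    def test_roi_restricts_mask(self):
        vol = np.full((1, 2, 16, 16), 1.0)
        roi = (slice(None), slice(0, 8), slice(None))
        mask = segment_blood_pool(vol, roi=roi)
        assert mask[:, :, 8:].sum() == 0


class TestBlandAltman:
    @pytest.mark.parametrize("bias,sd,expected", [
        (-1.6, 3.8, (-9.0, 5.8)),   # end-diastolic volume agreement
        (-0.1, 0.8, (-1.7, 1.5)),   # ejection fraction agreement
    ])
    def test_limits_match_printed_table(self, bias, sd, expected):
        lo, hi = limits_of_agreement(bias, sd)
        assert (round(lo, 1), round(hi, 1)) == expected

    def test_identical_pairs(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (ba.bias, ba.sd, ba.lower, ba.upper) == (0, 0, 0, 0)

    def test_limits_symmetric_about_bias(self):
        rng = np.random.default_rng(0)
        ba = bland_altman(rng.normal(size=30), rng.normal(size=30))
        assert ba.upper - ba.bias == pytest.approx(ba.bias - ba.lower)

    def test_coverage_on_gaussian_differences(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=5000)
        b = rng.normal(size=5000)
        ba = bland_altman(a, b)
        d = a - b
        frac = np.mean((d >= ba.lower) & (d <= ba.upper))
        assert frac >= 0.93

    def test_too_few_pairs(self):
        with pytest.raises(AnalysisError):
            bland_altman([1.0], [2.0])

    def test_plot_draws_bias_and_limits(self):
        import matplotlib
        matplotlib.use("Agg")
        from spiralcine.lv_function import plot_bland_altman
        rng = np.random.default_rng(4)
        ax = plot_bland_altman(rng.normal(size=10), rng.normal(size=10))
        assert len(ax.lines) == 3  # bias + two limits


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1, 2, 3.0], [1, 2, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_reduces_to_student_for_equal_variance_equal_n(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        from scipy import stats
        welch = welch_t_test(a, b)
        student = stats.ttest_ind(a, b, equal_var=True)
        assert welch.t == pytest.approx(float(student.statistic), abs=1e-10)

    def test_matches_independent_oracle(self):
        # reference values computed with R's t.test (Welch)
        a = [2.3, 1.9, 3.1, 2.7, 2.2]
        b = [1.1, 1.8, 0.9, 1.4, 2.0]
        res = welch_t_test(a, b)
        assert res.t == pytest.approx(3.406013516451, abs=1e-8)
        assert res.df == pytest.approx(7.998923492621, abs=1e-8)
        assert res.p == pytest.approx(9.2794923377e-3, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(AnalysisError):
            welch_t_test([1.0, 1.0], [2.0, 2.0])


def _enumeration_p(diffs):
    """Brute-force two-sided exact p over all sign assignments."""
    from scipy.stats import rankdata
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(ranks)
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=n)]
    ws = np.array(ws)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestWilcoxon:
    def test_antisymmetric_differences(self):
        d = [1.0, -1.0, 2.0, -2.0, 3.0, -3.0]
        res = wilcoxon_signed_rank(d)
        n = 6
        assert res.w == n * (n + 1) / 4
        assert res.p == 1.0

    def test_textbook_eight_pairs_matches_enumeration(self):
        d = [1.2, -0.8, 2.5, 3.1, -0.4, 1.9, 2.2, 0.7]
        res = wilcoxon_signed_rank(d)
        assert res.exact
        assert res.w == 32.0                      # R wilcox.test V statistic
        assert res.p == pytest.approx(0.0546875)  # R exact p
        assert res.p == pytest.approx(_enumeration_p(d))

    def test_all_negative_ten_pairs(self):
        res = wilcoxon_signed_rank([-float(i) for i in range(1, 11)])
        assert res.w == 0.0
        assert res.p == pytest.approx(2.0 / 2 ** 10)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(-5, 5), min_size=2, max_size=10))
    def test_exact_p_equals_enumeration(self, diffs):
        d = [float(x) for x in diffs]
        if all(x == 0 for x in d):
            with pytest.raises(AnalysisError):
                wilcoxon_signed_rank(d)
            return
        res = wilcoxon_signed_rank(d)
        assert res.p == pytest.approx(_enumeration_p(d), abs=1e-12)

    def test_zeros_discarded(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 1.0, -2.0, 3.0])
        assert res.n == 3

    def test_all_zero_rejected(self):
        with pytest.raises(AnalysisError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.3, 1.0, size=40)
        res = wilcoxon_signed_rank(d)
        assert not res.exact
        from scipy import stats
        ref = stats.wilcoxon(d, zero_method="wilcox", correction=False,
                             method="approx")
        assert res.p == pytest.approx(float(ref.pvalue), rel=1e-9)
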