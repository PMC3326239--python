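import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from petseg.metrics import (
    classification_error,
    evaluate_segmentation,
    paired_ttest,
    relative_volume_error,
    spatial_overlap_index,
    summarize_cohort,
)
from petseg.volume import BinaryMask


def mask_from_bits(bits, shape=(4, 4, 4), spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.array(bits, dtype=bool).reshape(shape), spacing)


bitmask = st.lists(st.booleans(), min_size=64, max_size=64)


class TestSOI:
    def test_identical_nonempty_masks(self):
        m = mask_from_bits(np.arange(64) % 3 == 0)
        assert spatial_overlap_index(m, m) == 1.0

    def test_disjoint_masks(self):
        a = mask_from_bits(np.arange(64) < 10)
        b = mask_from_bits(np.arange(64) >= 50)
        assert spatial_overlap_index(a, b) == 0.0

    def test_half_overlap(self):
        a = mask_from_bits(np.arange(64) < 8)
        b = mask_from_bits((np.arange(64) >= 4) & (np.arange(64) < 12))
        assert spatial_overlap_index(a, b) == 0.5

    def test_both_empty_convention(self):
        e = mask_from_bits([False] * 64)
        assert spatial_overlap_index(e, e) == 1.0

    def test_one_empty(self):
        e = mask_from_bits([False] * 64)
        a = mask_from_bits(np.arange(64) < 5)
        assert spatial_overlap_index(a, e) == 0.0

    def test_shape_mismatch_rejected(self):
        a = mask_from_bits(np.arange(64) < 5)
        b = BinaryMask(np.zeros((2, 4, 8), dtype=bool), (1.0,) * 3)
        with pytest.raises(ValueError):
            spatial_overlap_index(a, b)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(bitmask, bitmask)
    def test_matches_brute_force_counting(self, bits_a, bits_b):
        a, b = mask_from_bits(bits_a), mask_from_bits(bits_b)
        na = sum(bits_a)
        nb = sum(bits_b)
        inter = sum(x and y for x, y in zip(bits_a, bits_b))
        expected = 1.0 if na + nb == 0 else 2 * inter / (na + nb)
        soi = spatial_overlap_index(a, b)
        assert abs(soi - expected) < 1e-12
        assert 0.0 <= soi <= 1.0
        assert soi == spatial_overlap_index(b, a)  # symmetry


class TestCE:
    def test_perfect_segmentation(self):
        m = mask_from_bits(np.arange(64) % 2 == 0)
        assert classification_error(m, m) == (0, 0, 0.0)

    def test_direct_substitution(self):
        ref = mask_from_bits(np.arange(64) < 32)  # VoIL = 32
        seg_bits = (np.arange(64) >= 8) & (np.arange(64) < 36)
        seg = mask_from_bits(seg_bits)
        pce, nce, ce = classification_error(seg, ref)
        assert pce == 4 and nce == 8
        assert ce == pytest.approx(100.0 * 12 / 32)

    def test_gross_oversegmentation_exceeds_100(self):
        ref = mask_from_bits(np.arange(64) < 10)
        seg = mask_from_bits(np.arange(64) < 35)  # 2.5x superset + spill
        pce, nce, ce = classification_error(seg, ref)
        assert nce == 0 and pce == 25
        assert ce == 250.0  # > 100% is legal

    def test_not_symmetric(self):
        a = mask_from_bits(np.arange(64) < 10)
        b = mask_from_bits(np.arange(64) < 30)
        assert classification_error(a, b)[2] != classification_error(b, a)[2]

    def test_empty_reference_rejected(self):
        seg = mask_from_bits(np.arange(64) < 5)
        with pytest.raises(ValueError):
            classification_error(seg, mask_from_bits([False] * 64))

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(bitmask, bitmask)
    def test_matches_brute_force_counting(self, bits_seg, bits_ref):
        if not any(bits_ref):
            return
        seg, ref = mask_from_bits(bits_seg), mask_from_bits(bits_ref)
        pce = sum(s and not r for s, r in zip(bits_seg, bits_ref))
        nce = sum(r and not s for s, r in zip(bits_seg, bits_ref))
        got = classification_error(seg, ref)
        assert got[0] == pce and got[1] == nce
        assert abs(got[2] - 100.0 * (pce + nce) / sum(bits_ref)) < 1e-12

    def test_monotone_under_erosion(self):
        # eroding seg away from ref lowers SOI and raises CE
        ref_bits = np.arange(64) < 40
        ref = mask_from_bits(ref_bits)
        sois, ces = [], []
        for keep in (40, 30, 20, 10):
            seg = mask_from_bits(np.arange(64) < keep)
            sois.append(spatial_overlap_index(seg, ref))
            ces.append(classification_error(seg, ref)[2])
        assert np.all(np.diff(sois) < 0)
        assert np.all(np.diff(ces) > 0)


class TestRelVolErr:
    def test_identical_masks(self):
        m = mask_from_bits(np.arange(64) < 20)
        assert relative_volume_error(m, m) == 0.0

    def test_underestimation_negative(self):
        ref = mask_from_bits(np.arange(64) < 50)  # 100 -> use 50 voxels
        seg = mask_from_bits(np.arange(64) < 47)
        assert relative_volume_error(seg, ref) == pytest.approx(-6.0)

    def test_spacing_cancels(self):
        bits_a = np.arange(64) < 20
        bits_b = np.arange(64) < 25
        e1 = relative_volume_error(
            mask_from_bits(bits_a, spacing=(1.0,) * 3), mask_from_bits(bits_b, spacing=(1.0,) * 3)
        )
        e2 = relative_volume_error(
            mask_from_bits(bits_a, spacing=(2.0,) * 3), mask_from_bits(bits_b, spacing=(2.0,) * 3)
        )
        assert e1 == e2


class TestPairedT:
    def test_identical_lists(self):
        r = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 1.0 and r.degenerate

    def test_constant_nonzero_difference_degenerate(self):
        r = paired_ttest([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isinf(r.t) and r.degenerate and r.p == 0.0

    def test_hand_computed_oracle(self):
        d = np.array([2.0, -1.0, 3.0, 0.0, 1.0, -2.0, 4.0])
        x = d + 10.0
        y = np.full(7, 10.0)
        r = paired_ttest(x, y)
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(7))
        assert r.t == pytest.approx(t_hand, abs=1e-10)
        assert r.df == 6
        assert r.p == pytest.approx(2 * stats.t.sf(abs(t_hand), 6), abs=1e-12)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5, 1, 12)
        y = rng.normal(4.5, 1, 12)
        r = paired_ttest(x, y)
        ref = stats.ttest_rel(x, y)
        assert r.t == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [2.0])


class TestSummarize:
    def _records(self):
        rows = []
        data = {
            "a": [(0.8, 10.0, 12.0), (0.6, 8.0, 10.0), (0.7, 9.0, 9.0)],
            "b": [(0.5, 15.0, 12.0), (0.4, 14.0, 10.0), (0.45, 10.0, 9.0)],
        }
        for method, cases in data.items():
            for i, (soi, segv, refv) in enumerate(cases):
                rows.append(
                    dict(
                        case=f"c{i}",
                        method=method,
                        failed=False,
                        soi=soi,
                        ce_percent=100.0 * abs(segv - refv) / refv,
                        seg_volume_cm3=segv,
                        ref_volume_cm3=refv,
                        rel_vol_err_percent=100.0 * (segv - refv) / refv,
                    )
                )
        return pd.DataFrame(rows)

    def test_against_spreadsheet_arithmetic(self):
        s = summarize_cohort(self._records())
        assert s.loc["a", "soi_mean"] == pytest.approx((0.8 + 0.6 + 0.7) / 3)
        assert s.loc["a", "soi_sd"] == pytest.approx(np.std([0.8, 0.6, 0.7], ddof=1))
        assert s.loc["a", "soi_min"] == 0.6 and s.loc["a", "soi_max"] == 0.8
        assert s.loc["b", "seg_volume_mean_cm3"] == pytest.approx(13.0)
        tt = paired_ttest([15.0, 14.0, 10.0], [12.0, 10.0, 9.0])
        assert s.loc["b", "volume_p_value"] == pytest.approx(tt.p)

    def test_row_per_method_and_single_case(self):
        df = self._records()
        assert len(summarize_cohort(df)) == 2
        one = summarize_cohort(df[df["case"] == "c0"])
        assert one.loc["a", "soi_mean"] == 0.8
        assert one.loc["a", "soi_sd"] == 0.0

    def test_failed_rows_excluded(self):
        df = self._records()
        df.loc[len(df)] = dict(
            case="c3", method="a", failed=True, soi=np.nan, ce_percent=np.nan,
            seg_volume_cm3=np.nan, ref_volume_cm3=10.0, rel_vol_err_percent=np.nan,
        )
        s = summarize_cohort(df)
        assert s.loc["a", "n_cases"] == 3


class TestEvaluate:
    def test_record_internally_consistent(self):
        ref = mask_from_bits(np.arange(64) < 32)
        seg = mask_from_bits((np.arange(64) >= 8) & (np.arange(64) < 40))
        rec = evaluate_segmentation(seg, ref)
        assert rec.ce_percent == pytest.approx(100.0 * (rec.pce + rec.nce) / rec.voil)
        assert rec.voil == 32
        assert 0.0 <= rec.soi <= 1.0
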