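"""Dice, Added Path Length (vs brute-force oracles), exact Wilcoxon."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis.extra import numpy as hnp
from scipy.stats import rankdata

from fracseg.io import LabelMap
from fracseg.metrics import (MetricsReport, ToleranceSpec, added_path_length,
                             compare_methods, dice, evaluate_series,
                             extract_contour, wilcoxon_signed_rank)


# ---------------------------------------------------------------- oracles

def contour_pixels_oracle(mask2d):
    """Foreground pixels 4-adjacent to background or the grid edge."""
    pts = set()
    h, w = mask2d.shape
    for i in range(h):
        for j in range(w):
            if not mask2d[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not mask2d[ni, nj]:
                    pts.add((i, j))
                    break
    return pts


def apl_oracle(auto, ref, tol=1):
    """All-pairs Chebyshev-distance APL, slice by slice."""
    total = 0
    for k in range(auto.shape[2]):
        ac = contour_pixels_oracle(auto[:, :, k])
        rc = contour_pixels_oracle(ref[:, :, k])
        if not rc:
            total += len(ac)
            continue
        for (i, j) in ac:
            d = min(max(abs(i - ri), abs(j - rj)) for ri, rj in rc)
            if d > tol:
                total += 1
    return total


def wilcoxon_enumeration_oracle(x, y):
    """Two-sided p by full 2^n sign enumeration on midranked |differences|."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    mu = ranks.sum() / 2
    hits = sum(1 for signs in itertools.product((0, 1), repeat=len(d))
               if abs(sum(r for r, s in zip(ranks, signs) if s) - mu)
               >= abs(w - mu) - 1e-9)
    return hits / 2 ** len(d)


# ------------------------------------------------------------------- dice

class TestDice:
    def test_closed_form_cases(self, rng):
        m = rng.uniform(size=(8, 8, 4)) < 0.3
        assert dice(m, m) == 1.0
        a = np.zeros((4, 4, 2), bool); a[0, 0, 0] = True
        b = np.zeros((4, 4, 2), bool); b[1, 1, 1] = True
        assert dice(a, b) == 0.0
        a = np.zeros((4, 4), bool); a[0] = True          # |A| = 4
        b = np.zeros((4, 4), bool); b[:2, :2] = True      # |B| = 4, overlap 2
        assert dice(a, b) == 0.5
        assert dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0

    def test_symmetry_and_shape_check(self, rng):
        a = rng.uniform(size=(6, 6)) < 0.4
        b = rng.uniform(size=(6, 6)) < 0.4
        assert dice(a, b) == dice(b, a)
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


# ---------------------------------------------------------------- contour

class TestExtractContour:
    def test_empty_slice(self):
        assert not extract_contour(np.zeros((5, 5), bool)).any()

    def test_single_pixel_is_its_own_contour(self):
        m = np.zeros((5, 5), bool); m[2, 3] = True
        out = extract_contour(m)
        assert np.array_equal(out, m)

    def test_filled_square_has_perimeter_only(self):
        m = np.zeros((9, 9), bool); m[2:7, 2:7] = True
        out = extract_contour(m)
        assert int(out.sum()) == 16
        assert not out[3:6, 3:6].any()

    def test_matches_pixel_loop_oracle(self, rng):
        for _ in range(20):
            m = rng.uniform(size=(12, 12)) < 0.4
            got = {tuple(p) for p in np.argwhere(extract_contour(m))}
            assert got == contour_pixels_oracle(m)


# -------------------------------------------------------------------- APL

class TestAddedPathLength:
    def test_identical_masks_give_zero(self, rng):
        m = rng.uniform(size=(16, 16, 4)) < 0.3
        assert added_path_length(m, m) == 0

    def test_empty_reference_counts_whole_contour(self):
        auto = np.zeros((20, 20, 1), bool)
        auto[5:9, 5:9, 0] = True  # 4x4 square -> 12 contour pixels
        ref = np.zeros_like(auto)
        assert added_path_length(auto, ref) == 12

    def test_shifted_square_matches_oracle(self):
        ref = np.zeros((20, 20, 1), bool); ref[4:12, 4:12, 0] = True
        auto = np.zeros_like(ref); auto[7:15, 4:12, 0] = True
        assert added_path_length(auto, ref) == apl_oracle(auto, ref)

    def test_matches_brute_force_on_random_pairs(self, rng):
        """Exact integer agreement with the all-pairs oracle on 100 random
        32x32 slice pairs."""
        for _ in range(100):
            auto = rng.uniform(size=(32, 32, 1)) < rng.uniform(0.05, 0.5)
            ref = rng.uniform(size=(32, 32, 1)) < rng.uniform(0.05, 0.5)
            assert added_path_length(auto, ref) == apl_oracle(auto, ref)

    def test_nonincreasing_in_tolerance(self, rng):
        auto = rng.uniform(size=(24, 24, 2)) < 0.3
        ref = rng.uniform(size=(24, 24, 2)) < 0.3
        vals = [added_path_length(auto, ref, ToleranceSpec(tolerance_voxels=t))
                for t in range(5)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_direction_matters_and_flag_flips_it(self, rng):
        auto = np.zeros((16, 16, 1), bool); auto[2:14, 2:14, 0] = True
        ref = np.zeros_like(auto); ref[6:10, 6:10, 0] = True
        fwd = added_path_length(auto, ref)
        rev = added_path_length(auto, ref, ToleranceSpec(direction="ref_vs_auto"))
        assert fwd != rev
        assert rev == added_path_length(ref, auto)

    def test_euclidean_option(self):
        # diagonal offset of 1 pixel: Chebyshev distance 1 (in tolerance),
        # Euclidean sqrt(2) (out of tolerance)
        auto = np.zeros((8, 8, 1), bool); auto[2, 2, 0] = True
        ref = np.zeros_like(auto); ref[3, 3, 0] = True
        assert added_path_length(auto, ref) == 0
        assert added_path_length(auto, ref, ToleranceSpec(metric="euclidean")) == 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hnp.arrays(bool, (10, 10, 2)))
    def test_self_apl_always_zero(self, mask):
        assert added_path_length(mask, mask) == 0


# --------------------------------------------------------------- wilcoxon

class TestWilcoxon:
    def test_n5_all_positive_is_exact_sixteenth(self):
        assert wilcoxon_signed_rank(np.arange(1, 6.0), np.zeros(5)) == \
            pytest.approx(0.0625, abs=1e-12)

    def test_matches_enumeration_for_all_small_n(self, rng):
        for n in range(2, 9):
            for _ in range(20):
                x = rng.normal(size=n)
                y = rng.normal(size=n)
                if rng.uniform() < 0.4:
                    x, y = np.round(x), np.round(y)  # force ties/zeros
                if np.count_nonzero(x - y) == 0:
                    continue
                assert wilcoxon_signed_rank(x, y) == \
                    pytest.approx(wilcoxon_enumeration_oracle(x, y), abs=1e-12)

    def test_two_sided_symmetry(self, rng):
        x = rng.normal(size=12); y = rng.normal(size=12)
        assert wilcoxon_signed_rank(x, y) == wilcoxon_signed_rank(y, x)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="all differences zero"):
            wilcoxon_signed_rank(np.ones(4), np.ones(4))

    def test_large_n_matches_scipy_normal_approximation(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon
        x = rng.normal(size=40); y = rng.normal(size=40) + 0.2
        ours = wilcoxon_signed_rank(x, y)
        ref = float(scipy_wilcoxon(x, y, zero_method="wilcox",
                                   correction=True, method="approx").pvalue)
        assert ours == pytest.approx(ref, rel=1e-12)

    def test_exact_matches_scipy_when_no_ties(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon
        for _ in range(20):
            x = rng.normal(size=10); y = rng.normal(size=10)
            ref = float(scipy_wilcoxon(x, y, method="exact").pvalue)
            assert wilcoxon_signed_rank(x, y) == pytest.approx(ref, abs=1e-12)


# ------------------------------------------------------------ evaluation

def _series_pair(rng, perfect=True):
    pred, ref = {}, {}
    for frac in (2, 3):
        data = np.zeros((16, 16, 4), dtype=np.int16)
        data[2:8, 2:8, 1:3] = 1
        data[9:14, 2:8, 1:3] = 2
        data[2:8, 9:14, 1:3] = 3
        ref[frac] = LabelMap(data)
        if perfect:
            pred[frac] = LabelMap(data.copy())
        else:
            shifted = np.roll(data, rng.integers(1, 3), axis=0)
            pred[frac] = LabelMap(shifted)
    return pred, ref


class TestEvaluateSeries:
    def test_perfect_prediction(self, rng):
        pred, ref = _series_pair(rng)
        rep = evaluate_series(pred, ref)
        assert len(rep.rows) == 2 * 3
        assert np.all(rep.rows["dice"] == 1.0)
        assert np.all(rep.rows["apl"] == 0)

    def test_all_row_sums_structure_apls(self, rng):
        pred, ref = _series_pair(rng, perfect=False)
        rep = evaluate_series(pred, ref)
        per_frac = rep.rows.groupby("fraction")["apl"].sum()
        s = rep.summary()
        assert s.loc["all", "apl_mean"] == pytest.approx(per_frac.mean())

    def test_missing_fraction_rejected(self, rng):
        pred, ref = _series_pair(rng)
        del pred[3]
        with pytest.raises(ValueError, match="fraction sets differ"):
            evaluate_series(pred, ref)


class TestCompareMethods:
    def test_identical_reports_flagged_no_difference(self, rng):
        pred, ref = _series_pair(rng, perfect=False)
        a = evaluate_series(pred, ref, method_name="ann")
        b = evaluate_series(pred, ref, method_name="dir")
        comp = compare_methods(a, b)
        assert set(comp["note"]) == {"no difference"}
        assert comp["p_value"].isna().all()

    def test_known_difference_signs_match_enumeration(self, rng):
        """Six paired fractions with hand-built metric differences: the
        reported p equals the 2^6 enumeration oracle."""
        rows_a, rows_b = [], []
        dice_a = [0.90, 0.92, 0.88, 0.91, 0.93, 0.89]
        dice_b = [0.80, 0.85, 0.91, 0.84, 0.86, 0.90]
        for i in range(6):
            base = {"patient_id": "p", "fraction": i + 2, "structure": "ctv"}
            rows_a.append({**base, "method": "a", "dice": dice_a[i], "apl": 10 + i})
            rows_b.append({**base, "method": "b", "dice": dice_b[i], "apl": 12 + i})
        a = MetricsReport(rows=pd.DataFrame(rows_a), method="a")
        b = MetricsReport(rows=pd.DataFrame(rows_b), method="b")
        comp = compare_methods(a, b)
        got = float(comp[(comp.structure == "ctv") & (comp.metric == "dice")]
                    ["p_value"].iloc[0])
        assert got == pytest.approx(
            wilcoxon_enumeration_oracle(np.array(dice_a), np.array(dice_b)),
            abs=1e-12)

    def test_mismatched_index_rejected(self, rng):
        pred, ref = _series_pair(rng, perfect=False)
        a = evaluate_series(pred, ref, method_name="a")
        b = evaluate_series(pred, ref, method_name="b", patient_id="other")
        with pytest.raises(ValueError, match="different"):
            compare_methods(a, b)
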