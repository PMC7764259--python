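"""Operator unit and property tests against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirgrid import (
    SpectraBlock,
    WavenumberAxis,
    average_replicates,
    bin_axis,
    bin_spectrum,
    center_block,
    detrend,
    gap_segment_derivative,
    msc_correct,
    savgol_smooth,
)
from nirgrid.exceptions import DegenerateFitError, ParameterError

finite_vectors = st.lists(
    st.floats(min_value=-10, max_value=10, allow_nan=False), min_size=40, max_size=80
).map(np.array)


# ---------------------------------------------------------------------------
# Savitzky-Golay
# ---------------------------------------------------------------------------
class TestSavgol:
    @given(finite_vectors)
    @settings(max_examples=30, deadline=None)
    def test_order2_frame3_is_identity(self, y):
        assert np.abs(savgol_smooth(y, 2, 3) - y).max() < 1e-12

    def test_frame5_center_matches_parabola_fit(self):
        y = np.array([1.0, 2.0, 4.0, 2.0, 1.0])
        # brute-force least-squares parabola over all 5 points
        V = np.vander(np.arange(-2.0, 3.0), 3, increasing=True)
        coef, *_ = np.linalg.lstsq(V, y, rcond=None)
        expected_center = coef[0]  # value at x = 0
        out = savgol_smooth(y, 2, 5)
        assert abs(out[2] - expected_center) < 1e-12

    def test_constant_preserved(self):
        y = np.full(20, 3.7)
        assert np.allclose(savgol_smooth(y, 2, 5), y)

    def test_invalid_frame(self):
        with pytest.raises(ParameterError):
            savgol_smooth(np.arange(10.0), order=2, frame=2)
        with pytest.raises(ParameterError):
            savgol_smooth(np.arange(10.0), order=3, frame=3)


# ---------------------------------------------------------------------------
# MSC
# ---------------------------------------------------------------------------
class TestMSC:
    def test_identity_when_scans_equal_reference(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=30)
        X = np.tile(ref, (4, 1))
        corrected, used = msc_correct(X)
        assert np.allclose(corrected, X, atol=1e-12)
        assert np.allclose(used, ref)

    @given(
        st.floats(min_value=-2, max_value=2, allow_nan=False),
        st.floats(min_value=0.1, max_value=5, allow_nan=False),
    )
    @settings(max_examples=30, deadline=None)
    def test_inverts_affine_distortion(self, a, b):
        rng = np.random.default_rng(7)
        ref = rng.normal(size=50)
        X = a + b * np.tile(ref, (3, 1))
        corrected, _ = msc_correct(X, ref)
        assert np.abs(corrected - ref).max() < 1e-10

    def test_degenerate_slope_raises(self):
        ref = np.full(10, 2.0)
        X = np.vstack([np.linspace(-1, 1, 10), np.linspace(-1, 1, 10)])
        with pytest.raises(DegenerateFitError):
            msc_correct(X, ref)

    def test_single_scan_needs_reference(self):
        with pytest.raises(ParameterError):
            msc_correct(np.ones((1, 5)))


# ---------------------------------------------------------------------------
# Detrending
# ---------------------------------------------------------------------------
class TestDetrend:
    def test_annihilates_quadratic(self):
        w = np.arange(8000.0, 7599.0, -2.0)
        y = 3.0 - 0.01 * w + 2e-6 * w**2
        assert np.abs(detrend(y, w)).max() < 1e-9

    def test_constant_to_zeros(self):
        assert np.abs(detrend(np.full(50, 5.0))).max() < 1e-10

    def test_spike_matches_normal_equations_oracle(self):
        w = np.linspace(0.0, 1.0, 60)
        y = 1.0 + 2 * w - w**2
        y[30] += 5.0
        # independent oracle: explicit normal equations on the raw coordinate
        V = np.vander(w, 3, increasing=True)
        beta = np.linalg.solve(V.T @ V, V.T @ y)
        expected = y - V @ beta
        assert np.abs(detrend(y, w) - expected).max() < 1e-9

    @given(finite_vectors)
    @settings(max_examples=30, deadline=None)
    def test_idempotent(self, y):
        once = detrend(y)
        twice = detrend(once)
        assert np.abs(twice - once).max() < 1e-10

    def test_too_short(self):
        with pytest.raises(ParameterError):
            detrend(np.array([1.0, 2.0]), order=2)


# ---------------------------------------------------------------------------
# Gap-segment derivative
# ---------------------------------------------------------------------------
def _gap_seg_oracle(y, order, gap, segment, step):
    """Loop-based oracle forming each window by explicit index arithmetic."""
    n = len(y)
    out = []
    if order == "first":
        for j in range(n - gap - segment + 1):
            left = y[j : j + segment].mean()
            right = y[j + gap : j + gap + segment].mean()
            out.append((right - left) / (gap * step))
    else:
        for j in range(n - 2 * gap - segment + 1):
            left = y[j : j + segment].mean()
            center = y[j + gap : j + gap + segment].mean()
            right = y[j + 2 * gap : j + 2 * gap + segment].mean()
            out.append((left - 2 * center + right) / (gap * step) ** 2)
    return np.array(out)


class TestGapSegmentDerivative:
    def test_constant_first_derivative_zero(self):
        y = np.full(60, 2.5)
        assert np.abs(gap_segment_derivative(y, "first")).max() == 0.0

    def test_ramp_first_derivative_is_slope(self):
        s = 3.25
        y = s * np.arange(80.0)
        d = gap_segment_derivative(y, "first", 11, 11, 1.0)
        assert d.shape == (80 - 11 - 11 + 1,)
        assert np.abs(d - s).max() < 1e-10

    def test_affine_second_derivative_zero(self):
        y = 4.0 - 0.7 * np.arange(90.0)
        d = gap_segment_derivative(y, "second", 11, 11, 1.0)
        assert np.abs(d).max() < 1e-10

    @pytest.mark.parametrize("order", ["first", "second"])
    @pytest.mark.parametrize("gap,segment", [(11, 11), (5, 7), (3, 3)])
    def test_matches_loop_oracle(self, order, gap, segment):
        rng = np.random.default_rng(42)
        y = rng.normal(size=120)
        got = gap_segment_derivative(y, order, gap, segment, step=-2.0)
        expected = _gap_seg_oracle(y, order, gap, segment, step=-2.0)
        assert got.shape == expected.shape
        assert np.abs(got - expected).max() < 1e-10

    def test_too_short_raises(self):
        with pytest.raises(ParameterError):
            gap_segment_derivative(np.arange(20.0), "first", 11, 11)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------
class TestBinning:
    def test_window_one_identity(self):
        y = np.arange(13.0)
        assert np.array_equal(bin_spectrum(y, 1), y)

    def test_remainder_discarded(self):
        assert np.array_equal(bin_spectrum(np.array([1.0, 2, 3, 4, 5, 6]), 5), [3.0])

    def test_shorter_than_window_gives_empty(self):
        assert bin_spectrum(np.arange(4.0), 5).size == 0

    @given(finite_vectors, st.sampled_from([1, 5, 7, 10]))
    @settings(max_examples=30, deadline=None)
    def test_mean_conservation_over_covered_points(self, y, window):
        n_covered = (len(y) // window) * window
        out = bin_spectrum(y, window)
        assert abs(out.mean() - y[:n_covered].mean()) < 1e-12

    def test_binned_axis_is_window_mean(self):
        w = np.arange(8000.0, 7979.0, -2.0)  # 11 points
        assert np.array_equal(bin_axis(w, 5), [7996.0, 7986.0])

    def test_invalid_window(self):
        with pytest.raises(ParameterError):
            bin_spectrum(np.arange(5.0), 0)


# ---------------------------------------------------------------------------
# Replicate averaging
# ---------------------------------------------------------------------------
def _block_from(scans_by_sample, classes, axis=None):
    ids, X, cls = [], [], []
    for sid, scans in scans_by_sample.items():
        for scan in scans:
            ids.append(sid)
            X.append(scan)
            cls.append(classes[sid])
    X = np.array(X, dtype=float)
    if axis is None:
        axis = np.arange(X.shape[1], dtype=float) * -2.0 + 9000.0
    return SpectraBlock(
        axis=WavenumberAxis(axis),
        intensities=X,
        sample_id=np.array(ids, dtype=object),
        replicate_id=np.array(["r"] * len(ids), dtype=object),
        class_label=np.array(cls, dtype=object),
    )


class TestAveraging:
    @pytest.mark.parametrize("method", ["mean", "median", "median_spectrum"])
    def test_singleton_sample_unchanged(self, method):
        block = _block_from({"s": [[1.0, 2.0, 3.0]]}, {"s": "a"})
        out = average_replicates(block, method)
        assert np.array_equal(out.intensities, [[1.0, 2.0, 3.0]])

    def test_median_spectrum_picks_distance_sum_minimizer(self):
        # distance sums: [0,0]->4+sqrt(200); [0,4]->4+sqrt(136); [10,10]->sqrt(200)+sqrt(136)
        block = _block_from({"s": [[0.0, 0.0], [0.0, 4.0], [10.0, 10.0]]}, {"s": "a"})
        out = average_replicates(block, "median_spectrum")
        assert np.array_equal(out.intensities, [[0.0, 4.0]])

    def test_identical_scans_all_methods_agree(self):
        scans = [[2.0, 3.0, 4.0]] * 15
        block = _block_from({"s": scans}, {"s": "a"})
        results = [
            average_replicates(block, m).intensities
            for m in ("mean", "median", "median_spectrum")
        ]
        for r in results:
            assert np.array_equal(r, [[2.0, 3.0, 4.0]])

    def test_one_row_per_sample_in_first_appearance_order(self, tiny_block):
        out = average_replicates(tiny_block, "mean")
        assert list(out.sample_id) == [f"s{i}" for i in range(6)]
        assert out.n_scans == 6


# ---------------------------------------------------------------------------
# Centering
# ---------------------------------------------------------------------------
class TestCentering:
    def test_none_is_identity(self):
        X = np.arange(6.0).reshape(2, 3)
        assert np.array_equal(center_block(X, "none"), X)

    def test_mean_centering_example(self):
        X = np.array([[1.0, 3.0], [3.0, 5.0]])
        assert np.array_equal(center_block(X, "mean"), [[-1.0, -1.0], [1.0, 1.0]])

    def test_median_centering_zeroes_column_medians(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(9, 12))
        out = center_block(X, "median")
        assert np.abs(np.median(out, axis=0)).max() == 0.0

    def test_mean_centering_zeroes_column_means(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 5))
        assert np.abs(center_block(X, "mean").mean(axis=0)).max() < 1e-10
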