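"""Median filtering, min-max normalization and the corrected-intensity image."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from melaspec import (CohortSpec, DegenerateScanError, SpectralScan,
                      ValidationError, corrected_intensity, generate_cohort,
                      median_filter, minmax_normalize, preprocess_sample)
from melaspec.preprocess import NormalizedScan
from melaspec.scan_io import SCAN_SLOTS, SampleRecord

matrices = hnp.arrays(np.float64, hnp.array_shapes(min_dims=2, max_dims=2,
                                                   min_side=2, max_side=12),
                      elements=st.floats(0, 1e6, allow_nan=False))


def _brute_median(arr, wr, wc):
    """Independent oracle: reflect-pad (edge pixel included in the mirror,
    i.e. numpy's 'symmetric') then take the window median per pixel."""
    pr, pc = wr // 2, wc // 2
    padded = np.pad(arr, ((pr, pr), (pc, pc)), mode="symmetric")
    out = np.empty_like(arr, dtype=float)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            out[i, j] = np.median(padded[i:i + wr, j:j + wc])
    return out


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        scan = SpectralScan(np.full((8, 16), 3.5))
        assert np.all(median_filter(scan, 3).intensities == 3.5)

    def test_single_impulse_removed(self):
        arr = np.zeros((32, 512))
        arr[10, 100] = 9.0
        out = median_filter(SpectralScan(arr), 3)
        assert not out.intensities.any()

    def test_window_one_is_identity(self, rng):
        arr = rng.random((8, 16))
        np.testing.assert_array_equal(
            median_filter(SpectralScan(arr), 1).intensities, arr)

    @pytest.mark.parametrize("window", [2, 0, -3, (3, 4)])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValidationError, match="odd"):
            median_filter(SpectralScan(np.ones((8, 8))), window)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            median_filter(SpectralScan(np.ones((3, 8))), (5, 3))

    def test_matches_brute_force_oracle(self, rng):
        arr = rng.random((7, 11))
        for w in [(3, 3), (1, 5), (5, 3)]:
            np.testing.assert_allclose(
                median_filter(SpectralScan(arr), w).intensities,
                _brute_median(arr, *w), rtol=0, atol=0)

    def test_output_values_subset_of_input(self, rng):
        arr = rng.random((9, 9))
        out = median_filter(SpectralScan(arr), 3).intensities
        assert np.all(np.isin(out, arr))


class TestMinmaxNormalize:
    def test_hand_example(self):
        out = minmax_normalize(SpectralScan(np.array([[1.0, 3.0], [2.0, 5.0]])))
        np.testing.assert_allclose(out.intensities,
                                   [[0.0, 0.5], [0.25, 1.0]])

    def test_unit_range_input_unchanged(self):
        arr = np.array([[0.0, 0.3], [0.7, 1.0]])
        np.testing.assert_allclose(
            minmax_normalize(SpectralScan(arr)).intensities, arr)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateScanError, match="constant"):
            minmax_normalize(SpectralScan(np.full((4, 4), 2.0)))

    @settings(max_examples=50, derandomize=True)
    @given(matrices, st.floats(0.1, 100), st.floats(0, 1e5))
    def test_affine_invariance(self, arr, a, b):
        """Normalization is invariant under positive affine transforms."""
        if arr.max() == arr.min():
            return
        base = minmax_normalize(SpectralScan(arr)).intensities
        shifted = minmax_normalize(SpectralScan(a * arr + b)).intensities
        np.testing.assert_allclose(shifted, base, atol=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(matrices)
    def test_attains_zero_and_one(self, arr):
        if arr.max() == arr.min():
            return
        out = minmax_normalize(SpectralScan(arr)).intensities
        assert out.min() == 0.0 and out.max() == 1.0


def _norm(arr, pol="P", role="lesion1"):
    return NormalizedScan(np.asarray(arr, dtype=float), polarization=pol,
                          spot_role=role)


class TestCorrectedIntensity:
    def test_self_cancellation(self, rng):
        s = rng.random((4, 6))
        out = corrected_intensity(_norm(s), _norm(s), _norm(s, role="normal"))
        np.testing.assert_allclose(out.values, 0.0)

    def test_single_pixel_values(self):
        out = corrected_intensity(_norm([[0.4]]), _norm([[0.6]]),
                                  _norm([[0.2]], role="normal"))
        np.testing.assert_allclose(out.values, [[0.3]])
        neg = corrected_intensity(_norm([[0.1]]), _norm([[0.1]]),
                                  _norm([[0.5]], role="normal"))
        np.testing.assert_allclose(neg.values, [[-0.4]])  # signed, not clipped

    def test_polarization_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="polarization"):
            corrected_intensity(_norm([[0.1]]), _norm([[0.1]], pol="V"),
                                _norm([[0.1]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="shape"):
            corrected_intensity(_norm([[0.1, 0.2]]), _norm([[0.1, 0.2]]),
                                _norm([[0.1]]))

    @settings(max_examples=50, derandomize=True)
    @given(hnp.arrays(np.float64, (3, 4), elements=st.floats(0, 1)),
           hnp.arrays(np.float64, (3, 4), elements=st.floats(0, 1)),
           hnp.arrays(np.float64, (3, 4), elements=st.floats(0, 1)))
    def test_values_bounded(self, a, b, c):
        out = corrected_intensity(_norm(a), _norm(b), _norm(c))
        assert np.all(out.values >= -1.0) and np.all(out.values <= 1.0)


class TestPreprocessSample:
    def _sample(self, arrays):
        from melaspec.scan_io import _SLOT_META
        scans = {s: SpectralScan(arrays[s], *_SLOT_META[s]) for s in SCAN_SLOTS}
        return SampleRecord(sample_id="t", scans=scans)

    def test_identical_scans_give_zero_corrections(self, rng):
        arr = rng.random((8, 16))
        sample = self._sample({s: arr.copy() for s in SCAN_SLOTS})
        corr_p, corr_v = preprocess_sample(sample, 3)
        np.testing.assert_allclose(corr_p.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(corr_v.values, 0.0, atol=1e-12)

    def test_single_impulse_per_scan_is_removed(self):
        """A lone interior impulse in every scan does not change the output."""
        rec = generate_cohort(CohortSpec(n_melanoma=0, n_benign=1, n_cols=64,
                                         noise_rate=0.0, seed=6))[0]
        clean_p, clean_v = preprocess_sample(rec, 3)
        noisy = {}
        for slot in SCAN_SLOTS:
            arr = rec.scans[slot].intensities.astype(np.float64)
            # a salt impulse at the brightest interior pixel: the median
            # stage removes it without disturbing neighbouring windows
            interior = arr[1:-1, 1:-1]
            i, j = np.unravel_index(np.argmax(interior), interior.shape)
            arr[i + 1, j + 1] = arr.max() * 2
            noisy[slot] = arr
        noisy_p, noisy_v = preprocess_sample(self._sample(noisy), 3)
        np.testing.assert_allclose(noisy_p.values, clean_p.values, atol=1e-9)
        np.testing.assert_allclose(noisy_v.values, clean_v.values, atol=1e-9)

    def test_filter_before_normalize_order(self, rng):
        """The pipeline filters first: an impulse must not stretch the
        normalization range (which it would if normalization came first)."""
        base = np.tile(np.linspace(1.0, 2.0, 16), (8, 1)) + 0.01 * rng.random((8, 16))
        spiked = base.copy()
        spiked[4, 8] = 100.0
        filter_first = minmax_normalize(
            median_filter(SpectralScan(spiked), 3)).intensities
        normalize_first = median_filter(
            SpectralScan(minmax_normalize(SpectralScan(spiked)).intensities), 3
        ).intensities
        assert not np.allclose(filter_first, normalize_first)
        # the pipeline's corrected image matches the filter-first composition
        arrays = {s: base.copy() for s in SCAN_SLOTS}
        arrays["p1"] = spiked
        corr_p, _ = preprocess_sample(self._sample(arrays), 3)
        base_norm = minmax_normalize(median_filter(SpectralScan(base), 3)).intensities
        expected = (filter_first + base_norm) / 2.0 - base_norm
        np.testing.assert_allclose(corr_p.values, expected, atol=1e-12)

    def test_constant_scan_error_names_slot(self):
        arrays = {s: np.random.default_rng(0).random((8, 8)) for s in SCAN_SLOTS}
        arrays["v2"] = np.full((8, 8), 1.0)
        with pytest.raises(DegenerateScanError, match="v2"):
            preprocess_sample(self._sample(arrays), 3)

    def test_common_baseline_cancels(self, rng):
        """A multiplicative subject baseline common to all six scans leaves the
        corrected images unchanged (normalization removes the affine part)."""
        rec = generate_cohort(CohortSpec(n_melanoma=1, n_benign=0, n_cols=64,
                                         noise_rate=0.0, seed=12))[0]
        base_p, base_v = preprocess_sample(rec, 3)
        scaled = self._sample({s: rec.scans[s].intensities.astype(np.float64)
                               * 3.7 + 40.0 for s in SCAN_SLOTS})
        scaled_p, scaled_v = preprocess_sample(scaled, 3)
        np.testing.assert_allclose(scaled_p.values, base_p.values, atol=1e-9)
        np.testing.assert_allclose(scaled_v.values, base_v.values, atol=1e-9)
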