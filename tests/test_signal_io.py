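"""Preprocessing pipeline: filtering, normalization, mapping, segmentation,
splitting and augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.optimize import curve_fit

from beatfusion.signal_io import (
    CLASSES,
    BeatSegment,
    DegenerateInputError,
    LabeledDataset,
    UnmappedSymbolError,
    augment_beat,
    bandpass_filter,
    map_annotation_symbol,
    segment_beats,
    split_dataset,
    zscore_normalize,
)

FS = 360.0


class TestBandpass:
    def test_dc_is_rejected(self):
        out = bandpass_filter(np.full(3600, 5.0), FS)
        assert np.abs(out).max() < 0.05

    def test_midband_passes_at_unit_gain(self):
        t = np.arange(int(10 * FS)) / FS
        out = bandpass_filter(np.sin(2 * np.pi * 10.0 * t), FS)
        central = out[len(out) // 10 : -len(out) // 10]
        assert 0.95 <= np.abs(central).max() <= 1.05

    def test_above_band_is_attenuated(self):
        t = np.arange(int(10 * FS)) / FS
        out = bandpass_filter(np.sin(2 * np.pi * 120.0 * t), FS)
        central = out[len(out) // 10 : -len(out) // 10]
        assert np.abs(central).max() < 0.1

    def test_invalid_band_ordering_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(100), FS, low=50.0, high=0.5)
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(100), FS, low=0.5, high=200.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        coeffs=st.tuples(st.floats(-3, 3), st.floats(-3, 3)),
        seed=st.integers(0, 2**16),
    )
    def test_filter_is_linear(self, coeffs, seed):
        rng = np.random.default_rng(seed)
        a, b = coeffs
        x, y = rng.normal(size=500), rng.normal(size=500)
        lhs = bandpass_filter(a * x + b * y, FS)
        rhs = a * bandpass_filter(x, FS) + b * bandpass_filter(y, FS)
        np.testing.assert_allclose(lhs, rhs, atol=1e-6)


class TestZscore:
    def test_three_point_example(self):
        out = zscore_normalize(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0], atol=1e-12)
        assert out.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_idempotence(self, rng):
        x = zscore_normalize(rng.normal(size=100))
        np.testing.assert_allclose(zscore_normalize(x), x, atol=1e-9)

    def test_constant_signal_rejected(self):
        with pytest.raises(DegenerateInputError):
            zscore_normalize(np.full(5, 7.0))


class TestSymbolMapping:
    @pytest.mark.parametrize(
        "symbol,expected",
        [("N", "N"), ("L", "N"), ("R", "N"), ("e", "N"), ("j", "N"),
         ("A", "S"), ("a", "S"), ("J", "S"), ("S", "S"),
         ("V", "V"), ("E", "V"),
         ("F", "F"),
         ("f", "Q"), ("u", "Q")],
    )
    def test_five_class_mapping(self, symbol, expected):
        assert map_annotation_symbol(symbol) == expected

    @pytest.mark.parametrize("symbol", ["+", "~", "/", "x", "?"])
    def test_non_beat_symbols_rejected(self, symbol):
        with pytest.raises(UnmappedSymbolError):
            map_annotation_symbol(symbol)

    def test_multichar_input_rejected(self):
        with pytest.raises(ValueError):
            map_annotation_symbol("NN")


class TestSegmentation:
    def test_window_centered_on_r_peak(self, rng):
        x = rng.normal(size=2000)
        result = segment_beats(x, np.array([1000]), ["N"], window_len=360)
        np.testing.assert_array_equal(result.segments[0].samples, x[820:1180])
        assert result.segments[0].r_peak_index == 1000

    def test_boundary_beats_skipped(self, rng):
        x = rng.normal(size=2000)
        result = segment_beats(x, np.array([100, 1900]), ["N", "V"], window_len=360)
        assert len(result) == 0
        assert result.n_skipped_boundary == 2

    def test_interior_mappable_beats_all_kept(self, rng):
        x = rng.normal(size=5000)
        peaks = np.arange(500, 4500, 400)
        result = segment_beats(x, peaks, ["N"] * len(peaks), window_len=360)
        assert len(result) == len(peaks)

    def test_conservation_of_annotations(self, rng):
        x = rng.normal(size=4000)
        peaks = np.sort(rng.choice(np.arange(10, 3990), size=40, replace=False))
        symbols = rng.choice(list("NLVF+~u/"), size=40).tolist()
        result = segment_beats(x, peaks, symbols, window_len=360)
        assert len(result) + result.n_skipped_boundary + result.n_skipped_unmapped == 40

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            segment_beats(np.zeros(100), np.array([50]), ["N"], window_len=360)


def _toy_dataset(counts: dict[str, int]) -> LabeledDataset:
    beats = [BeatSegment(np.arange(8.0), label=c) for c, n in counts.items() for _ in range(n)]
    return LabeledDataset(beats, CLASSES)


class TestSplit:
    def test_70_10_20_exact(self):
        ds = split_dataset(_toy_dataset({"N": 100}), (0.7, 0.1, 0.2), rng_seed=0)
        tags = np.array(ds.split_tags)
        assert (tags == "train").sum() == 70
        assert (tags == "val").sum() == 10
        assert (tags == "test").sum() == 20

    def test_deterministic_under_seed(self):
        ds = _toy_dataset({"N": 50, "V": 20})
        a = split_dataset(ds, rng_seed=3).split_tags
        b = split_dataset(ds, rng_seed=3).split_tags
        assert a == b

    def test_stratified_within_one_of_target(self):
        ds = split_dataset(_toy_dataset({"N": 83, "S": 10, "V": 27}), (0.7, 0.1, 0.2), rng_seed=1)
        for cls, n in (("N", 83), ("S", 10), ("V", 27)):
            for split, frac in (("train", 0.7), ("val", 0.1), ("test", 0.2)):
                assert abs(ds.label_counts(split)[cls] - n * frac) < 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 17])
    def test_splits_disjoint_and_exhaustive(self, seed):
        ds = split_dataset(_toy_dataset({"N": 40, "V": 13, "Q": 8}), rng_seed=seed)
        assert all(t in ("train", "val", "test") for t in ds.split_tags)
        assert len(ds.subset("train")) + len(ds.subset("val")) + len(ds.subset("test")) == 61

    def test_tiny_class_kept_whole_in_train(self):
        ds = split_dataset(_toy_dataset({"N": 30, "F": 2}), rng_seed=0)
        assert ds.label_counts("train")["F"] == 2

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_toy_dataset({"N": 10}), (0.5, 0.5, 0.5))


class TestAugmentation:
    def test_identity_factors(self, rng):
        beat = BeatSegment(rng.normal(size=360), label="N")
        out = augment_beat(beat, 1.0, 1.0)
        np.testing.assert_allclose(out.samples, beat.samples, atol=1e-9)
        assert out.label == "N"

    def test_amplitude_scaling_is_linear(self, rng):
        beat = BeatSegment(rng.normal(size=360), label="V")
        out = augment_beat(beat, 1.0, 2.0)
        np.testing.assert_allclose(out.samples, 2.0 * beat.samples, atol=1e-12)

    def test_stretch_widens_a_gaussian_bump(self):
        t = np.arange(360, dtype=float)
        w = 20.0
        beat = BeatSegment(np.exp(-((t - 180) ** 2) / (2 * w**2)), label="N")
        out = augment_beat(beat, 1.5, 1.0)

        def gauss(x, mu, sigma, amp):
            return amp * np.exp(-((x - mu) ** 2) / (2 * sigma**2))

        (mu, sigma, amp), _ = curve_fit(gauss, t, out.samples, p0=[180, w, 1.0])
        assert abs(abs(sigma) - 1.5 * w) / (1.5 * w) < 0.10

    @pytest.mark.parametrize("stretch,scale", [(0.4, 1.0), (2.5, 1.0), (1.0, 0.0), (1.0, -1.0)])
    def test_out_of_range_factors_rejected(self, stretch, scale, rng):
        with pytest.raises(ValueError):
            augment_beat(BeatSegment(rng.normal(size=100), label="N"), stretch, scale)
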