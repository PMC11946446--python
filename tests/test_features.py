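"""Welch PSD, band slicing, trapezoidal band power and the feature bank."""

import numpy as np
import pytest
from scipy.signal import get_window

from ledgaze.channels import ACTIVE_CHANNELS
from ledgaze.features import (
    BANDS,
    DEFAULT_WELCH,
    PSDSpectrum,
    STATISTICS,
    WelchConfig,
    band_features,
    band_slice,
    band_trapz,
    describe_feature,
    feature_id,
    feature_vector,
    welch_psd,
)
from ledgaze.preprocess import Segment
from ledgaze.simulate import RecordingMeta


def welch_oracle(x, cfg):
    """Independent averaged-modified-periodogram implementation.

    Hand-rolls the windowing, overlap bookkeeping, scaling and one-sided
    folding; only the window values come from a library table.
    """
    w = get_window(cfg.window_fn, cfg.window_len)
    step = cfg.window_len - cfg.noverlap
    n_win = (len(x) - cfg.window_len) // step + 1
    nfft = cfg.resolved_nfft
    acc = np.zeros(nfft // 2 + 1)
    for i in range(n_win):
        block = x[i * step : i * step + cfg.window_len] * w
        spec = np.abs(np.fft.rfft(block, n=nfft)) ** 2
        acc += spec
    # density scaling: divide by fs * sum(w^2); double interior bins (one-sided)
    psd = acc / (n_win * cfg.fs * (w ** 2).sum())
    psd[1:] *= 2.0
    if nfft % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, 1.0 / cfg.fs)
    return freqs, psd


def _segment(data):
    meta = RecordingMeta(1, True, "right_left", 1)
    return Segment(data, 256.0, ACTIVE_CHANNELS[: data.shape[1]], meta, 0, 0)


class TestWelch:
    def test_matches_independent_oracle(self, rng):
        x = rng.standard_normal(768)
        psd = welch_psd(x)
        freqs, oracle = welch_oracle(x, DEFAULT_WELCH)
        np.testing.assert_allclose(psd.freqs_hz, freqs, atol=1e-12)
        np.testing.assert_allclose(psd.power, oracle, rtol=1e-10, atol=1e-14)

    def test_window_count_and_resolution(self):
        cfg = DEFAULT_WELCH
        assert cfg.n_windows(768) == 132
        assert cfg.delta_f == pytest.approx(256.0 / 637.0)

    def test_sinusoid_peaks_at_nearest_bin(self):
        t = np.arange(768) / 256.0
        psd = welch_psd(np.sin(2 * np.pi * 7.0 * t))
        peak_bin = int(np.argmax(psd.power))
        assert peak_bin == round(7.0 / psd.delta_f)

    def test_white_noise_is_flat(self, rng):
        # ensemble mean over independent draws: with 636/637 overlap the 132
        # windows of a single record are nearly identical, so flatness only
        # emerges across records
        acc = np.zeros(319)
        n_draws = 25
        for _ in range(n_draws):
            acc += welch_psd(rng.standard_normal(768)).power
        inner = (acc / n_draws)[5:-5]
        assert inner.std() / inner.mean() < 0.5

    def test_parseval_with_rectangular_window(self, rng):
        # boxcar window, no overlap: integrated PSD equals signal variance
        x = rng.standard_normal(768)
        x -= x.mean()
        cfg = WelchConfig(window_len=768, noverlap=0, window_fn="boxcar")
        psd = welch_psd(x, cfg)
        total = psd.power.sum() * cfg.fs / cfg.resolved_nfft
        assert total == pytest.approx(x.var(), rel=0.01)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="window_len"):
            welch_psd(np.zeros(100))


class TestBandSlice:
    def test_delta_bins_on_default_grid(self, rng):
        psd = welch_psd(rng.standard_normal(768))
        delta = band_slice(psd, BANDS[0])
        assert delta.freqs_hz.size == 10  # bins 0..9 stay below 4 Hz
        assert delta.freqs_hz.max() < 4.0

    def test_full_range_slice_is_identity(self, rng):
        from ledgaze.features import BandDefinition

        psd = welch_psd(rng.standard_normal(768))
        full = band_slice(psd, BandDefinition("all", 0.0, 128.0, closed_right=True))
        np.testing.assert_array_equal(full.power, psd.power)

    def test_nested_band_containment(self, rng):
        from ledgaze.features import BandDefinition

        psd = welch_psd(rng.standard_normal(768))
        narrow = band_slice(psd, BandDefinition("n", 6.0, 8.0))
        wide = band_slice(psd, BandDefinition("w", 1.0, 10.0))
        assert set(narrow.freqs_hz) < set(wide.freqs_hz)

    def test_bands_are_contiguous_cover(self, rng):
        psd = welch_psd(rng.standard_normal(768))
        n_bins = sum(band_slice(psd, b).freqs_hz.size for b in BANDS)
        expected = int(((psd.freqs_hz >= 0) & (psd.freqs_hz <= 45.0)).sum())
        assert n_bins == expected


class TestBandTrapz:
    def test_constant_power_rectangle(self):
        f = np.linspace(0, 4, 11)
        assert band_trapz(PSDSpectrum(f, np.full(11, 2.5))) == pytest.approx(10.0)

    def test_linear_ramp_exact(self):
        f = np.linspace(0, 1, 5)
        assert band_trapz(PSDSpectrum(f, 3.0 * f)) == pytest.approx(1.5)

    def test_quadratic_against_closed_form(self):
        f = np.linspace(0, 1, 101)
        assert band_trapz(PSDSpectrum(f, f ** 2)) == pytest.approx(1.0 / 3.0, abs=1e-4)

    def test_single_bin_warns_zero(self):
        with pytest.warns(UserWarning, match="single-bin"):
            assert band_trapz(PSDSpectrum(np.array([1.0]), np.array([5.0]))) == 0.0


class TestBandFeatures:
    def test_eight_statistics_five_bands(self, rng):
        psd = welch_psd(rng.standard_normal(768))
        for band in BANDS:
            assert band_features(band_slice(psd, band)).shape == (8,)

    def test_constant_slice_conventions(self):
        f = np.linspace(0, 4, 10)
        feats = dict(zip(STATISTICS, band_features(PSDSpectrum(f, np.full(10, 2.0)))))
        assert feats["variance"] == 0.0
        assert feats["skewness"] == 0.0 and feats["kurtosis"] == 0.0
        assert feats["entropy"] == pytest.approx(np.log(10))
        assert feats["mobility"] == 0.0 and feats["complexity"] == 0.0

    def test_hjorth_matches_difference_quotient_oracle(self, rng):
        y = rng.standard_normal(40)
        feats = dict(zip(STATISTICS, band_features(PSDSpectrum(np.arange(40.0), y))))
        mob = np.sqrt(np.var(np.diff(y)) / np.var(y))
        mob_d = np.sqrt(np.var(np.diff(y, 2)) / np.var(np.diff(y)))
        assert feats["mobility"] == pytest.approx(mob, rel=1e-12)
        assert feats["complexity"] == pytest.approx(mob_d / mob, rel=1e-12)

    def test_amplitude_scaling_laws(self, rng):
        """Doubling signal amplitude quadruples band power but leaves the
        shape statistics of the normalized slice unchanged."""
        x = rng.standard_normal(768)
        a = {b.name: band_features(band_slice(welch_psd(x), b)) for b in BANDS}
        b2 = {b.name: band_features(band_slice(welch_psd(2 * x), b)) for b in BANDS}
        for name in a:
            s1 = dict(zip(STATISTICS, a[name]))
            s2 = dict(zip(STATISTICS, b2[name]))
            assert s2["trapz"] == pytest.approx(4 * s1["trapz"], rel=1e-9)
            for stat in ("skewness", "kurtosis", "entropy"):
                assert s2[stat] == pytest.approx(s1[stat], rel=1e-9)


class TestFeatureVector:
    def test_lengths(self, rng):
        seg4 = _segment(rng.standard_normal((768, 4)))
        assert feature_vector(seg4).shape == (160,)
        seg1 = _segment(rng.standard_normal((768, 1)))
        assert feature_vector(seg1, active_channels=("AF3",)).shape == (40,)

    def test_missing_channel_named(self, rng):
        seg = _segment(rng.standard_normal((768, 2)))
        with pytest.raises(ValueError, match="F8"):
            feature_vector(seg, active_channels=("AF3", "F8"))

    @pytest.mark.parametrize(
        "fid,expected",
        [
            (42, ("F7", "delta", "mean")),
            (43, ("F7", "delta", "skewness")),
            (52, ("F7", "theta", "trapz")),
            (53, ("F7", "theta", "entropy")),
            (82, ("F8", "delta", "mean")),
            (83, ("F8", "delta", "skewness")),
            (92, ("F8", "theta", "trapz")),
            (93, ("F8", "theta", "entropy")),
        ],
    )
    def test_worked_feature_ids(self, fid, expected):
        assert describe_feature(fid) == expected
        assert feature_id(*expected) == fid

    def test_id_arithmetic_round_trip(self):
        for fid in range(1, 161):
            assert feature_id(*describe_feature(fid)) == fid

    def test_vector_layout_matches_ids(self, rng):
        """Entry fid-1 of the vector is the statistic describe_feature names."""
        seg = _segment(rng.standard_normal((768, 4)))
        vec = feature_vector(seg)
        psd = welch_psd(seg.channel("F8"))
        from ledgaze.features import BandDefinition

        theta = band_slice(psd, BANDS[1])
        expected = dict(zip(STATISTICS, band_features(theta)))
        assert vec[92 - 1] == pytest.approx(expected["trapz"])
        assert vec[93 - 1] == pytest.approx(expected["entropy"])
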