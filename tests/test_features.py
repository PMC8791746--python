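"""Spectral feature extraction: windowing, FFT, 1 Hz resampling,
normalization, concatenation."""

import numpy as np
import pytest
from hypothesis import given, strategies as hst

import silenttalk as st
from silenttalk.features import feature_names
from silenttalk.preprocess import InstanceSegment


def dft_magnitude(x, fs):
    """Brute-force DFT oracle (explicit matrix, one-sided)."""
    n = x.shape[-1]
    k = np.arange(n // 2 + 1)
    basis = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    return k * fs / n, np.abs(x @ basis.T)


def make_segment(data, fs=100.0, names=None, class_code=32, record_id=2):
    names = names or tuple(st.SCALP_CHANNELS_1020[:data.shape[0]])
    return InstanceSegment(class_code=class_code, subject_id=1,
                           record_id=record_id, data=np.asarray(data, float),
                           fs_hz=fs, channel_names=names)


@pytest.fixture()
def full_segment(rng):
    """A 21-channel, 4 s segment at 100 Hz with random content."""
    names = st.SCALP_CHANNELS_1020 + st.REFERENCE_CHANNELS
    return make_segment(rng.standard_normal((21, 400)), names=names)


class TestSelectChannels:
    def test_default_config_keeps_19_scalp_rows(self, full_segment):
        out = st.select_channels(full_segment, st.FeatureConfig().channels)
        assert out.data.shape[0] == 19
        assert out.channel_names == st.SCALP_CHANNELS_1020

    def test_singleton_selection(self, full_segment):
        out = st.select_channels(full_segment, ["Cz"])
        row = full_segment.channel_names.index("Cz")
        assert np.array_equal(out.data, full_segment.data[row:row + 1])

    def test_rows_follow_requested_order(self, full_segment):
        out = st.select_channels(full_segment, ["O2", "Fp1"])
        assert out.channel_names == ("O2", "Fp1")
        assert np.array_equal(out.data[1], full_segment.data[0])

    def test_unknown_channel_rejected(self, full_segment):
        with pytest.raises(ValueError, match="unknown channel"):
            st.select_channels(full_segment, ["Cz", "XX"])

    def test_reference_channels_rejected_by_default_config(self):
        with pytest.raises(ValueError, match="reference"):
            st.FeatureConfig(channels=("Cz", "A1"))
        cfg = st.FeatureConfig(channels=("Cz", "A1"),
                               allow_reference_channels=True)
        assert cfg.channels == ("Cz", "A1")


class TestSelectTimeWindow:
    def test_default_window_is_250_samples_from_index_100(self, full_segment):
        out = st.select_time_window(full_segment.data, 100.0, 1.0, 2.5)
        assert out.shape == (21, 250)
        assert np.array_equal(out, full_segment.data[:, 100:350])

    def test_identity_window(self, full_segment):
        out = st.select_time_window(full_segment.data, 100.0, 0.0, 4.0)
        assert np.array_equal(out, full_segment.data)

    def test_window_past_segment_end_rejected(self, full_segment):
        with pytest.raises(ValueError, match="exceeds"):
            st.select_time_window(full_segment.data, 100.0, 4.0, 0.5)


class TestMagnitudeSpectrum:
    def test_tone_at_bin_center_dominates_its_bin(self):
        t = np.arange(250) / 100.0
        freqs, mags = st.magnitude_spectrum(np.sin(2 * np.pi * 10 * t), 100.0)
        assert freqs[np.argmax(mags)] == pytest.approx(10.0)

    def test_zero_signal_gives_zero_spectrum(self):
        _, mags = st.magnitude_spectrum(np.zeros(250), 100.0)
        assert np.allclose(mags, 0.0)

    def test_two_tone_ratio_matches_amplitudes(self):
        t = np.arange(250) / 100.0
        x = 2.0 * np.sin(2 * np.pi * 8 * t) + 1.0 * np.sin(2 * np.pi * 20 * t)
        freqs, mags = st.magnitude_spectrum(x, 100.0)
        m8 = mags[np.isclose(freqs, 8.0)][0]
        m20 = mags[np.isclose(freqs, 20.0)][0]
        assert m8 / m20 == pytest.approx(2.0, rel=1e-6)

    def test_agrees_with_brute_force_dft(self, rng):
        x = rng.standard_normal((3, 250))
        freqs, mags = st.magnitude_spectrum(x, 100.0)
        o_freqs, o_mags = dft_magnitude(x, 100.0)
        assert np.allclose(freqs, o_freqs)
        assert np.allclose(mags, o_mags, atol=1e-8)

    def test_native_resolution_is_inverse_duration(self):
        freqs, _ = st.magnitude_spectrum(np.zeros(250), 100.0)
        assert freqs[1] - freqs[0] == pytest.approx(0.4)


class TestResampleTo1Hz:
    def test_integer_native_bins_pass_through(self):
        freqs = np.arange(0, 51, 1.0)  # 1 s window at 100 Hz
        mags = np.arange(51.0)
        out = st.resample_to_1hz(freqs, mags)
        assert out.shape == (33,)
        assert np.array_equal(out, mags[:33])

    def test_flat_spectrum_stays_flat(self):
        freqs = np.arange(0, 50, 0.4)
        out = st.resample_to_1hz(freqs, np.ones_like(freqs))
        assert np.allclose(out, 1.0)

    def test_tone_lands_on_its_integer_bin(self):
        t = np.arange(250) / 100.0
        freqs, mags = st.magnitude_spectrum(np.sin(2 * np.pi * 10 * t), 100.0)
        out = st.resample_to_1hz(freqs, mags)
        assert np.argmax(out) == 10

    def test_mean_binning_matches_direct_oracle(self, rng):
        freqs = np.arange(0, 50, 0.4)
        mags = rng.uniform(size=freqs.shape)
        out = st.resample_to_1hz(freqs, mags)
        for f in range(33):
            sel = (freqs >= f - 0.5) & (freqs < f + 0.5)
            assert out[f] == pytest.approx(mags[sel].mean())

    def test_coarse_native_resolution_rejected(self):
        with pytest.raises(ValueError, match="coarser"):
            st.resample_to_1hz(np.arange(0, 50, 2.0), np.ones(25))


class TestNormalizeAndBandSelect:
    def test_division_by_max(self):
        cfg = st.FeatureConfig(freq_lo_hz=0, freq_hi_hz=32, exclude_dc=False)
        vals = np.zeros(33)
        vals[:4] = [2, 4, 8, 6]
        out = st.normalize_and_band_select(vals, cfg)
        assert out[:4] == pytest.approx([0.25, 0.5, 1.0, 0.75])

    def test_all_zero_channel_passes_through(self):
        out = st.normalize_and_band_select(np.zeros(33), st.FeatureConfig())
        assert np.allclose(out, 0.0)

    def test_default_band_keeps_31_values(self):
        cfg = st.FeatureConfig()
        assert cfg.n_freqs == 31
        out = st.normalize_and_band_select(np.ones(33), cfg)
        assert out.shape == (31,)

    def test_one_to_32_band_selectable(self):
        cfg = st.FeatureConfig(freq_hi_hz=32)
        assert cfg.n_freqs == 32


class TestBuildFeatureVector:
    def test_default_length_is_19_by_31(self, full_segment):
        fv = st.build_feature_vector(full_segment)
        assert fv.values.shape == (19 * 31,)
        assert fv.n_channels == 19 and fv.n_freqs == 31

    def test_values_bounded_in_unit_interval(self, full_segment):
        fv = st.build_feature_vector(full_segment)
        assert fv.values.min() >= 0.0 and fv.values.max() <= 1.0

    def test_single_channel_vector_equals_that_channels_features(
            self, full_segment):
        cfg = st.FeatureConfig(channels=("Cz",))
        fv = st.build_feature_vector(full_segment, cfg)
        full = st.build_feature_vector(
            full_segment, st.FeatureConfig())
        block = st.SCALP_CHANNELS_1020.index("Cz")
        assert fv.values == pytest.approx(
            full.values[block * 31:(block + 1) * 31])

    def test_duplicated_channel_gives_identical_blocks(self, full_segment):
        cfg = st.FeatureConfig(channels=("Pz", "Pz"))
        fv = st.build_feature_vector(full_segment, cfg)
        assert np.array_equal(fv.values[:31], fv.values[31:])

    @given(scale=hst.floats(1e-3, 1e3))
    def test_amplitude_invariance(self, full_segment, scale):
        """Max-normalization removes overall gain: scaling every sample
        leaves the feature vector unchanged."""
        from dataclasses import replace
        fv = st.build_feature_vector(full_segment)
        scaled = replace(full_segment, data=full_segment.data * scale)
        fv2 = st.build_feature_vector(scaled)
        assert fv2.values == pytest.approx(fv.values, rel=1e-9, abs=1e-12)

    def test_length_independent_of_fs_and_duration(self, rng):
        """The point of 1 Hz resampling: feature length does not depend
        on the sampling rate or analysed duration."""
        names = st.SCALP_CHANNELS_1020
        a = make_segment(rng.standard_normal((19, 400)), fs=100.0,
                         names=names)
        b = make_segment(rng.standard_normal((19, 1000)), fs=250.0,
                         names=names)
        cfg_a = st.FeatureConfig(t_s_s=2.5)
        cfg_b = st.FeatureConfig(t_s_s=2.0)
        va = st.build_feature_vector(a, cfg_a)
        vb = st.build_feature_vector(b, cfg_b)
        assert va.values.shape == vb.values.shape

    def test_feature_names_are_channel_by_frequency(self):
        names = feature_names(st.FeatureConfig())
        assert len(names) == 589
        assert names[0] == "Fp1_1Hz" and names[30] == "Fp1_31Hz"
        assert "Cz_10Hz" in names
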