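import numpy as np
import pytest

from callscape.audio import AudioClip
from callscape.frontend import (
    FRAME_HOP,
    FRAME_LEN,
    FeatureStats,
    FrontendConfig,
    activity_gate,
    agc_rescale,
    deltas,
    extract_features,
    frame_signal,
    highpass,
    lfcc,
    load_features,
    resample_24k,
    save_features,
)

from conftest import tone


def band_power_db(samples, rate, f_lo, f_hi):
    mag = np.abs(np.fft.rfft(samples)) ** 2
    freqs = np.fft.rfftfreq(len(samples), 1 / rate)
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    return 10 * np.log10(mag[sel].sum() + 1e-300)


class TestAgc:
    def test_quarter_peak_scaled_by_four(self):
        clip = AudioClip(np.array([0.25, -0.1, 0.05]), 48_000.0)
        out = agc_rescale(clip)
        assert np.allclose(out.samples, [1.0, -0.4, 0.2])

    def test_identity_when_already_full_scale(self):
        clip = AudioClip(np.array([1.0, -0.5]), 48_000.0)
        assert np.array_equal(agc_rescale(clip).samples, clip.samples)

    def test_gain_bookkeeping_in_db(self):
        clip = tone(1000, amplitude=0.1)
        out = agc_rescale(clip)
        assert out.peak_dbfs == pytest.approx(0.0, abs=1e-9)
        assert out.gain_db == pytest.approx(20.0, abs=1e-6)

    def test_all_zero_clip_rejected(self):
        with pytest.raises(ValueError):
            agc_rescale(AudioClip(np.zeros(100), 48_000.0))


class TestResample:
    def test_sample_count(self):
        out = resample_24k(tone(1000, rate_hz=48_000, duration_s=1.0))
        assert out.rate_hz == 24_000
        assert len(out.samples) == 24_000

    @staticmethod
    def _tone_amplitude_db(samples, rate, f_lo, f_hi):
        """Amplitude (dB re full scale) of the strongest line in a band."""
        mag = np.abs(np.fft.rfft(samples)) * 2.0 / len(samples)
        freqs = np.fft.rfftfreq(len(samples), 1 / rate)
        sel = (freqs >= f_lo) & (freqs <= f_hi)
        return 20 * np.log10(mag[sel].max() + 1e-300)

    def test_13khz_tone_attenuated(self):
        # FFT band-amplitude oracle: 13 kHz aliases to 11 kHz after decimation
        clip = tone(13_000, rate_hz=48_000, duration_s=1.0)
        before = self._tone_amplitude_db(clip.samples, 48_000, 12_800, 13_200)
        out = resample_24k(clip)
        after = self._tone_amplitude_db(out.samples, 24_000, 500, 12_000)
        assert before - after >= 40

    def test_2khz_tone_preserved(self):
        clip = tone(2000, rate_hz=48_000, duration_s=1.0)
        out = resample_24k(clip)
        before = self._tone_amplitude_db(clip.samples, 48_000, 1_900, 2_100)
        after = self._tone_amplitude_db(out.samples, 24_000, 1_900, 2_100)
        assert after - before == pytest.approx(0.0, abs=0.5)

    def test_upsampling_out_of_contract(self):
        with pytest.raises(ValueError):
            resample_24k(tone(1000, rate_hz=16_000))

    def test_24k_passthrough(self):
        clip = tone(1000, rate_hz=24_000)
        assert np.array_equal(resample_24k(clip).samples, clip.samples)


class TestHighpass:
    def _gain_db(self, freq):
        clip = tone(freq, rate_hz=24_000, duration_s=1.0)
        out = highpass(clip)
        mid = slice(4000, 20_000)  # avoid filtfilt edge transients
        return 20 * np.log10(np.sqrt(np.mean(out.samples[mid] ** 2))
                             / np.sqrt(np.mean(clip.samples[mid] ** 2)))

    def test_100hz_attenuated_at_least_60db(self):
        # order-10 Butterworth: asymptote 200 dB/decade per pass
        assert self._gain_db(100) <= -60

    def test_cutoff_is_minus_three_db_per_pass(self):
        # zero-phase = two passes -> -6.02 dB at 1 kHz
        assert self._gain_db(1000) == pytest.approx(-6.02, abs=0.3)

    def test_4khz_passed(self):
        assert abs(self._gain_db(4000)) < 0.5


class TestFraming:
    def test_197_frames_per_second(self):
        frames, starts, _ = frame_signal(tone(2000, rate_hz=24_000, duration_s=1.0))
        expected = (24_000 - FRAME_LEN) // FRAME_HOP + 1
        assert expected == 197
        assert frames.shape == (197, 480)
        assert starts[1] - starts[0] == pytest.approx(0.005)

    def test_full_scale_constant_is_zero_dbfs(self):
        clip = AudioClip(np.ones(480), 24_000.0)
        _, _, energy = frame_signal(clip)
        assert energy[0] == pytest.approx(0.0)

    def test_silence_clamped_to_floor(self):
        _, _, energy = frame_signal(AudioClip(np.zeros(1000), 24_000.0))
        assert np.all(energy == -120.0)

    def test_short_clip_warns_and_returns_zero_frames(self):
        with pytest.warns(UserWarning):
            frames, starts, energy = frame_signal(AudioClip(np.zeros(100), 24_000.0))
        assert frames.shape[0] == 0


class TestLfcc:
    def test_white_noise_gives_small_coefficients(self, rng):
        # flat spectrum -> flat log filter energies -> all non-c0 DCT terms ~ 0
        frames = rng.standard_normal((2000, 480))
        ceps = lfcc(frames).mean(axis=0)  # average out per-frame noise
        assert np.max(np.abs(ceps)) < 0.5

    def test_dct_invertibility(self, rng):
        from scipy.fft import dct, idct

        log_e = rng.standard_normal(40)
        coeffs = dct(log_e, type=2, norm="ortho")
        assert np.allclose(idct(coeffs, type=2, norm="ortho"), log_e, atol=1e-6)

    def test_gain_invariance(self):
        clip = tone(3000, rate_hz=24_000, duration_s=0.5, amplitude=0.3)
        frames, _, _ = frame_signal(clip)
        a = lfcc(frames)
        b = lfcc(frames * 2.0)
        assert np.allclose(a, b, atol=1e-9)

    def test_tone_at_filter_center_concentrates_energy(self):
        from callscape.frontend import _triangular_filterbank

        fbank = _triangular_filterbank(40, 480, 24_000)
        edges = np.linspace(0, 12_000, 42)
        center = edges[11]  # center of filter index 10
        clip = tone(center, rate_hz=24_000, duration_s=0.5)
        frames, _, _ = frame_signal(clip)
        spectrum = np.abs(np.fft.rfft(frames * np.hamming(480), axis=1)) ** 2
        energies = spectrum @ fbank.T
        assert np.argmax(energies.mean(axis=0)) == 10

    def test_output_width(self, rng):
        assert lfcc(rng.standard_normal((10, 480))).shape == (10, 35)


class TestDeltas:
    def test_constant_input_gives_zero(self):
        ceps = np.ones((20, 35)) * 3.0
        assert np.all(deltas(ceps) == 0.0)

    def test_linear_ramp_recovers_slope(self):
        # regression formula: sum(k * (x[t+k] - x[t-k])) / (2 * sum k^2) = slope
        slope = 0.37
        ceps = np.outer(np.arange(30) * slope, np.ones(35))
        d = deltas(ceps)
        assert np.allclose(d[5:-5, :35], slope, atol=1e-12)

    def test_stacked_feature_width_is_90(self):
        ceps = np.random.default_rng(0).standard_normal((12, 35))
        stacked = np.hstack([ceps, deltas(ceps)])
        assert stacked.shape[1] == 90

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            deltas(np.ones((3, 35)))


class TestStandardize:
    def test_training_data_lands_in_unit_range(self, rng):
        X = rng.normal(3.0, 10.0, size=(500, 7))
        stats = FeatureStats.fit(X)
        Z = stats.transform(X)
        assert Z.min() >= -1.0 and Z.max() <= 1.0
        assert Z.min() == pytest.approx(-1.0)
        assert Z.max() == pytest.approx(1.0)

    def test_constant_dimension_maps_to_zero(self):
        X = np.hstack([np.ones((10, 1)) * 4.2, np.arange(10.0)[:, None]])
        Z = FeatureStats.fit(X).transform(X)
        assert np.all(Z[:, 0] == 0.0)
        assert not np.any(np.isnan(Z))

    def test_out_of_range_values_clipped(self, rng):
        X = rng.uniform(-1, 1, size=(100, 3))
        stats = FeatureStats.fit(X)
        Z = stats.transform(X * 50)
        assert Z.min() == -1.0 and Z.max() == 1.0

    def test_dimension_mismatch_rejected(self, rng):
        stats = FeatureStats.fit(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError):
            stats.transform(rng.normal(size=(5, 6)))

    def test_json_round_trip(self, rng):
        stats = FeatureStats.fit(rng.normal(size=(10, 4)), stats_id="s1")
        back = FeatureStats.from_json(stats.to_json())
        assert back.stats_id == "s1"
        assert np.allclose(back.min_, stats.min_)


class TestActivityGate:
    def test_threshold_trivials(self):
        assert activity_gate(np.array([-40.0]))[0]
        assert not activity_gate(np.array([-60.0]))[0]
        assert activity_gate(np.array([-50.0]))[0]  # boundary inclusive

    def test_mask_flips_where_windowed_rms_crosses(self, rng):
        # brute-force RMS oracle on a mixed loud/quiet clip
        x = np.concatenate([0.5 * rng.standard_normal(4800),
                            1e-4 * rng.standard_normal(4800)])
        clip = AudioClip(np.clip(x, -1, 1), 24_000.0)
        _, _, energy = frame_signal(clip)
        mask = activity_gate(energy)
        for i in [0, 10, 25, 36, 40, 60, 76]:
            seg = clip.samples[i * 120 : i * 120 + 480]
            rms_db = 20 * np.log10(max(np.sqrt(np.mean(seg**2)), 1e-6))
            assert mask[i] == (rms_db >= -50)


class TestPipeline:
    def test_determinism(self):
        clip = tone(2500, rate_hz=48_000, duration_s=0.5, amplitude=0.3)
        a = extract_features(clip)
        b = extract_features(clip)
        assert np.array_equal(a.features, b.features)

    def test_feature_width_and_mask(self):
        clip = tone(2500, rate_hz=48_000, duration_s=1.0, amplitude=0.3)
        feats = extract_features(clip)
        assert feats.features.shape[1] == 90
        assert feats.active_mask.dtype == bool

    def test_chain_order_matters(self):
        # a 500 Hz probe must be suppressed by the high-pass stage before
        # framing; a chain that frames the unfiltered signal looks different
        clip = tone(500, rate_hz=48_000, duration_s=0.5, amplitude=0.5)
        canonical = highpass(resample_24k(agc_rescale(clip)))
        scrambled = resample_24k(agc_rescale(clip))  # high-pass dropped
        rms_canonical = np.sqrt(np.mean(canonical.samples[2000:8000] ** 2))
        rms_scrambled = np.sqrt(np.mean(scrambled.samples[2000:8000] ** 2))
        assert rms_canonical < 1e-3 * rms_scrambled
        a = lfcc(frame_signal(canonical)[0])
        b = lfcc(frame_signal(scrambled)[0])
        assert not np.allclose(a, b, atol=1e-2)

    def test_gate_monotone_in_gain(self):
        clip = tone(2500, rate_hz=48_000, duration_s=0.5, amplitude=0.01)
        cfg = FrontendConfig(gate_pre_agc=False)
        quiet = extract_features(clip, config=cfg)
        loud = extract_features(clip.with_samples(clip.samples * 10), config=cfg)
        assert np.all(loud.active_mask >= quiet.active_mask)

    def test_pre_agc_gate_uses_recorder_level(self):
        # a -60 dBFS tone is inactive pre-AGC even though AGC lifts it to 0 dBFS
        clip = tone(2500, rate_hz=48_000, duration_s=0.5, amplitude=0.001)
        pre = extract_features(clip, config=FrontendConfig(gate_pre_agc=True))
        post = extract_features(clip, config=FrontendConfig(gate_pre_agc=False))
        assert not pre.active_mask.any()
        assert post.active_mask.any()

    def test_feature_file_round_trip(self, tmp_path):
        clip = tone(2500, rate_hz=48_000, duration_s=0.5, amplitude=0.3)
        feats = extract_features(clip)
        save_features(tmp_path / "f.npz", feats)
        back = load_features(tmp_path / "f.npz")
        assert np.array_equal(back.features, feats.features)
        assert back.hop_s == feats.hop_s
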