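"""Preprocessing, band split, multiunit detection, maps, profiles, detectors."""

import numpy as np
import pytest

from probeloc.ephys_features import (
    EventTrain,
    FeatureProfile,
    RawRecording,
    common_average_reference,
    depth_profiles,
    detect_multiunit,
    detect_surface,
    evoked_profile,
    read_recording,
    remove_offset,
    spike_rate_map,
    split_bands,
    write_recording,
)


def _rec(samples, fs=30_000.0, depths=None):
    samples = np.asarray(samples, dtype=float)
    return RawRecording(samples=samples, sample_rate_hz=fs, uV_per_bit=1.0,
                        channel_depth_um=depths, in_uv=True)


class TestPreprocessing:
    def test_offset_removal_zeroes_constant_channels(self):
        rec = remove_offset(_rec(np.full((3, 100), 7.0)))
        np.testing.assert_allclose(rec.samples, 0.0)

    def test_offset_removal_median_case(self):
        rec = remove_offset(_rec([[1.0, 1.0, 5.0]]))
        np.testing.assert_allclose(rec.samples, [[0.0, 0.0, 4.0]])

    def test_offset_removal_postcondition_on_random_input(self, rng):
        rec = remove_offset(_rec(rng.normal(size=(8, 501))))
        np.testing.assert_allclose(np.median(rec.samples, axis=1), 0.0,
                                   atol=1e-12)

    def test_car_zeroes_identical_channels(self, rng):
        x = rng.normal(size=600)
        rec = common_average_reference(_rec(np.tile(x, (5, 1))))
        np.testing.assert_allclose(rec.samples, 0.0, atol=1e-12)

    def test_car_median_case(self):
        rec = common_average_reference(_rec([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(rec.samples, [[-1.0], [0.0], [1.0]])

    def test_car_postcondition_on_random_input(self, rng):
        rec = common_average_reference(_rec(rng.normal(size=(7, 400))))
        np.testing.assert_allclose(np.median(rec.samples, axis=0), 0.0,
                                   atol=1e-12)

    def test_car_needs_two_channels(self):
        with pytest.raises(ValueError):
            common_average_reference(_rec(np.zeros((1, 10))))

    @pytest.mark.parametrize("op", [remove_offset, common_average_reference])
    def test_idempotence(self, rng, op):
        rec = _rec(rng.normal(size=(6, 1001)))
        once = op(rec)
        twice = op(once)
        np.testing.assert_allclose(twice.samples, once.samples, atol=1e-12)


class TestSplitBands:
    def _tone(self, freq, fs=30_000.0, dur=2.0):
        t = np.arange(int(dur * fs)) / fs
        return _rec(np.sin(2 * np.pi * freq * t)[None, :], fs=fs)

    def test_slow_tone_kept_in_lfp_suppressed_in_ap(self):
        ap, lfp = split_bands(self._tone(100.0))
        mid = slice(lfp.n_samples // 4, -lfp.n_samples // 4)
        assert lfp.samples[0, mid].max() >= 0.95
        ap_mid = ap.samples[0, ap.n_samples // 4: -ap.n_samples // 4]
        assert np.abs(ap_mid).max() <= 10 ** (-20 / 20)  # >= 20 dB down

    def test_fast_tone_kept_in_ap_suppressed_in_lfp(self):
        ap, lfp = split_bands(self._tone(1000.0))
        ap_mid = ap.samples[0, ap.n_samples // 4: -ap.n_samples // 4]
        assert np.abs(ap_mid).max() >= 0.95
        lfp_mid = lfp.samples[0, lfp.n_samples // 4: -lfp.n_samples // 4]
        assert np.abs(lfp_mid).max() <= 10 ** (-20 / 20)

    def test_dc_absent_from_ap_band(self):
        rec = _rec(np.full((2, 60_000), 50.0))
        ap, _ = split_bands(rec)
        assert np.abs(ap.samples[:, 1000:-1000]).max() < 1e-6

    def test_lfp_rate_is_2500(self):
        ap, lfp = split_bands(self._tone(100.0))
        assert lfp.sample_rate_hz == 2500.0
        assert ap.sample_rate_hz == 30_000.0

    def test_mixture_energy_separation(self):
        t = np.arange(60_000) / 30_000.0
        mix = np.sin(2 * np.pi * 100 * t) + np.sin(2 * np.pi * 1000 * t)
        ap, lfp = split_bands(_rec(mix[None, :]))
        # cross-band leakage <= -20 dB in energy each way
        sl = slice(10_000, 50_000)
        ap_energy = np.mean(ap.samples[0, sl] ** 2)
        lfp_sl = slice(10_000 // 12, 50_000 // 12)
        lfp_energy = np.mean(lfp.samples[0, lfp_sl] ** 2)
        assert ap_energy == pytest.approx(0.5, rel=0.05)
        assert lfp_energy == pytest.approx(0.5, rel=0.05)

    def test_low_rate_input_rejected(self):
        with pytest.raises(ValueError):
            split_bands(_rec(np.zeros((1, 100)), fs=2500.0))


def _inject_spikes(n_samples, spike_idx, amp_uV, noise_uV, rng, fs=30_000.0):
    x = rng.normal(0, noise_uV, n_samples) if noise_uV > 0 else np.zeros(n_samples)
    width = int(0.3e-3 * fs)
    lobe = -np.sin(np.pi * np.arange(width) / width)
    for i in spike_idx:
        x[i:i + width] += amp_uV * lobe
        x[i + width:i + 2 * width] += -0.3 * amp_uV * lobe
    return x


class TestDetectMultiunit:
    def test_silence_gives_no_events(self):
        assert len(detect_multiunit(_rec(np.zeros((4, 1000))))) == 0

    def test_threshold_selects_by_amplitude(self, rng):
        x = _inject_spikes(30_000, [5_000], amp_uV=60.0, noise_uV=0.0, rng=rng)
        rec = _rec(x[None, :])
        assert len(detect_multiunit(rec, threshold_uV=-50.0)) == 1
        assert len(detect_multiunit(rec, threshold_uV=-70.0)) == 0

    def test_injected_spikes_counted_exactly(self, rng):
        """100 spikes of -100 uV in 5 uV noise: all found, none invented.
        (P(noise < -50 uV) at 10 sigma is ~8e-24 per sample.)"""
        idx = np.sort(rng.choice(np.arange(100, 590_000, 60), 100, replace=False))
        x = _inject_spikes(600_000, idx, amp_uV=100.0, noise_uV=5.0, rng=rng)
        events = detect_multiunit(_rec(x[None, :]))
        assert len(events) == 100
        np.testing.assert_allclose(np.sort(events.time_s * 30_000.0), idx + 1,
                                   atol=2.0)

    def test_dead_time_suppresses_double_counting(self):
        fs = 30_000.0
        x = np.zeros(3000)
        x[100:104] = -80.0
        x[110:114] = -90.0  # second crossing within 1 ms
        x[200:204] = -80.0  # > 1 ms later
        events = detect_multiunit(_rec(x[None, :], fs=fs))
        assert len(events) == 2

    def test_amplitude_is_trough_in_window(self):
        x = np.zeros(1000)
        x[100] = -55.0
        x[105] = -120.0
        events = detect_multiunit(_rec(x[None, :]))
        assert events.amplitude_uV[0] == pytest.approx(-120.0)


class TestBinnedMaps:
    def test_rate_map_of_uniform_train(self):
        events = EventTrain(channel=np.zeros(600, int),
                            time_s=np.linspace(0, 59.999, 600),
                            amplitude_uV=np.full(600, -60.0))
        m, t_edges, d_edges = spike_rate_map(events, np.array([100.0]),
                                             duration_s=60.0)
        assert m.shape[0] == 6
        np.testing.assert_allclose(m.sum(axis=1), 10.0)

    def test_empty_train_gives_zero_map(self):
        events = EventTrain(channel=np.empty(0, int), time_s=np.empty(0),
                            amplitude_uV=np.empty(0))
        m, _, _ = spike_rate_map(events, np.array([0.0, 20.0]), duration_s=30.0)
        assert m.sum() == 0.0

    def test_event_count_conserved(self, rng):
        n = 500
        depths = np.arange(16) * 20.0
        events = EventTrain(channel=rng.integers(0, 16, n),
                            time_s=rng.uniform(0, 100, n),
                            amplitude_uV=np.full(n, -60.0))
        m, _, _ = spike_rate_map(events, depths, duration_s=100.0)
        assert m.sum() * 10.0 == pytest.approx(n)


class TestDepthProfiles:
    def test_silent_channels_have_zero_rate_and_power(self):
        rec = _rec(np.zeros((8, 2500)), fs=2500.0)
        events = EventTrain(channel=np.empty(0, int), time_s=np.empty(0),
                            amplitude_uV=np.empty(0))
        profs = depth_profiles(events, rec)
        assert profs["spike_rate"].values.sum() == 0.0
        assert profs["lfp_power"].values.sum() == 0.0

    def test_injected_rate_gradient_is_monotone(self, rng):
        depths = np.arange(10) * 20.0
        counts = (np.arange(10) + 1) * 40
        chans = np.repeat(np.arange(10), counts)
        events = EventTrain(channel=chans,
                            time_s=rng.uniform(0, 10, counts.sum()),
                            amplitude_uV=np.full(counts.sum(), -60.0))
        lfp = _rec(np.zeros((10, 25_000)), fs=2500.0, depths=depths)
        profs = depth_profiles(events, lfp)
        assert np.all(np.diff(profs["spike_rate"].values) > 0)

    def test_amplitude_step_marks_layer_transition(self, rng):
        """Channels below a depth carry 80 uV units, channels above none —
        the median-amplitude profile steps at that depth."""
        depths = np.arange(20) * 20.0
        deep = np.repeat(np.arange(10), 30)  # only the 10 deepest channels
        events = EventTrain(channel=deep, time_s=rng.uniform(0, 10, 300),
                            amplitude_uV=np.full(300, -80.0))
        lfp = _rec(np.zeros((20, 2500)), fs=2500.0, depths=depths)
        amp = depth_profiles(events, lfp)["amplitude"].values
        assert np.all(amp[:10] == 80.0) and np.all(amp[10:] == 0.0)


class TestDetectSurface:
    def _profile(self, values):
        edges = 20.0 * np.arange(len(values) + 1)
        return FeatureProfile(edges, np.asarray(values, float), kind="lfp_power")

    def test_clean_step_found_exactly(self):
        vals = np.r_[np.full(200, 10.0), np.full(100, 1.0)]  # deep..shallow
        depth, idx, conf = detect_surface(self._profile(vals))
        assert idx == 199
        assert conf > 2.0

    def test_noisy_step_within_two_channels(self, rng):
        vals = np.r_[np.full(200, 10.0), np.full(100, 1.0)]
        vals += rng.normal(0, 0.5, vals.shape)
        _, idx, _ = detect_surface(self._profile(vals))
        assert abs(idx - 199) <= 2

    def test_flat_profile_rejected(self, rng):
        vals = 5.0 + rng.normal(0, 0.3, 120)
        with pytest.raises(ValueError, match="surface"):
            detect_surface(self._profile(vals))


class TestEvokedProfile:
    def _events(self, chans, times):
        return EventTrain(channel=np.asarray(chans, int),
                          time_s=np.asarray(times, float),
                          amplitude_uV=np.full(len(times), -60.0))

    def test_no_events_gives_zero_profile(self):
        depths = np.arange(4) * 20.0
        prof, psth = evoked_profile(self._events([], []), np.arange(1.0, 11.0),
                                    channel_depth_um=depths)
        assert prof.values.sum() == 0.0

    def test_fixed_latency_events_all_counted(self):
        stim = 1.0 + 0.1 * np.arange(300)
        events = self._events(np.full(300, 2), stim + 0.003)
        depths = np.arange(6) * 20.0
        prof, psth = evoked_profile(events, stim, window_ms=(0, 5),
                                    channel_depth_um=depths)
        assert prof.values[2] == pytest.approx(300)
        assert prof.values.sum() == pytest.approx(300)
        peak_bin = psth.loc[psth["rate_hz"].idxmax(), "time_ms"]
        assert peak_bin == pytest.approx(3.0, abs=0.5)

    def test_window_selects_latency(self):
        stim = 1.0 + 0.1 * np.arange(100)
        events = self._events(np.zeros(100), stim + 0.010)  # 10 ms latency
        depths = np.arange(2) * 20.0
        early, _ = evoked_profile(events, stim, window_ms=(0, 5),
                                  channel_depth_um=depths)
        late, _ = evoked_profile(events, stim, window_ms=(5, 20),
                                 channel_depth_um=depths)
        assert early.values.sum() == 0.0
        assert late.values[0] == pytest.approx(100)

    def test_baseline_subtraction_cancels_steady_activity(self, rng):
        stim = 1.0 + 0.1 * np.arange(200)
        times = rng.uniform(0.5, 21.5, 20_000)  # steady background
        events = self._events(np.zeros(20_000), np.sort(times))
        prof, _ = evoked_profile(events, stim, window_ms=(0, 20),
                                 channel_depth_um=np.arange(2) * 20.0)
        # expected counts in window ~ baseline; residual ~ Poisson noise
        assert abs(prof.values[0]) < 4 * np.sqrt(2 * 20e-3 * 200 * 1000)

    def test_empty_stims_rejected(self):
        with pytest.raises(ValueError):
            evoked_profile(self._events([], []), np.array([]),
                           channel_depth_um=np.arange(2) * 20.0)


class TestRecordingIO:
    def test_binary_round_trip(self, tmp_path, rng):
        counts = rng.integers(-2000, 2000, size=(4, 500)).astype(np.int16)
        rec = RawRecording(samples=counts, sample_rate_hz=30_000.0,
                           uV_per_bit=0.25,
                           channel_depth_um=np.arange(4) * 20.0)
        path = write_recording(rec, tmp_path / "rec.bin")
        back = read_recording(path)
        np.testing.assert_array_equal(back.samples, counts)
        assert back.uV_per_bit == 0.25
        np.testing.assert_allclose(back.channel_depth_um, rec.channel_depth_um)

    def test_acquisition_meta_text_shim(self, tmp_path, rng):
        counts = rng.integers(-100, 100, size=(3, 40)).astype(np.int16)
        path = tmp_path / "rec.bin"
        counts.T.tofile(path)
        (tmp_path / "rec.meta").write_text(
            "nSavedChans=3\nimSampRate=30000.0\n~extra=junk\n")
        back = read_recording(path)
        assert back.n_channels == 3
        assert back.sample_rate_hz == 30_000.0
        np.testing.assert_array_equal(back.samples, counts)

    def test_missing_metadata_rejected(self, tmp_path):
        path = tmp_path / "orphan.bin"
        np.zeros(10, dtype=np.int16).tofile(path)
        with pytest.raises(FileNotFoundError):
            read_recording(path)
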