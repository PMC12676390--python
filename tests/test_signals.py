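"""Signal-feature pipeline: filters, artifact repair, spectra, bursts, coherence."""

import numpy as np
import pytest

from neurolatent.signals import (
    ANALYSIS_RANGE,
    BandDefinition,
    Burst,
    BurstSet,
    DEFAULT_BANDS,
    DegenerateScaleError,
    FeatureConfig,
    Recording,
    SpectralEstimate,
    band_envelope,
    band_power,
    build_physio_features,
    burst_summary,
    detect_and_repair_artifacts,
    detect_bursts,
    msc_coherence,
    multitaper_psd,
    normalize_spectrum,
    notch_line_noise,
    physio_feature_names,
)
from neurolatent.synth import ArtifactSpec, BurstSpec, SignalSimConfig, inject_artifacts, simulate_coupled_channels, simulate_oscillatory_channel

from conftest import planted_burst_config

FS = 1000.0


def tone(freq, duration=10.0, amp=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def rec_of(x, labels=("M1",)):
    return Recording(np.atleast_2d(x), fs=FS, labels=list(labels))


class TestBandDefinition:
    def test_defaults(self):
        names = [(b.name, b.f_lo, b.f_hi) for b in DEFAULT_BANDS]
        assert names == [
            ("alpha", 8.0, 11.0), ("low_beta", 12.0, 20.0),
            ("high_beta", 21.0, 35.0), ("gamma", 65.0, 110.0),
        ]
        assert DEFAULT_BANDS[1].center == 16.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 20.0, 12.0)


class TestNotch:
    def test_line_tone_removed(self):
        out = notch_line_noise(rec_of(tone(60.0)))
        assert np.sqrt((out.samples**2).mean()) < 0.03 * np.sqrt((tone(60.0) ** 2).mean())

    def test_passband_preserved(self):
        out = notch_line_noise(rec_of(tone(20.0)))
        in_rms = np.sqrt((tone(20.0) ** 2).mean())
        assert abs(np.sqrt((out.samples**2).mean()) - in_rms) < 0.01 * in_rms

    def test_zero_signal(self):
        out = notch_line_noise(rec_of(np.zeros(5000)))
        assert np.allclose(out.samples, 0)

    def test_line_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            notch_line_noise(rec_of(tone(20.0)), line_hz=600.0)


class TestArtifactRepair:
    def test_pure_sinusoid_untouched(self):
        rec = rec_of(tone(16.0))
        out, frac = detect_and_repair_artifacts(rec)
        assert frac == 0.0
        assert np.array_equal(out.samples, rec.samples)

    def test_three_spikes_repaired_and_clean_after(self, rng):
        rec = rec_of(tone(16.0, duration=20.0) + 0.05 * rng.standard_normal(20000))
        spiked, _ = inject_artifacts(rec, ArtifactSpec(count=3, amplitude_mad=50.0), rng)
        out, frac = detect_and_repair_artifacts(spiked)
        runs = np.diff(np.r_[0, out.artifact_mask[0].astype(int), 0])
        assert (runs == 1).sum() == 3
        assert 0 < frac < 0.01
        _, frac2 = detect_and_repair_artifacts(out)
        assert frac2 == 0.0

    def test_flat_recording_degenerate(self):
        with pytest.raises(DegenerateScaleError):
            detect_and_repair_artifacts(rec_of(np.ones(5000)))


class TestMultitaperPSD:
    def test_tone_peak_location(self):
        sp = multitaper_psd(rec_of(tone(20.0)))[0]
        assert abs(sp.freqs[np.argmax(sp.psd)] - 20.0) <= 2.0
        assert sp.freqs[0] >= ANALYSIS_RANGE[0] and sp.freqs[-1] <= ANALYSIS_RANGE[1]

    def test_zero_signal_zero_psd(self):
        sp = multitaper_psd(rec_of(np.zeros(5000)))[0]
        assert np.allclose(sp.psd, 0)

    def test_white_noise_band_averaged_flat(self, rng):
        sp = multitaper_psd(rec_of(rng.standard_normal(200_000)))[0]
        mean = sp.psd.mean()
        for band in DEFAULT_BANDS:
            sel = (sp.freqs >= band.f_lo) & (sp.freqs <= band.f_hi)
            assert abs(sp.psd[sel].mean() - mean) < 0.10 * mean

    def test_too_short_recording(self):
        with pytest.raises(ValueError):
            multitaper_psd(rec_of(np.zeros(500)))


class TestNormalizeSpectrum:
    def test_flat_spectrum_uniform(self):
        freqs = np.arange(4.0, 111.0)
        sp = SpectralEstimate(freqs=freqs, psd=np.ones_like(freqs))
        out = normalize_spectrum(sp)
        m = out.included.sum()
        assert np.allclose(out.psd[out.included], 1.0 / m)
        assert not out.included[(freqs >= 58) & (freqs <= 62)].any()

    def test_included_bins_sum_to_one(self, rng):
        freqs = np.arange(4.0, 111.0)
        sp = SpectralEstimate(freqs=freqs, psd=rng.uniform(0.1, 2.0, freqs.size))
        out = normalize_spectrum(sp)
        assert out.psd[out.included].sum() == pytest.approx(1.0)

    def test_line_only_power_errors(self):
        freqs = np.arange(4.0, 111.0)
        psd = np.where((freqs >= 58) & (freqs <= 62), 1.0, 0.0)
        with pytest.raises(ValueError):
            normalize_spectrum(SpectralEstimate(freqs=freqs, psd=psd))


class TestBandPower:
    def test_flat_normalized_equals_uniform_mean(self):
        freqs = np.arange(4.0, 111.0)
        sp = normalize_spectrum(SpectralEstimate(freqs=freqs, psd=np.ones_like(freqs)))
        m = sp.included.sum()
        for band in DEFAULT_BANDS:
            assert band_power(sp, band) == pytest.approx(1.0 / m)

    def test_tone_concentrates_power(self):
        sp = normalize_spectrum(multitaper_psd(rec_of(tone(25.0)))[0])
        hb = band_power(sp, DEFAULT_BANDS[2])
        al = band_power(sp, DEFAULT_BANDS[0])
        assert hb > 100 * al

    def test_out_of_band_tone_negligible(self):
        sp = normalize_spectrum(multitaper_psd(rec_of(tone(10.0)))[0])
        assert band_power(sp, DEFAULT_BANDS[3]) < 1e-3 * band_power(sp, DEFAULT_BANDS[0])


class TestBandEnvelope:
    def test_center_carrier_amplitude_recovered(self, low_beta):
        env = band_envelope(rec_of(tone(16.0, amp=2.0)), low_beta)[0]
        interior = env[2000:-2000]
        assert np.all(np.abs(interior - 2.0) < 0.04)

    def test_zero_signal(self, low_beta):
        env = band_envelope(rec_of(np.zeros(5000)), low_beta)
        assert np.allclose(env, 0)

    def test_stopband_tone_suppressed(self, low_beta):
        env = band_envelope(rec_of(tone(60.0)), low_beta)[0]
        assert env[1000:-1000].max() < 0.05

    def test_band_above_nyquist(self):
        with pytest.raises(ValueError):
            band_envelope(rec_of(tone(10.0)), BandDefinition("hf", 400.0, 600.0))


class TestDetectBursts:
    def test_constant_envelope_no_bursts(self, low_beta):
        bs = detect_bursts(np.ones(5000), low_beta, FS)
        assert bs.bursts == []

    def test_planted_bursts_recovered(self, low_beta):
        rec, truth = simulate_oscillatory_channel(planted_burst_config(21))
        env = band_envelope(rec, low_beta)[0]
        bs = detect_bursts(env, low_beta, FS)
        assert len(bs.bursts) == len(truth.burst_intervals["low_beta"]) == 10
        mean_dur = np.mean([b.duration_s for b in bs.bursts])
        assert abs(mean_dur - 0.3) < 0.03

    def test_sub_cycle_run_rejected(self, low_beta):
        env = np.zeros(5000)
        env[1000:1030] = 1.0  # 30 ms < one 16 Hz cycle (62.5 ms)
        bs = detect_bursts(env, low_beta, FS)
        assert bs.bursts == []

    def test_peak_amplitude_mode(self, low_beta):
        env = np.zeros(5000)
        env[1000:1100] = np.linspace(1.0, 2.0, 100)
        mean_bs = detect_bursts(env, low_beta, FS, amp_mode="mean")
        peak_bs = detect_bursts(env, low_beta, FS, amp_mode="peak")
        assert peak_bs.bursts[0].amplitude == pytest.approx(2.0)
        assert mean_bs.bursts[0].amplitude < 2.0

    def test_artifact_samples_excluded_from_threshold(self, low_beta):
        env = np.ones(8000)
        env[:2000] = 10.0
        mask = np.zeros(8000, bool)
        mask[:2000] = True
        bs = detect_bursts(env, low_beta, FS, artifact_mask=mask)
        # clean samples are constant -> threshold 1, only the artifact span exceeds
        assert bs.threshold == 1.0
        assert bs.clean_duration_s == pytest.approx(6.0)

    def test_burst_fraction_bounded_by_quantile(self, low_beta, rng):
        env = np.abs(rng.standard_normal(20000)).cumsum() * 0  # placeholder replaced below
        env = np.abs(np.convolve(rng.standard_normal(20000), np.ones(50) / 50, mode="same"))
        bs = detect_bursts(env, low_beta, FS)
        frac = sum(b.duration_s for b in bs.bursts) / (len(env) / FS)
        assert frac <= 0.25 + 1e-9


class TestRecordingIO:
    def test_round_trip_with_sidecar(self, tmp_path, rng):
        from neurolatent.signals import read_recording, write_recording

        rec = rec_of(np.vstack([tone(16.0, 2.0), tone(9.0, 2.0)]), labels=("M1", "PM"))
        write_recording(rec, tmp_path / "rec.tsv")
        back = read_recording(tmp_path / "rec.tsv")
        assert back.labels == ["M1", "PM"] and back.fs == rec.fs
        assert np.allclose(back.samples, rec.samples, atol=1e-12)


class TestBurstSummary:
    def test_rate_arithmetic(self):
        bursts = [Burst(i * 2.0, i * 2.0 + 0.5, 1.0) for i in range(10)]
        bs = BurstSet("low_beta", bursts, threshold=0.5, clean_duration_s=20.0)
        s = burst_summary(bs)
        assert s["rate"] == pytest.approx(0.5)
        assert s["duration"] == pytest.approx(0.5)

    def test_empty_set_missing_flags(self):
        s = burst_summary(BurstSet("alpha", [], threshold=1.0, clean_duration_s=10.0))
        assert s["rate"] == 0.0
        assert np.isnan(s["duration"]) and np.isnan(s["amplitude"])

    def test_zero_duration_errors(self):
        with pytest.raises(ValueError):
            burst_summary(BurstSet("alpha", [], threshold=1.0, clean_duration_s=0.0))


class TestCoherence:
    def test_identical_channels_unity(self, low_beta, rng):
        x = rng.standard_normal(20000)
        assert msc_coherence(x, x, FS, low_beta) == pytest.approx(1.0)

    def test_independent_noise_low(self, low_beta, rng):
        x = rng.standard_normal(100_000)
        y = rng.standard_normal(100_000)
        assert msc_coherence(x, y, FS, low_beta) < 0.1

    def test_symmetric(self, low_beta, rng):
        cfg = SignalSimConfig(duration_s=30, bursts=(BurstSpec("low_beta", 16.0),), seed=4)
        rec, _ = simulate_coupled_channels(cfg, mix=0.6)
        a = msc_coherence(rec.samples[0], rec.samples[1], FS, low_beta)
        b = msc_coherence(rec.samples[1], rec.samples[0], FS, low_beta)
        assert a == pytest.approx(b)
        assert 0.0 <= a <= 1.0

    def test_single_window_rejected(self, low_beta, rng):
        x = rng.standard_normal(1000)
        with pytest.raises(ValueError, match="two analysis windows"):
            msc_coherence(x, x, FS, low_beta)


def make_multichannel(seed, labels=("M1", "PM", "S1", "SubCort"), duration=20.0):
    chans = []
    for j, lab in enumerate(labels):
        cfg = SignalSimConfig(
            duration_s=duration,
            bursts=(BurstSpec("low_beta", 16.0, rate_hz=0.3, amplitude=1.0, baseline=0.3),),
            seed=seed + j,
        )
        rec, _ = simulate_oscillatory_channel(cfg, label=lab)
        chans.append(rec)
    return Recording(
        samples=np.vstack([c.samples for c in chans]),
        fs=FS,
        labels=list(labels),
    )


class TestFeatureAssembly:
    def test_default_enumeration_84_columns(self):
        names = physio_feature_names()
        assert len(names) == 84
        assert len(set(names)) == 84
        assert names[0] == "power.alpha.M1"

    def test_theta_band_adds_21_columns(self):
        cfg = FeatureConfig(bands=DEFAULT_BANDS + (BandDefinition("theta", 4.0, 7.0),))
        assert len(physio_feature_names(cfg)) == 84 + 21

    def test_build_features_table(self):
        table = build_physio_features({"A": make_multichannel(100)})
        assert table.shape == (1, 84)
        assert table.isna().sum().sum() == 0
        assert (table.filter(like="power.").iloc[0] > 0).all()
        coh = table.iloc[0].filter(like="coh_")
        assert ((coh >= 0) & (coh <= 1)).all()

    def test_missing_site_flags_not_errors(self):
        table = build_physio_features(
            {"A": make_multichannel(200, labels=("M1", "PM", "SubCort"))}
        )
        s1_cols = [c for c in table.columns if c.endswith(".S1") or "S1-" in c or "-S1" in c]
        assert table[s1_cols].isna().all().all()
        other = [c for c in table.columns if c not in s1_cols]
        assert table[other].notna().all().all()

    def test_no_pallidal_channel_errors(self):
        with pytest.raises(ValueError, match="pallidal"):
            build_physio_features({"A": make_multichannel(300, labels=("M1", "PM", "S1"))})

    def test_gain_invariance(self):
        rec = make_multichannel(400)
        rec10 = Recording(rec.samples * 10.0, fs=rec.fs, labels=list(rec.labels))
        t1 = build_physio_features({"A": rec}).iloc[0]
        t2 = build_physio_features({"A": rec10}).iloc[0]
        amp_cols = [c for c in t1.index if c.startswith("burst_amp.")]
        inv_cols = [c for c in t1.index if c not in amp_cols]
        assert np.allclose(t1[inv_cols], t2[inv_cols], rtol=1e-6)
        assert np.allclose(10.0 * t1[amp_cols], t2[amp_cols], rtol=1e-6)
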