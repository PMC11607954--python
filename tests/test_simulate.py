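"""Synthetic radar-bed generator: beat model, displacement, I/Q, reference."""

import numpy as np
import pytest
from scipy import signal

from radarhr import (
    SimulationConfig, generate_beat_times, synthesize_displacement,
    modulate_iq, generate_reference_beats, simulate_recording,
    demodulate_displacement, extract_heart_sound,
)


def config(**kw):
    kw.setdefault("sampling_rate", 500.0)
    kw.setdefault("n_channels", 1)
    kw.setdefault("channel_snr", (np.inf,))
    kw.setdefault("artifact_rate", 0.0)
    return SimulationConfig(**kw)


class TestBeatTimes:
    def test_zero_variance_is_metronomic(self):
        truth = generate_beat_times(config(duration=300.0, base_hr=60.0, hrv_sd=0.0))
        assert abs(truth.n_beats - 300) <= 1
        np.testing.assert_allclose(np.diff(truth.beat_times), 1.0, atol=1e-9)

    def test_mean_rate_matches_base_hr(self):
        # white HRV only (no drift): the mean instantaneous rate obeys the
        # law of large numbers around base_hr
        truth = generate_beat_times(config(duration=60.0, base_hr=80.0,
                                           hrv_sd=3.0, drift_innovation_sd=0.0,
                                           seed=4))
        inst = 60.0 / np.diff(truth.beat_times)
        assert abs(inst.mean() - 80.0) < 1.0

    def test_ves_affected_ibi_fraction(self):
        # ~5573 beats at 75 bpm needs ~4460 s; 39% affected IBIs as in a
        # heavily extrasystolic subject
        truth = generate_beat_times(config(duration=4460.0, base_hr=75.0,
                                           hrv_sd=2.0, ves_fraction=0.39, seed=2))
        assert abs(truth.n_beats - 5573) < 120
        frac = truth.n_affected_ibis / truth.n_beats
        assert abs(frac - 0.39) < 0.01
        assert truth.beat_times.size == truth.beat_labels.size
        assert np.all(np.diff(truth.beat_times) > 0)

    def test_s2_offset_is_systolic_fraction(self):
        truth = generate_beat_times(config(duration=60.0, base_hr=60.0, hrv_sd=0.0))
        ibis = np.diff(truth.beat_times)
        np.testing.assert_allclose(truth.s2_offsets[:-1], 0.33 * ibis, rtol=1e-9)

    def test_rejects_bad_base_hr(self):
        with pytest.raises(ValueError):
            config(base_hr=-10.0)
        with pytest.raises(ValueError):
            config(base_hr=np.nan)

    def test_beat_count_conservation(self):
        # artifact-free, deterministic IBIs: count tracks the HR integral
        cfg = config(duration=600.0, base_hr=70.0, hrv_sd=0.0,
                     trend_knots=((0.0, 0.0), (300.0, 12.0), (600.0, 12.0)))
        truth = generate_beat_times(cfg)
        expected = truth.true_hr.sum() / 60.0
        assert abs(truth.n_beats - expected) <= 2


class TestDisplacement:
    def test_silence_is_exactly_zero(self):
        cfg = config(duration=20.0, base_hr=60.0, hrv_sd=0.0, resp_amplitude=0.0,
                     s1_amplitude=0.0, s2_amplitude=0.0)
        truth = generate_beat_times(cfg)
        d = synthesize_displacement(truth, cfg)
        assert np.all(d == 0.0)

    def test_single_beat_bandpassed_peak_scale(self):
        from radarhr.simulate import GroundTruth
        cfg = config(duration=10.0, resp_amplitude=0.0, s1_amplitude=30.0,
                     s2_amplitude=0.0)
        truth = GroundTruth(beat_times=np.array([5.0]), s2_offsets=np.array([0.3]),
                            true_hr=np.full(10, 60.0),
                            beat_labels=np.array(["normal"], dtype=object))
        d = synthesize_displacement(truth, cfg)
        from radarhr import DisplacementSignal
        hs = extract_heart_sound(DisplacementSignal(d, cfg.sampling_rate))
        i = np.argmax(np.abs(hs.values))
        peak = abs(hs.values[i])
        assert 0.5 * 30.0 <= peak <= 1.0 * 30.0
        assert abs(i / cfg.sampling_rate - 5.0) < 0.05

    def test_respiration_dominates_below_1hz(self):
        cfg = config(duration=120.0, base_hr=60.0, hrv_sd=0.0,
                     resp_amplitude=5.0, s1_amplitude=30.0, s2_amplitude=0.0)
        truth = generate_beat_times(cfg)
        d = synthesize_displacement(truth, cfg)
        f, pxx = signal.welch(d, fs=cfg.sampling_rate, nperseg=1 << 14)
        p_low = pxx[f <= 1.0].sum()
        p_band = pxx[(f >= 16.0) & (f <= 80.0)].sum()
        assert 10.0 * np.log10(p_low / p_band) >= 40.0

    def test_zero_during_absence(self):
        cfg = config(duration=60.0, absence_intervals=((20.0, 40.0),))
        truth = generate_beat_times(cfg)
        d = synthesize_displacement(truth, cfg)
        fs = cfg.sampling_rate
        assert np.all(d[int(20 * fs):int(40 * fs)] == 0.0)
        assert np.any(d[: int(20 * fs)] != 0.0)


class TestIQModulation:
    def test_constant_displacement_constant_iq(self):
        cfg = config(duration=2.0)
        iq = modulate_iq(np.zeros(1000), cfg)
        assert np.allclose(iq.samples, iq.samples[0])

    def test_phase_excursion_closed_form(self):
        # 1 mm sweep at lambda = 12.49 mm -> 4*pi/12.49 = 1.006 rad
        cfg = config(duration=2.0)
        d_um = np.linspace(0.0, 1000.0, 1000)
        iq = modulate_iq(d_um, cfg)
        d_rec = demodulate_displacement(iq)
        excursion_rad = (d_rec.values.max() - d_rec.values.min()) / 1000.0 \
            * 4.0 * np.pi / cfg.carrier_wavelength
        assert abs(excursion_rad - 1.006) < 0.01

    def test_roundtrip_identity_noiseless(self):
        cfg = config(duration=30.0, base_hr=75.0, resp_amplitude=1.0,
                     s1_amplitude=30.0)
        truth = generate_beat_times(cfg)
        d = synthesize_displacement(truth, cfg)
        iq = modulate_iq(d, cfg)
        rec = demodulate_displacement(iq)
        rmse = np.sqrt(np.mean((rec.values - (d - d.mean())) ** 2))
        assert rmse < 0.1  # um

    def test_roundtrip_in_band_at_high_snr(self):
        cfg = config(duration=30.0, base_hr=75.0, resp_amplitude=1.0,
                     s1_amplitude=30.0, channel_snr=(50.0,), seed=3)
        truth = generate_beat_times(cfg)
        d = synthesize_displacement(truth, cfg)
        iq = modulate_iq(d, cfg)
        rec = demodulate_displacement(iq)
        from radarhr import DisplacementSignal
        band_true = extract_heart_sound(DisplacementSignal(d, cfg.sampling_rate)).values
        band_rec = extract_heart_sound(rec).values
        rmse = np.sqrt(np.mean((band_rec - band_true) ** 2))
        assert rmse < 1.0  # um, in the 16-80 Hz band


class TestReferenceBeats:
    def test_zero_jitter_is_exact(self):
        truth = generate_beat_times(config(duration=60.0))
        ref = generate_reference_beats(truth, jitter_sd=0.0)
        np.testing.assert_array_equal(ref.times, truth.beat_times)
        assert ref.resolution_hz == 1000.0

    def test_half_normal_mean_shift(self):
        truth = generate_beat_times(config(duration=1000.0, base_hr=60.0,
                                           hrv_sd=0.0))
        assert truth.n_beats >= 990
        ref = generate_reference_beats(truth, jitter_sd=5.0, seed=7)
        shift = np.abs(ref.times - truth.beat_times) * 1000.0
        # E|N(0, 5 ms)| = 5 * sqrt(2/pi) ~= 3.99 ms
        assert abs(shift.mean() - 3.99) < 0.5

    def test_absence_masks_reference(self):
        cfg = config(duration=300.0, absence_intervals=((100.0, 200.0),))
        truth = generate_beat_times(cfg)
        ref = generate_reference_beats(truth, jitter_sd=0.0)
        assert not np.any((ref.times >= 100.0) & (ref.times < 200.0))

    def test_negative_jitter_rejected(self):
        truth = generate_beat_times(config(duration=30.0))
        with pytest.raises(ValueError):
            generate_reference_beats(truth, jitter_sd=-1.0)


class TestDeterminism:
    def test_identical_seeds_bit_identical(self):
        cfg = SimulationConfig(duration=30.0, sampling_rate=500.0, seed=99,
                               channel_snr=(20.0, 10.0), n_channels=2)
        a = simulate_recording(cfg)
        b = simulate_recording(cfg)
        for ca, cb in zip(a.channels, b.channels):
            np.testing.assert_array_equal(ca.samples, cb.samples)
        np.testing.assert_array_equal(a.ground_truth.beat_times,
                                      b.ground_truth.beat_times)
        np.testing.assert_array_equal(a.reference_beats.times,
                                      b.reference_beats.times)

    def test_different_seeds_differ(self):
        cfg1 = SimulationConfig(duration=30.0, sampling_rate=500.0, seed=1,
                                n_channels=1, channel_snr=(20.0,))
        cfg2 = SimulationConfig(duration=30.0, sampling_rate=500.0, seed=2,
                                n_channels=1, channel_snr=(20.0,))
        a, b = simulate_recording(cfg1), simulate_recording(cfg2)
        assert not np.array_equal(a.ground_truth.beat_times,
                                  b.ground_truth.beat_times)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"duration": 0.0},
        {"duration": -5.0},
        {"sampling_rate": 150.0},
        {"ves_fraction": 0.7, "sves_fraction": 0.5},
        {"resp_amplitude": -1.0},
        {"carrier_wavelength": 0.0},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            config(**kw)
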