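"""HR aggregation, pairing, exclusion rules and outlier filters."""

import numpy as np
import pandas as pd
import pytest

from radarhr import (
    BeatSequence, HRSeries, PairedHRSeries, AnnotationSet, SimulationConfig,
    compute_ibis, generate_beat_times,
    interval_mean_hr, rolling_mean_hr, block_mean_hr, synchronize_pairs,
    exclude_half_double, apply_annotations, annotation_burden,
    should_exclude_patient, global_outlier_filter, local_outlier_filter,
)


def beats_from_ibis(ibis, t0=0.0):
    s1 = t0 + np.concatenate([[0.0], np.cumsum(ibis)])
    return compute_ibis(BeatSequence(s1_times=s1))


def make_pairs(radar, ref, reasons=None):
    radar = np.asarray(radar, dtype=float)
    ref = np.asarray(ref, dtype=float)
    frame = pd.DataFrame({
        "t": np.arange(radar.size, dtype=float),
        "radar_hr": radar, "ref_hr": ref, "diff": radar - ref,
        "exclusion_reason": reasons if reasons is not None else "none",
    })
    return PairedHRSeries(frame)


class TestIntervalMean:
    def test_constant_ibis(self):
        beats = beats_from_ibis(np.ones(600))
        hr = interval_mean_hr(beats, width=300.0, duration=600.0)
        assert np.all(hr.hr[hr.valid] == 60.0)

    def test_mean_of_ibis_not_of_rates(self):
        # mean of the intervals (1.0 s), not mean of the rates (75+50)/2
        ibis = np.tile([0.8, 1.2], 149)
        hr = interval_mean_hr(beats_from_ibis(ibis), width=300.0, duration=300.0)
        np.testing.assert_allclose(hr.hr[hr.valid], 60.0, atol=1e-12)

    def test_long_run_tracks_base_hr(self):
        cfg = SimulationConfig(duration=30000.0, base_hr=75.0, hrv_sd=2.0,
                               sampling_rate=500.0, n_channels=1,
                               channel_snr=(20.0,), seed=17)
        truth = generate_beat_times(cfg)
        beats = compute_ibis(BeatSequence(s1_times=truth.beat_times))
        hr = interval_mean_hr(beats, width=300.0, duration=30000.0)
        assert hr.hr.size == 100
        assert np.all(np.abs(hr.hr[hr.valid] - 75.0) < 2.0)

    def test_sparse_interval_invalid(self):
        beats = beats_from_ibis(np.ones(5))
        hr = interval_mean_hr(beats, width=300.0, duration=300.0)
        assert not hr.valid[0]


class TestRollingMean:
    def test_single_window(self):
        hr = rolling_mean_hr(beats_from_ibis(np.full(10, 0.75)), k=10)
        assert hr.hr.size == 1
        np.testing.assert_allclose(hr.hr, [80.0])

    def test_window_update(self):
        ibis = np.concatenate([np.ones(10), [0.5]])
        hr = rolling_mean_hr(beats_from_ibis(ibis), k=10)
        np.testing.assert_allclose(hr.hr[-1], 60.0 / 0.95, rtol=1e-9)  # 63.16

    def test_insufficient_ibis_empty(self):
        assert rolling_mean_hr(beats_from_ibis(np.ones(5)), k=10).hr.size == 0


class TestBlockMean:
    def test_thirty_fast_beats(self):
        hr = block_mean_hr(beats_from_ibis(np.full(30, 0.5)), k=30)
        np.testing.assert_allclose(hr.hr, [120.0])

    def test_block_count(self):
        hr = block_mean_hr(beats_from_ibis(np.ones(90)), k=30)
        assert hr.hr.size == 3

    def test_ramp_reproduced_in_time_blocks(self):
        # +10 bpm ramp over 30 min, as seen around a symptom episode
        cfg = SimulationConfig(duration=1800.0, base_hr=75.0, hrv_sd=1.0,
                               sampling_rate=500.0, n_channels=1,
                               channel_snr=(20.0,), seed=19,
                               trend_knots=((0, 0), (600, 0), (1200, 10), (1800, 10)))
        truth = generate_beat_times(cfg)
        beats = compute_ibis(BeatSequence(s1_times=truth.beat_times))
        hr = block_mean_hr(beats, mode="time", width=30.0, duration=1800.0)
        mid = np.interp(hr.timestamps + 15.0, [0, 600, 1200, 1800], [75, 75, 85, 85])
        assert np.all(np.abs(hr.hr[hr.valid] - mid[hr.valid]) < 2.0)

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            block_mean_hr(beats_from_ibis(np.ones(40)), mode="nope")


class TestAggregatorConsistency:
    def test_all_rules_agree_on_constant_input(self):
        beats = beats_from_ibis(np.ones(600))
        hr_i = interval_mean_hr(beats, width=300.0, duration=600.0)
        hr_r = rolling_mean_hr(beats, k=10)
        hr_b = block_mean_hr(beats, k=30)
        for hr in (hr_i, hr_r, hr_b):
            np.testing.assert_allclose(hr.hr[hr.valid], 60.0, atol=1e-12)


class TestSynchronize:
    def test_identical_interval_series(self):
        ts = np.arange(0.0, 3000.0, 300.0)
        hr = HRSeries(timestamps=ts, hr=np.full(10, 70.0), aggregation="interval_5min")
        ref = HRSeries(timestamps=ts, hr=np.full(10, 70.0), aggregation="interval_5min")
        pairs = synchronize_pairs(hr, ref)
        assert np.all(pairs.frame["diff"] == 0.0)
        assert pairs.exclusion_counts()["none"] == 10

    def test_dropout_counted_as_missing_radar(self, rng):
        # 12% radar dropout -> 12% missing_radar exclusions
        n = 1000
        ts = np.arange(n) * 300.0
        valid = np.ones(n, dtype=bool)
        valid[rng.choice(n, size=120, replace=False)] = False
        radar = HRSeries(timestamps=ts, hr=np.full(n, 70.0),
                         aggregation="interval_5min", valid=valid)
        ref = HRSeries(timestamps=ts, hr=np.full(n, 70.0),
                       aggregation="interval_5min")
        counts = synchronize_pairs(radar, ref).exclusion_counts()
        assert counts["missing_radar"] == 120
        assert counts["none"] == 880

    def test_beat_mode_nearest_within_tolerance(self):
        radar = HRSeries(timestamps=np.array([10.0, 11.0, 12.0]),
                         hr=np.array([60.0, 61.0, 62.0]), aggregation="rolling_10beat")
        ref = HRSeries(timestamps=np.array([10.02, 11.4, 25.0]),
                       hr=np.array([60.5, 61.5, 62.5]), aggregation="rolling_10beat")
        pairs = synchronize_pairs(radar, ref, tolerance=0.2)
        reasons = list(pairs.frame["exclusion_reason"])
        assert reasons == ["none", "missing_radar", "missing_radar"]

    def test_disjoint_clocks_no_matches(self):
        radar = HRSeries(timestamps=np.arange(3) + 1000.0, hr=np.full(3, 60.0),
                         aggregation="rolling_10beat")
        ref = HRSeries(timestamps=np.arange(3, dtype=float), hr=np.full(3, 60.0),
                       aggregation="rolling_10beat")
        pairs = synchronize_pairs(radar, ref, tolerance=0.5)
        assert pairs.exclusion_counts()["none"] == 0


class TestHalfDouble:
    @pytest.mark.parametrize("radar,ref,excluded", [
        (41.0, 80.0, True),    # near half
        (78.0, 80.0, False),   # honest
        (160.0, 80.0, True),   # exact double
        (44.1, 80.0, False),   # just outside the 10% band around 40
        (43.9, 80.0, True),    # just inside
    ])
    def test_rule(self, radar, ref, excluded):
        pairs = exclude_half_double(make_pairs([radar], [ref]))
        got = pairs.frame["exclusion_reason"].iloc[0] == "half_double"
        assert got == excluded

    def test_idempotent(self):
        pairs = make_pairs([41.0, 78.0, 160.0], [80.0, 80.0, 80.0])
        once = exclude_half_double(pairs)
        twice = exclude_half_double(once)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_does_not_touch_already_excluded(self):
        pairs = make_pairs([41.0], [80.0], reasons=["missing_radar"])
        out = exclude_half_double(pairs)
        assert out.frame["exclusion_reason"].iloc[0] == "missing_radar"


class TestAnnotations:
    def test_empty_annotations_noop(self):
        pairs = make_pairs(np.full(20, 70.0), np.full(20, 70.0))
        out = apply_annotations(pairs, AnnotationSet.from_records([]), k=10)
        pd.testing.assert_frame_equal(out.frame, pairs.frame)

    def test_single_ves_taints_k_windows(self):
        # rows correspond to rolling values ending at beats 10..59
        pairs = make_pairs(np.full(50, 70.0), np.full(50, 70.0))
        ann = AnnotationSet.from_records([(50, "VES")])
        out = apply_annotations(pairs, ann, k=10)
        excluded = np.flatnonzero(out.frame["exclusion_reason"] == "arrhythmia_label")
        assert excluded.size == 10
        assert list(excluded) == list(range(40, 50))  # windows ending at beats 50..59

    def test_noisy_label_reason(self):
        pairs = make_pairs(np.full(20, 70.0), np.full(20, 70.0))
        out = apply_annotations(pairs, AnnotationSet.from_records([(15, "noisy")]), k=10)
        assert (out.frame["exclusion_reason"] == "noisy_reference").sum() == 10

    def test_out_of_range_index_rejected(self):
        pairs = make_pairs(np.full(5, 70.0), np.full(5, 70.0))
        with pytest.raises(ValueError, match="out of range"):
            apply_annotations(pairs, AnnotationSet.from_records([(99, "VES")]), k=10)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            AnnotationSet.from_records([(1, "weird")])

    def test_burden_and_patient_exclusion(self):
        # 1086 extrasystoles among 5573 beats -> 2172 affected -> 39.0%
        ann = AnnotationSet.from_records(
            [(int(i), "VES") for i in np.arange(2, 5560, 5.12)][:1086])
        burden = annotation_burden(ann, 5573)
        assert abs(burden - 0.390) < 0.005
        assert should_exclude_patient(ann, 5573, threshold=0.20)
        light = AnnotationSet.from_records([(10, "VES")])
        assert not should_exclude_patient(light, 5573, threshold=0.20)


class TestOutlierFilters:
    def series(self, values, **kw):
        values = np.asarray(values, dtype=float)
        return HRSeries(timestamps=np.arange(values.size, dtype=float) * 30.0,
                        hr=values, aggregation="block_30s", **kw)

    def test_global_removes_impossible(self):
        hr = global_outlier_filter(self.series([70.0, 300.0, 80.0]))
        assert list(hr.valid) == [True, False, True]

    def test_global_keeps_in_range(self):
        hr = global_outlier_filter(self.series([70.0, 80.0, 90.0]))
        assert np.all(hr.valid)

    def test_global_bad_thresholds(self):
        with pytest.raises(ValueError):
            global_outlier_filter(self.series([70.0]), lo=100.0, hi=50.0)

    def test_local_constant_untouched(self):
        hr = local_outlier_filter(self.series(np.full(100, 75.0)))
        assert np.all(hr.valid)

    def test_local_spike_removed(self):
        vals = np.full(60, 75.0)
        vals[30] = 115.0
        hr = local_outlier_filter(self.series(vals))
        assert not hr.valid[30]
        assert hr.valid.sum() == 59

    def test_local_preserves_medication_ramp(self):
        # a genuine 10-bpm drop over 20 min must survive
        t = np.arange(0, 3600.0, 30.0)
        vals = 85.0 - 10.0 * np.clip((t - 1200.0) / 1200.0, 0.0, 1.0)
        hr = local_outlier_filter(self.series(vals))
        assert np.all(hr.valid)

    def test_filters_idempotent(self, rng):
        vals = 75.0 + rng.normal(0, 2, 300)
        vals[rng.choice(300, 5, replace=False)] += 60.0
        hr = self.series(vals)
        once = local_outlier_filter(global_outlier_filter(hr))
        twice = local_outlier_filter(global_outlier_filter(once))
        np.testing.assert_array_equal(once.valid, twice.valid)

    def test_local_segment_too_small(self):
        with pytest.raises(ValueError):
            local_outlier_filter(self.series(np.full(10, 75.0)), segment=3)
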