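import numpy as np
import pytest

from wristhr import simulate as sim


class TestMakeSchedule:
    def test_default_matches_protocol_table(self):
        sch = sim.make_schedule()
        assert len(sch.segments) == 9
        assert sch.total_duration == 29 * 60.0
        acts = [s.activity for s in sch.segments]
        assert acts == [
            "A_rest", "B_read", "A_rest", "D_walk_slow", "A_rest",
            "C_write", "A_rest", "E_walk_fast", "A_rest",
        ]
        minutes = [s.duration_s / 60 for s in sch.segments]
        assert minutes == [5, 3, 2, 5, 2, 3, 2, 5, 2]

    def test_single_segment(self):
        sch = sim.make_schedule([("A_rest", 1.0)])
        assert len(sch.segments) == 1
        assert sch.segments[0].duration_s == 60.0
        assert sch.segments[0].group == 1

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError, match="at least one segment"):
            sim.make_schedule([])

    def test_unknown_activity_named_in_error(self):
        with pytest.raises(ValueError, match="F_jump"):
            sim.make_schedule([("F_jump", 1.0)])

    def test_group_mapping_total(self):
        assert {sim.ACTIVITY_GROUP[a] for a in sim.ACTIVITIES} == {1, 2, 3}

    def test_activity_at(self):
        sch = sim.make_schedule([("A_rest", 1.0), ("D_walk_slow", 1.0)])
        assert sch.activity_at(np.array([0.0, 59.9])).tolist() == ["A_rest"] * 2
        assert sch.activity_at(np.array([60.0, 119.0])).tolist() == ["D_walk_slow"] * 2


class TestPhysiology:
    def test_defaults_valid(self):
        sim.UserPhysiology()

    @pytest.mark.parametrize("bad", [{"resting_hr": 30.0}, {"resting_hr": 120.0},
                                     {"temp_lag": -1.0}, {"hr_time_constant": 0.0}])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            sim.UserPhysiology(**bad)

    def test_delta_ordering_enforced(self):
        deltas = dict(A_rest=0.0, B_read=5.0, C_write=5.0, D_walk_slow=2.0,
                      E_walk_fast=10.0)
        with pytest.raises(ValueError, match="non-decreasing"):
            sim.UserPhysiology(hr_delta_per_activity=deltas)

    def test_sampled_physiology_in_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = sim.sample_physiology(rng)
            assert 45.0 <= p.resting_hr <= 85.0
            assert 33.0 <= p.base_temperature <= 35.0

    def test_negative_artifact_gain_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            sim.ArtifactModel(mmec_gain=-0.1)


class TestHrTrace:
    def test_constant_60_gives_peaks_1s_apart(self):
        sch = sim.make_schedule([("A_rest", 2.0)])
        phys = sim.UserPhysiology(resting_hr=60.0, ibi_jitter_sd=0.0)
        _, hr, peaks = sim.simulate_hr_trace(sch, phys)
        assert np.allclose(hr, 60.0)
        assert np.allclose(np.diff(peaks), 1.0, atol=1e-9)

    def test_exponential_relaxation_reaches_target(self):
        # after 3 time constants the response covers >= 95% of the step
        deltas = dict(A_rest=0.0, B_read=0.0, C_write=0.0, D_walk_slow=0.0,
                      E_walk_fast=30.0)
        phys = sim.UserPhysiology(resting_hr=60.0, hr_delta_per_activity=deltas,
                                  hr_time_constant=35.0, ibi_jitter_sd=0.0)
        sch = sim.make_schedule([("A_rest", 1.0), ("E_walk_fast", 4.0)])
        t, hr, _ = sim.simulate_hr_trace(sch, phys)
        after_3tau = t >= 60.0 + 3 * 35.0
        assert np.all(hr[after_3tau] >= 60.0 + 0.95 * 30.0)

    def test_same_seed_identical_peaks(self):
        sch = sim.make_schedule([("A_rest", 2.0)])
        phys = sim.UserPhysiology(random_seed=5)
        _, _, p1 = sim.simulate_hr_trace(sch, phys)
        _, _, p2 = sim.simulate_hr_trace(sch, phys)
        assert np.array_equal(p1, p2)


class TestSession:
    def test_channel_shapes_and_rates(self, short_session, short_schedule):
        dur = short_schedule.total_duration
        assert len(short_session.ppg) == int(dur * 20)
        assert short_session.accel.shape == (int(dur * 10), 3)
        assert short_session.gyro.shape == (int(dur * 10), 3)
        assert len(short_session.temperature) == int(dur * 0.1)
        assert len(short_session.reference_ecg) == int(dur * 250)
        assert short_session.reference_accel.shape == (int(dur * 100), 3)
        assert len(short_session.task_track) == len(short_session.ppg)

    def test_determinism_bit_identical(self, short_schedule):
        phys = sim.UserPhysiology(random_seed=9)
        a = sim.simulate_session(short_schedule, phys, clock_offset=1.0)
        b = sim.simulate_session(short_schedule, phys, clock_offset=1.0)
        assert np.array_equal(a.ppg, b.ppg)
        assert np.array_equal(a.accel, b.accel)
        assert np.array_equal(a.temperature, b.temperature)
        assert np.array_equal(a.reference_ecg, b.reference_ecg)

    def test_intensity_bounded_by_input(self, short_schedule):
        phys = sim.UserPhysiology(random_seed=3)
        art = sim.ArtifactModel(ppg_noise_sd=0.0)
        s = sim.simulate_session(short_schedule, phys, art)
        assert np.all(s.ppg <= art.input_intensity + 1e-12)
        assert np.all(s.ppg > 0)

    def test_clean_rest_spectrum_peaks_at_hr(self):
        sch = sim.make_schedule([("A_rest", 3.0)])
        phys = sim.UserPhysiology(resting_hr=66.0, random_seed=1)
        art = sim.ArtifactModel(mmec_gain=0.0, mvascular_gain=0.0,
                                perfusion_noise_sd=0.0, distractor_rel_amp=0.0)
        s = sim.simulate_session(sch, phys, art)
        x = s.ppg - s.ppg.mean()
        freqs = np.fft.rfftfreq(len(x), 1 / 20.0)
        spec = np.abs(np.fft.rfft(x))
        band = (freqs >= 0.6) & (freqs <= 3.0)
        peak = freqs[band][np.argmax(spec[band])]
        assert peak == pytest.approx(66.0 / 60.0, abs=0.05)

    def test_finger_artifacts_invisible_to_wrist_accel(self):
        # accel-norm variance in a finger-movement segment matches rest
        sch = sim.make_schedule([("A_rest", 3.0), ("B_read", 3.0)])
        phys = sim.UserPhysiology(random_seed=2)
        s = sim.simulate_session(sch, phys, sim.ArtifactModel(mvascular_gain=0.8))
        norm = np.linalg.norm(s.accel, axis=1)
        n_rest = int(3 * 60 * 10)
        v_rest = np.var(norm[:n_rest])
        v_finger = np.var(norm[n_rest:])
        assert 0.8 < v_finger / v_rest < 1.25

    def test_artifact_power_decomposition(self, short_schedule):
        phys = sim.UserPhysiology(random_seed=11)
        kw = dict(distractor_rel_amp=0.0, perfusion_noise_sd=0.0, ppg_noise_sd=0.0)
        full = sim.simulate_session(short_schedule, phys, sim.ArtifactModel(**kw))
        clean = sim.simulate_session(
            short_schedule, phys, sim.ArtifactModel(mmec_gain=0, mvascular_gain=0, **kw))
        mmec = sim.simulate_session(
            short_schedule, phys, sim.ArtifactModel(mvascular_gain=0, **kw))
        mvas = sim.simulate_session(
            short_schedule, phys, sim.ArtifactModel(mmec_gain=0, **kw))
        total = full.ppg - clean.ppg
        parts = (mmec.ppg - clean.ppg) + (mvas.ppg - clean.ppg)
        p = lambda x: np.mean(x**2)
        assert p(total) == pytest.approx(p(parts), rel=0.1)
        # disabling both gains leaves a clean quasi-periodic pulse train
        x = clean.ppg - clean.ppg.mean()
        freqs = np.fft.rfftfreq(len(x), 1 / 20.0)
        spec = np.abs(np.fft.rfft(x))
        band = (freqs >= 0.6) & (freqs <= 3.0)
        assert spec[band].max() > 5 * np.median(spec[band])

    def test_temperature_carries_lagged_hr(self):
        sch = sim.make_schedule()
        phys = sim.sample_physiology(np.random.default_rng(4))
        s = sim.simulate_session(sch, phys)
        t01 = np.arange(len(s.temperature)) * 10.0
        t20 = np.arange(len(s.true_hr_track)) / 20.0
        corrs = {}
        for lag in np.arange(0.0, 130.0, 10.0):
            hl = np.interp(t01 - lag, t20, s.true_hr_track)
            corrs[lag] = np.corrcoef(s.temperature, hl)[0, 1]
        best_lag = max(corrs, key=corrs.get)
        assert corrs[best_lag] > 0.8
        assert abs(best_lag - phys.temp_lag) <= 20.0

    def test_group_separability_on_accel_variance(self, cfg):
        from wristhr.preprocess import process_session, window_session

        sch = sim.make_schedule()
        phys = sim.sample_physiology(np.random.default_rng(3))
        s = sim.simulate_session(sch, phys)
        proc = process_session(s, cfg, hr_source="truth")
        wins = window_session(proc, cfg)
        lv = np.log10([np.var(w.accel_norm) + 1e-12 for w in wins])
        lab = np.array([w.label_task for w in wins])
        cent = {g: lv[lab == g].mean() for g in (1, 2, 3)}
        pred = np.array([min(cent, key=lambda g: abs(x - cent[g])) for x in lv])
        assert np.mean((pred == 3) == (lab == 3)) >= 0.95
        mask = lab != 3
        assert np.mean(pred[mask] == lab[mask]) <= 0.75
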