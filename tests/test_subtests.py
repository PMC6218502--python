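import math

import numpy as np
import pytest

from fallkit.core_io import AppLog, CRTTrial, Location, Subtest, ValidationError
from fallkit.features import extract_all
from fallkit.features.catalogue import CATALOGUE_SIZE, measure_catalogue, screened_reference
from fallkit.features.events import detect_gait_events, detect_turn
from fallkit.features.subtests import (
    CycleCountError,
    crt_measures,
    fes_score,
    gait_measures,
    knee_rom,
    los_measures,
    sts5_measures,
)
from fallkit.synthetic_data import (
    GaitProfile,
    simulate_los,
    simulate_mf,
    simulate_sts5,
    simulate_tug,
)

RATE = 100.0


class TestGaitMeasures:
    def _events_and_lowback(self, profile, seed=0):
        session, gt = simulate_tug(profile, seed=seed)
        left = session.recording(Location.LEFT_LOWER_LEG).gyro[:, 1]
        right = session.recording(Location.RIGHT_LOWER_LEG).gyro[:, 1]
        events = detect_gait_events(left, right, RATE)
        ts, te = detect_turn(events, rate=RATE)
        return events.with_turn(ts, te), session.recording(Location.LOW_BACK), gt

    def test_arithmetic_10_steps(self, clean_tug):
        session, gt = clean_tug
        left = session.recording(Location.LEFT_LOWER_LEG).gyro[:, 1]
        right = session.recording(Location.RIGHT_LOWER_LEG).gyro[:, 1]
        events = detect_gait_events(left, right, RATE)
        events = events.with_turn(*detect_turn(events, rate=RATE))
        out = gait_measures(events, session.recording(Location.LOW_BACK), 3.0)
        assert out["n_steps"] == 10
        assert out["step_length"] == pytest.approx(2 * 3.0 / 10)  # 0.6 m
        assert out["gait_velocity"] == pytest.approx(6.0 / out["walk_time"])
        assert out["step_time"] == pytest.approx(1.0, abs=0.02)

    def test_turn_max_equals_pulse_amplitude(self):
        profile = GaitProfile(n_steps=12, stride_time=1.0, noise_sd=0.0,
                              turn_duration=2.5, turn_yaw_rate=113.78)
        events, low_back, gt = self._events_and_lowback(profile)
        out = gait_measures(events, low_back, 3.0)
        assert out["turn_gyro_max"] == pytest.approx(113.78, rel=0.01)
        assert out["turn_gyro_rms"] < out["turn_gyro_max"]

    def test_zero_walkway_rejected(self, clean_tug):
        session, _ = clean_tug
        left = session.recording(Location.LEFT_LOWER_LEG).gyro[:, 1]
        right = session.recording(Location.RIGHT_LOWER_LEG).gyro[:, 1]
        events = detect_gait_events(left, right, RATE)
        events = events.with_turn(*detect_turn(events, rate=RATE))
        with pytest.raises(ValidationError):
            gait_measures(events, session.recording(Location.LOW_BACK), 0.0)


class TestSts5Measures:
    def test_noiseless_durations(self):
        session, _ = simulate_sts5([2.0] * 5, seed=0)
        transitions, measures = sts5_measures(session.recording(Location.RIGHT_UPPER_LEG))
        np.testing.assert_allclose(transitions.sit_stand_sit_durations, 2.0, atol=1.0 / RATE)
        assert measures["sit_stand_sit_duration"] == pytest.approx(2.0, abs=1.0 / RATE)

    def test_mixed_durations(self):
        scheduled = [2.0, 2.3, 1.8, 2.5, 2.1]
        session, _ = simulate_sts5(scheduled, seed=1)
        transitions, _ = sts5_measures(session.recording(Location.RIGHT_UPPER_LEG))
        np.testing.assert_allclose(transitions.sit_stand_sit_durations, scheduled,
                                   atol=1.0 / RATE)

    def test_four_cycles_error(self):
        session, _ = simulate_sts5([2.0] * 4, seed=0)
        with pytest.raises(CycleCountError):
            sts5_measures(session.recording(Location.RIGHT_UPPER_LEG))

    def test_group_means_recoverable(self):
        rng = np.random.default_rng(0)
        for mean in (2.05, 2.44):
            recovered = []
            for seed in range(5):
                durations = np.maximum(mean + rng.standard_normal(5) * 0.05, 1.0)
                session, _ = simulate_sts5(durations, seed=seed, noise_sd=1.0)
                _, m = sts5_measures(session.recording(Location.RIGHT_UPPER_LEG))
                recovered.append(m["sit_stand_sit_duration"] - np.mean(durations))
            assert abs(np.mean(recovered)) < 0.02


class TestLosMeasures:
    def test_metadata_passthrough(self):
        session, _ = simulate_los(peak_pitch_deg=12.0, seed=0)
        out = los_measures(session.recording(Location.LOW_BACK), reach_distance_m=0.25)
        assert out["reach_distance"] == 0.25
        assert out["reach_method"] == "measured"

    def test_estimated_from_pitch_and_height(self):
        session, _ = simulate_los(peak_pitch_deg=15.0, seed=0)
        out = los_measures(session.recording(Location.LOW_BACK), height_cm=155.0)
        assert out["reach_method"] == "estimated"
        assert out["reach_distance"] == pytest.approx(1.55 * math.sin(math.radians(15)),
                                                      rel=0.01)

    def test_motion_free_trial_zero_jerk(self):
        session, _ = simulate_los(peak_pitch_deg=0.0, seed=0, noise_sd=0.0)
        out = los_measures(session.recording(Location.LOW_BACK), reach_distance_m=0.2)
        assert out["jerk_gyro_ml"] == pytest.approx(0.0, abs=1e-6)
        assert out["jerk_gyro_ap"] == pytest.approx(0.0, abs=1e-6)


class TestKneeRom:
    def test_synthetic_sweep(self):
        session, _ = simulate_mf("flexion", 130.0, seed=0)
        rom = knee_rom(session.recording(Location.LEFT_UPPER_LEG),
                       session.recording(Location.LEFT_LOWER_LEG))
        assert rom == pytest.approx(130.0, abs=0.5)

    def test_gyro_integration_route(self):
        session, _ = simulate_mf("flexion", 130.0, seed=0, with_orientation=False)
        rom = knee_rom(session.recording(Location.LEFT_UPPER_LEG),
                       session.recording(Location.LEFT_LOWER_LEG))
        assert rom == pytest.approx(130.0, abs=1.0)

    def test_static_trial(self):
        session, _ = simulate_mf("extension", 0.0, seed=0)
        rom = knee_rom(session.recording(Location.LEFT_UPPER_LEG),
                       session.recording(Location.LEFT_LOWER_LEG))
        assert rom == pytest.approx(0.0, abs=1e-6)


class TestAppMeasures:
    def test_ips_arithmetic(self):
        log = AppLog("CRT", crt_trials=[CRTTrial(1, 0.25, True)] * 3
                     + [CRTTrial(4, 0.30, True)] * 3)
        ips, srt = crt_measures(log)
        assert ips == pytest.approx(2.0 / 0.30, rel=1e-9)  # ~6.67 bit/s
        assert srt == pytest.approx(0.25)

    def test_two_alternative_one_second(self):
        log = AppLog("CRT", crt_trials=[CRTTrial(1, 0.3, True), CRTTrial(2, 1.0, True)])
        ips, _ = crt_measures(log)
        assert ips == pytest.approx(1.0)

    def test_all_incorrect_errors(self):
        log = AppLog("CRT", crt_trials=[CRTTrial(1, 0.3, False), CRTTrial(4, 0.4, False)])
        with pytest.raises(ValidationError):
            crt_measures(log)

    def test_fes_bounds(self):
        assert fes_score(AppLog("FES", fes_items=[1] * 7)) == 7
        assert fes_score(AppLog("FES", fes_items=[4] * 7)) == 28
        assert fes_score(AppLog("FES", fes_items=[1, 1, 2, 1, 1, 2, 2])) == 10

    def test_fes_missing_items(self):
        with pytest.raises(ValidationError, match="missing"):
            fes_score(AppLog("FES", fes_items=[1, 2, 3]))


class TestExtractAll:
    def test_complete_battery_populates_catalogue(self, battery):
        sessions, logs, _ = battery
        vec = extract_all(sessions, logs)
        assert vec.n_populated == CATALOGUE_SIZE
        assert not vec.missing

    def test_missing_mf_flagged(self, battery):
        sessions, logs, _ = battery
        partial = {k: v for k, v in sessions.items()
                   if k not in (Subtest.MF_FLEXION, Subtest.MF_EXTENSION)}
        vec = extract_all(partial, logs)
        mf_ids = set(measure_catalogue().query("subtest.str.startswith('MF')")["measure_id"])
        assert mf_ids <= vec.missing
        assert vec.n_populated == CATALOGUE_SIZE - len(mf_ids)

    def test_deterministic(self, battery):
        sessions, logs, _ = battery
        v1 = extract_all(sessions, logs)
        v2 = extract_all(sessions, logs)
        assert v1.values == v2.values

    def test_extraction_matches_ground_truth(self, battery):
        sessions, logs, truths = battery
        vec = extract_all(sessions, logs)
        gt = truths["SIT_EO_FIRM"].measures
        assert vec.values["sit_eo_firm_rms_acc_ap"] == pytest.approx(gt["rms_acc_ap"], abs=1e-9)
        assert vec.values["sit_eo_firm_rms_gyro_ap"] == pytest.approx(gt["rms_gyro_ap"], abs=1e-9)
        sts = truths["STS5"].measures
        assert vec.values["sts5_sit_stand_sit_duration"] == pytest.approx(
            sts["sit_stand_sit_duration"], abs=0.02)
        tug = truths["TUG"].measures
        assert vec.values["tug_turn_time"] == pytest.approx(tug["turn_time"], abs=0.03)
        assert vec.values["tug_n_steps"] == tug["n_steps"]


def test_catalogue_shape():
    cat = measure_catalogue()
    assert len(cat) == CATALOGUE_SIZE
    assert cat["measure_id"].is_unique
    assert set(screened_reference()) <= set(cat["measure_id"])
    assert len(screened_reference()) == 38
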