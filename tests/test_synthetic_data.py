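import numpy as np
import pytest
from scipy.signal import periodogram
from scipy.stats import norm

from fallkit.core_io import Location, Subtest, ValidationError
from fallkit.preprocess import FilterSpec, butterworth_lowpass
from fallkit.features.measures import rms
from fallkit.synthetic_data import (
    CohortSpec,
    GaitProfile,
    SwayProfile,
    simulate_battery,
    simulate_cohort_features,
    simulate_los,
    simulate_mf,
    simulate_sts5,
    simulate_sway,
    simulate_tug,
    table3_cohort_spec,
)

RATE = 100.0


class TestSimulateTug:
    def test_noiseless_event_schedule(self):
        profile = GaitProfile(n_steps=10, stride_time=1.0, noise_sd=0.0, turn_duration=2.0)
        session, gt = simulate_tug(profile, seed=0)
        for leg in ("left", "right"):
            diffs = np.diff(gt.gait_events[leg]["mid_swing"])
            # same-leg spacing is one stride everywhere except across the turn
            np.testing.assert_allclose(diffs[diffs < 1.5], 1.0)
        merged = np.sort(np.concatenate([gt.gait_events["left"]["mid_swing"],
                                         gt.gait_events["right"]["mid_swing"]]))
        steps = np.diff(merged)
        assert np.allclose(steps[steps < 1.0], 0.5)  # half-stride alternation
        # signal peak lands on the scheduled time within one sample
        rec = session.recording(Location.LEFT_LOWER_LEG)
        y = rec.gyro[:, 1]
        for t_ms in gt.gait_events["left"]["mid_swing"]:
            i = int(round(t_ms * RATE))
            window = y[i - 3: i + 4]
            assert abs((i - 3 + int(np.argmax(window))) / RATE - t_ms) <= 1.0 / RATE

    def test_deterministic(self):
        profile = GaitProfile(noise_sd=10.0, stride_time_sd=0.05)
        s1, g1 = simulate_tug(profile, seed=9)
        s2, g2 = simulate_tug(profile, seed=9)
        for loc in s1.recordings:
            np.testing.assert_array_equal(s1.recordings[loc].gyro, s2.recordings[loc].gyro)
            np.testing.assert_array_equal(s1.recordings[loc].acc, s2.recordings[loc].acc)
        np.testing.assert_array_equal(g1.gait_events["left"]["mid_swing"],
                                      g2.gait_events["left"]["mid_swing"])

    @pytest.mark.parametrize("stride", [1.04, 1.08])
    def test_step_time_mean_matches_profile(self, stride):
        profile = GaitProfile(n_steps=60, stride_time=stride, stride_time_sd=0.05,
                              noise_sd=0.0, turn_duration=2.2)
        means = []
        for seed in range(8):
            _, gt = simulate_tug(profile, seed=seed)
            means.append(gt.measures["step_time"])
        assert np.mean(means) == pytest.approx(stride, rel=0.01)

    def test_turn_longer_than_trial_rejected(self):
        profile = GaitProfile(n_steps=4, stride_time=1.0, turn_duration=60.0)
        with pytest.raises(ValidationError):
            simulate_tug(profile, seed=0)

    def test_invalid_profile(self):
        with pytest.raises(ValidationError):
            GaitProfile(swing_peak_amp=50.0, toe_off_trough_amp=120.0).validate()


class TestSimulateSway:
    def test_rms_exact_through_extraction_path(self):
        profile = SwayProfile(rms_acc_ap=0.02, rms_acc_ml=0.007, duration=30.0)
        session, _ = simulate_sway(profile, Subtest.SIT_EO_FOAM, seed=1)
        rec = session.recording(Location.LOW_BACK)
        filt = butterworth_lowpass(rec.acc, FilterSpec(), RATE)
        assert rms(filt[:, 0]) == pytest.approx(0.02, abs=1e-9)
        assert rms(filt[:, 1]) == pytest.approx(0.007, abs=1e-9)

    def test_zero_request_gives_flat_channel(self):
        profile = SwayProfile(rms_acc_ap=0.0, rms_acc_ml=0.0, rms_gyro_ap=0.0,
                              rms_gyro_ml=0.0, duration=12.0)
        session, _ = simulate_sway(profile, seed=2)
        rec = session.recording(Location.LOW_BACK)
        assert rms(rec.acc[:, 0]) == 0.0
        assert rms(rec.gyro[:, 0]) == 0.0

    def test_band_limited(self):
        profile = SwayProfile(bandwidth=2.0, duration=30.0)
        session, _ = simulate_sway(profile, seed=3)
        x = session.recording(Location.LOW_BACK).acc[:, 0]
        freqs, psd = periodogram(x, fs=RATE)
        assert psd[freqs <= 4.0].sum() / psd.sum() > 0.99

    def test_duration_too_short(self):
        with pytest.raises(ValidationError):
            simulate_sway(SwayProfile(duration=5.0), seed=0)

    def test_deterministic(self):
        s1, _ = simulate_sway(SwayProfile(), seed=4)
        s2, _ = simulate_sway(SwayProfile(), seed=4)
        np.testing.assert_array_equal(s1.recordings[Location.LOW_BACK].acc,
                                      s2.recordings[Location.LOW_BACK].acc)


class TestSimulateSts5:
    def test_schedule_recorded(self):
        session, gt = simulate_sts5([2.0] * 5, seed=0)
        assert len(gt.sts_cycles) == 5
        for cyc in gt.sts_cycles:
            assert cyc["stand_sit"][1] - cyc["sit_stand"][0] == pytest.approx(2.0)

    def test_overlap_rejected(self):
        with pytest.raises(ValidationError):
            simulate_sts5([-1.0] * 5, seed=0)

    def test_deterministic(self):
        s1, _ = simulate_sts5([2.0, 2.1, 1.9, 2.2, 2.0], seed=5, noise_sd=2.0)
        s2, _ = simulate_sts5([2.0, 2.1, 1.9, 2.2, 2.0], seed=5, noise_sd=2.0)
        np.testing.assert_array_equal(s1.recordings[Location.RIGHT_UPPER_LEG].gyro,
                                      s2.recordings[Location.RIGHT_UPPER_LEG].gyro)


class TestSimulateLosMf:
    def test_los_orientation_consistent(self):
        session, gt = simulate_los(peak_pitch_deg=15.0, seed=0)
        rec = session.recording(Location.LOW_BACK)
        assert rec.orientation[:, 1].max() == pytest.approx(15.0, abs=1e-6)

    def test_mf_requires_valid_task(self):
        with pytest.raises(ValidationError):
            simulate_mf("sideways", 90.0)


class TestBattery:
    def test_complete_battery_shape(self, battery):
        sessions, logs, truths = battery
        assert len(sessions) == 9  # 4 SIT conditions + LOS + STS5 + TUG + 2 MF
        assert set(logs) == {"CRT", "FES"}


class TestCohort:
    def test_group_means_within_3se(self, cohort_df):
        spec = table3_cohort_spec()
        for measure, ((m_nf, sd_nf), (m_f, sd_f)) in spec.measures.items():
            nf = cohort_df.loc[cohort_df.fall_status == "non_faller", measure]
            f = cohort_df.loc[cohort_df.fall_status == "faller", measure]
            assert abs(nf.mean() - m_nf) <= 3 * sd_nf / np.sqrt(114), measure
            assert abs(f.mean() - m_f) <= 3 * sd_f / np.sqrt(82), measure

    def test_effect_direction_fidelity(self, cohort_df):
        spec = table3_cohort_spec()
        for measure, ((m_nf, _), (m_f, _)) in spec.measures.items():
            nf = cohort_df.loc[cohort_df.fall_status == "non_faller", measure].mean()
            f = cohort_df.loc[cohort_df.fall_status == "faller", measure].mean()
            assert np.sign(f - nf) == np.sign(m_f - m_nf), measure

    def test_binormal_auc_fes(self, cohort_df):
        from fallkit.stats_screen import roc_auc

        # closed-form binormal AUC for the FES parameters
        expected = norm.cdf((14.96 - 9.73) / np.sqrt(2.98**2 + 4.92**2))
        assert expected == pytest.approx(0.818, abs=0.002)
        auc, _, _ = roc_auc(cohort_df["fes_score"],
                            cohort_df["fall_status"] == "faller")
        assert auc == pytest.approx(expected, abs=0.05)

    def test_unknown_measure_rejected(self):
        spec = CohortSpec(10, 10, {"not_a_measure": ((0, 1), (1, 1))})
        with pytest.raises(ValidationError, match="absent from catalogue"):
            simulate_cohort_features(spec)

    def test_identical_groups_auc_half(self):
        spec = CohortSpec(200, 200, {"fes_score": ((10.0, 3.0), (10.0, 3.0))}, seed=3)
        df = simulate_cohort_features(spec)
        from fallkit.stats_screen import roc_auc

        auc, se, _ = roc_auc(df["fes_score"], df["fall_status"] == "faller")
        assert auc == pytest.approx(0.5, abs=3 * se)

    def test_deterministic_and_subject_stable(self):
        spec = table3_cohort_spec(seed=21)
        df1 = simulate_cohort_features(spec)
        df2 = simulate_cohort_features(spec)
        assert df1.equals(df2)
        # enlarging the cohort leaves earlier subjects unchanged (counter scheme)
        bigger = table3_cohort_spec(n_nonfaller=120, n_faller=90, seed=21)
        df3 = simulate_cohort_features(bigger)
        nf1 = df1[df1.fall_status == "non_faller"].reset_index(drop=True)
        nf3 = df3[df3.fall_status == "non_faller"].iloc[: len(nf1)].reset_index(drop=True)
        assert nf1.equals(nf3)

    def test_correlation_psd_required(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        spec = CohortSpec(10, 10, {"fes_score": ((10, 3), (15, 5)),
                                   "crt_ips": ((7, 1), (6, 1))}, correlation=bad)
        with pytest.raises(ValidationError, match="positive semi-definite"):
            simulate_cohort_features(spec)

    def test_correlated_draws(self):
        r = np.array([[1.0, 0.8], [0.8, 1.0]])
        spec = CohortSpec(400, 400, {"fes_score": ((10, 3), (15, 5)),
                                     "crt_ips": ((7, 1), (6, 1))},
                          correlation=r, seed=2)
        df = simulate_cohort_features(spec)
        nf = df[df.fall_status == "non_faller"]
        assert np.corrcoef(nf["fes_score"], nf["crt_ips"])[0, 1] == pytest.approx(0.8, abs=0.08)
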