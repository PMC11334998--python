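import numpy as np
import pandas as pd
import pytest

from hrenergetics import hrsignal, synth
from hrenergetics.respirometry import recover_metabolic_rates


class TestHRProfile:
    def test_unknown_season_rejected(self):
        with pytest.raises(ValueError, match="season"):
            synth.gen_hr_profile("winter", 24, seed=0)

    def test_truth_track_partitions_period(self, spring_profile):
        series, track = spring_profile
        iv = track.intervals
        assert (iv["end"].to_numpy()[:-1] == iv["start"].to_numpy()[1:]).all()
        assert (iv["state"].to_numpy()[1:] != iv["state"].to_numpy()[:-1]).all()
        assert iv["start"].iloc[0] == series.timestamps[0]

    def test_spring_torpid_samples_match_generating_distribution(self, spring_profile):
        series, track = spring_profile
        state = track.state_at(series.timestamps)
        torpid_hr = series.hr[state == "torpid"]
        assert torpid_hr.size > 300
        # sample mean within the 26 +/- 9 band (clipping shifts it slightly up)
        assert 17.0 < torpid_hr.mean() < 35.0

    def test_summer_never_torpid_and_fluctuates_200_400(self, summer_profile):
        series, track = summer_profile
        assert "torpid" not in set(track.intervals["state"])
        state = track.state_at(series.timestamps)
        day_rest = series.hr[state == "resting"]
        assert 200 < np.median(day_rest) < 400

    def test_flight_heart_rates_within_band(self, spring_profile, summer_profile):
        for series, track in (spring_profile, summer_profile):
            state = track.state_at(series.timestamps)
            fl = series.hr[state == "flight"]
            assert fl.size > 0
            assert fl.min() >= 600 and fl.max() <= 900

    def test_forced_no_flight_removes_flight_state(self):
        _, track = synth.gen_hr_profile("summer", 24, seed=2, force_no_flight=True)
        assert "flight" not in set(track.intervals["state"])

    def test_state_means_recover_generating_parameters(self):
        """Monte-Carlo: truth-track state means match the generator's
        own distribution parameters within 2 standard errors."""
        params = synth.SEASON_DEFAULTS["spring"]
        hrs = []
        for seed in (3, 4, 5):
            series, track = synth.gen_hr_profile("spring", 48, seed=seed)
            state = track.state_at(series.timestamps)
            hrs.append(series.hr[state == "torpid"])
        hr = np.concatenate(hrs)
        mean, sd = params.torpid_hr
        se = sd / np.sqrt(hr.size)
        # clipping at the 10 b.p.m. floor biases the realized mean up by ~1
        assert abs(hr.mean() - mean) < 2 * se + 1.5

    def test_reproducible(self):
        a, _ = synth.gen_hr_profile("spring", 24, seed=9)
        b, _ = synth.gen_hr_profile("spring", 24, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestCarrierAudio:
    def test_noise_free_constant_schedule_interruption_count(self):
        sched = synth.BeatSchedule.constant(600, 10.0)
        audio = synth.gen_carrier_audio(sched)
        env = hrsignal.envelope(audio)
        # count envelope dips directly: 10 per second
        below = env < 0.5
        n_runs = int(np.sum(np.diff(below.astype(int)) == 1) + below[0])
        assert n_runs == 100

    def test_empty_schedule_is_pure_tone(self):
        sched = synth.BeatSchedule(np.empty(0), np.empty(0), 5.0)
        audio = synth.gen_carrier_audio(sched)
        env = hrsignal.envelope(audio)
        assert env[10:-10].min() > 0.5

    def test_nyquist_violation_rejected(self):
        sched = synth.BeatSchedule.constant(120, 5.0)
        with pytest.raises(ValueError, match="Nyquist"):
            synth.gen_carrier_audio(sched, sample_rate=8000, carrier_freq=5000)

    def test_interruption_longer_than_ibi_rejected(self):
        sched = synth.BeatSchedule.constant(1000, 5.0)  # 60 ms IBI
        with pytest.raises(ValueError, match="inter-beat"):
            synth.gen_carrier_audio(sched, interruption_ms=70)

    def test_dropout_removes_beats(self):
        sched = synth.BeatSchedule.constant(300, 30.0)
        audio = synth.gen_carrier_audio(sched, dropout_fraction=0.5, seed=3)
        ev = hrsignal.detect_beats(hrsignal.envelope(audio), audio.sample_rate)
        assert len(ev) < len(sched.beat_times)


class TestRespirometrySim:
    def test_zero_vo2_settles_at_incurrent(self):
        cfg = synth.ChamberConfig(n_chambers=1, baseline_channel=False, dwell_s=3600)
        trace, _ = synth.gen_respirometry({"ch1": 0.0}, cfg, duration_min=30)
        tail = trace.data["fo2"].tail(300)
        assert np.allclose(tail, 0.2095, atol=1e-6)

    def test_step_response_95pct_after_three_time_constants(self):
        cfg = synth.ChamberConfig(n_chambers=1, baseline_channel=False, dwell_s=7200)
        step_at = 30.0
        trace, _ = synth.gen_respirometry(
            {"ch1": lambda tm: 0.0 if tm < step_at else 30.0}, cfg, duration_min=90
        )
        f = trace.data["fo2"].to_numpy()
        f_pre = f[int(step_at * 60) - 5]
        f_final = f[-1]
        t95 = int((step_at + 16.0) * 60)  # 3 * (800/150) min = 16 min
        progress = (f[t95] - f_pre) / (f_final - f_pre)
        assert progress >= 0.95
        assert progress < 0.99  # still visibly converging

    def test_steady_state_depletion_equals_vo2_over_flow(self):
        cfg = synth.ChamberConfig(n_chambers=1, baseline_channel=False, dwell_s=7200)
        trace, _ = synth.gen_respirometry({"ch1": 30.0}, cfg, duration_min=60, rer=0.85)
        depletion = 0.2095 - trace.data["fo2"].iloc[-1]
        # first-order approximation: VO2/flow
        assert depletion == pytest.approx(30.0 / 60.0 / 150.0, rel=0.05)
        # exact pull-mode steady state carries the (1 - RER) flow correction
        exact = (30.0 / 60.0) * (1.0 - (1.0 - 0.85) * 0.2095) / 150.0
        assert depletion == pytest.approx(exact, rel=1e-3)

    def test_invalid_rer_rejected(self):
        with pytest.raises(ValueError, match="RER"):
            synth.gen_respirometry({"ch1": 10.0}, rer=1.2, duration_min=10)


class TestCalibrationPairs:
    def test_noise_free_pairs_lie_on_power_law(self):
        pairs = synth.gen_calibration_pairs(-5.0, 1.2, 0.0, n=20, seed=1)
        lhs = np.log(pairs["vo2_ml_g_h"])
        rhs = -5.0 + 1.2 * np.log(pairs["hr_bpm"])
        assert np.allclose(lhs, rhs)

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(n=2), "3 pairs"),
            (dict(hr_range=(200.0, 200.0)), "hr_range"),
            (dict(hr_range=(5.0, 500.0)), "hr_range"),
        ],
    )
    def test_invalid_requests_rejected(self, kwargs, msg):
        base = dict(intercept=-5.0, slope=1.0, noise_sd=0.1, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError, match=msg):
            synth.gen_calibration_pairs(
                base["intercept"], base["slope"], base["noise_sd"],
                hr_range=base.get("hr_range", (40.0, 800.0)),
                n=base.get("n", 50), seed=base["seed"],
            )

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            synth.gen_calibration_pairs(-5.0, 0.0, 0.1)


class TestTemperature:
    def test_spring_long_run_mean(self):
        temp = synth.gen_temperature("spring", 30, seed=1)
        assert temp["temp_c"].mean() == pytest.approx(13.5, abs=1.0)

    def test_zero_amplitude_constant_at_seasonal_mean(self):
        p = synth.SEASON_DEFAULTS["summer"]
        import dataclasses

        p0 = dataclasses.replace(p, temp_noise_sd_c=0.0)
        temp = synth.gen_temperature("summer", 3, seed=0, params=p0, amplitude=0.0)
        assert np.allclose(temp["temp_c"], p.temp_mean_c)

    def test_summer_clipped_to_configured_range(self):
        temp = synth.gen_temperature("summer", 30, seed=2)
        assert temp["temp_c"].between(10.0, 32.0).all()


class TestApplyGaps:
    def test_gap_fraction_achieved(self, spring_profile):
        series, _ = spring_profile
        gapped = synth.apply_gaps(series, 0.2, seed=5)
        assert gapped.gap_fraction() == pytest.approx(0.2, abs=0.01)
        assert np.isnan(gapped.hr[gapped.is_gap]).all()

    def test_zero_fraction_is_identity(self, spring_profile):
        series, _ = spring_profile
        gapped = synth.apply_gaps(series, 0.0, seed=5)
        pd.testing.assert_frame_equal(gapped.data, series.data)
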