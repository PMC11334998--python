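import numpy as np
import pandas as pd
import pytest

from hrenergetics import synth
from hrenergetics.respirometry import (
    GasTrace,
    compute_vo2_vco2,
    drift_correct,
    dry_correct,
    lag_align,
    mass_specific_and_energy,
    recover_metabolic_rates,
    split_and_discard,
)


def _trace(duration_min=40.0, dwell_s=120.0, vo2=30.0, **kwargs):
    cfg = synth.ChamberConfig(dwell_s=dwell_s, **{k: v for k, v in kwargs.items() if k in ("n_chambers", "baseline_channel")})
    sim_kw = {k: v for k, v in kwargs.items() if k not in ("n_chambers", "baseline_channel")}
    return synth.gen_respirometry({"ch1": vo2}, cfg, duration_min=duration_min, **sim_kw)


class TestSplitAndDiscard:
    def test_30s_discard_leaves_90s_of_120s_dwell(self):
        trace, _ = _trace()
        segs = split_and_discard(trace, discard_s=30.0)
        for seg in segs:
            span = seg.data["time_s"].iloc[-1] - seg.data["time_s"].iloc[0]
            assert span == pytest.approx(89.0, abs=1.0)
            assert seg.data["time_s"].iloc[0] == pytest.approx(seg.switch_time_s + 30.0, abs=1.0)

    def test_zero_discard_partitions_raw_runs(self):
        trace, _ = _trace(duration_min=20)
        segs = split_and_discard(trace, discard_s=0.0)
        total = sum(len(s.data) for s in segs)
        assert total == len(trace.data)

    def test_single_channel_trace_one_segment(self):
        trace, _ = _trace(duration_min=10, dwell_s=3600, n_chambers=1, baseline_channel=False)
        segs = split_and_discard(trace, discard_s=30.0)
        assert len(segs) == 1
        assert segs[0].data["time_s"].iloc[0] == pytest.approx(30.0, abs=1.0)

    def test_dwell_not_exceeding_discard_rejected(self):
        trace, _ = _trace(duration_min=10, dwell_s=40.0)
        with pytest.raises(ValueError, match="dwell"):
            split_and_discard(trace, discard_s=60.0)


class TestDriftCorrect:
    def test_zero_drift_identity(self):
        trace, _ = _trace()
        segs = split_and_discard(trace)
        corrected = drift_correct(segs)
        for a, b in zip(segs, corrected):
            assert np.allclose(a.data["fo2"], b.data["fo2"], atol=1e-9)

    def test_linear_drift_recovered(self):
        slope_per_s = 0.001 / 3600.0
        trace, _ = _trace(duration_min=60, drift_o2=lambda ts: slope_per_s * ts)
        segs = split_and_discard(trace)
        corrected = drift_correct(segs)
        base = [s for s in corrected if s.channel == "baseline"]
        resid = np.concatenate([s.data["fo2"].to_numpy() - 0.2095 for s in base])
        # corrected baseline residuals are < 5% of the total injected drift
        assert np.abs(resid).max() < 0.05 * slope_per_s * 3600

    def test_drift_on_co2_only_leaves_o2_unchanged(self):
        trace, _ = _trace(duration_min=40, drift_co2=lambda ts: 1e-7 * ts)
        segs = split_and_discard(trace)
        corrected = drift_correct(segs)
        for a, b in zip(segs, corrected):
            assert np.allclose(a.data["fo2"], b.data["fo2"], atol=1e-7)

    def test_single_baseline_visit_rejected(self):
        trace, _ = _trace(duration_min=9.9)  # only one baseline dwell
        segs = split_and_discard(trace)
        with pytest.raises(ValueError, match="baseline"):
            drift_correct(segs)


class TestLagAlign:
    def _step_trace(self, lag_s):
        cfg = synth.ChamberConfig(n_chambers=1, baseline_channel=False, dwell_s=7200)
        return synth.gen_respirometry(
            {"ch1": lambda tm: 10.0 if tm < 30 else 40.0},
            cfg, duration_min=60, lag_co2_s=lag_s,
        )

    def test_zero_lag_estimated_as_zero(self):
        trace, _ = self._step_trace(0.0)
        _, lag = lag_align(trace.data["fo2"], trace.data["fco2"])
        assert abs(lag) <= 1.0

    def test_injected_8s_lag_recovered(self):
        trace, _ = self._step_trace(8.0)
        _, lag = lag_align(trace.data["fo2"], trace.data["fco2"])
        assert lag == pytest.approx(8.0, abs=1.0)

    def test_lag_beyond_window_saturates_with_warning(self):
        trace, _ = self._step_trace(30.0)
        with pytest.warns(UserWarning, match="saturated"):
            _, lag = lag_align(trace.data["fo2"], trace.data["fco2"], max_lag_s=10.0)
        assert abs(lag) == 10.0

    def test_flat_series_returns_zero_with_warning(self):
        flat = pd.Series(np.full(2000, 0.2095))
        with pytest.warns(UserWarning, match="flat"):
            _, lag = lag_align(flat, flat)
        assert lag == 0.0

    def test_short_overlap_rejected(self):
        s = pd.Series(np.random.default_rng(0).normal(size=100))
        with pytest.raises(ValueError, match="overlap"):
            lag_align(s, s, max_lag_s=60.0)


class TestDryCorrect:
    def test_zero_wvp_identity(self):
        assert dry_correct(0.2, 101.3, 0.0) == pytest.approx(0.2)

    def test_stated_formula_value(self):
        assert dry_correct(0.2000, 101.3, 1.013) == pytest.approx(0.2020, abs=5e-5)

    def test_homogeneous_in_pressures(self):
        a = dry_correct(0.2, 101.3, 1.5)
        b = dry_correct(0.2, 202.6, 3.0)
        assert a == pytest.approx(b)

    def test_wvp_at_or_above_barometric_rejected(self):
        with pytest.raises(ValueError, match="vapour"):
            dry_correct(0.2, 100.0, 100.0)


class TestComputeVO2:
    def test_equal_fractions_give_zero_rates(self):
        vo2, vco2, _, flagged = compute_vo2_vco2(0.2095, 0.0004, 0.2095, 0.0004, 150.0)
        assert vo2 == pytest.approx(0.0, abs=1e-9)
        assert vco2 == pytest.approx(0.0, abs=1e-9)
        assert not flagged

    def test_steady_chamber_vo2_recovered(self):
        trace, _ = _trace(duration_min=60, vo2=30.0)
        rates = recover_metabolic_rates(trace)
        ch1 = rates.loc[rates["channel"] == "ch1", "vo2_ml_h"]
        assert ch1.mean() == pytest.approx(30.0, rel=0.01)

    def test_rer_matches_generating_schedule(self):
        trace, _ = _trace(duration_min=60, vo2=30.0, rer=0.8)
        rates = recover_metabolic_rates(trace)
        ch1 = rates.loc[rates["channel"] == "ch1", "rer"]
        assert ch1.mean() == pytest.approx(0.8, rel=0.01)

    def test_negative_vo2_flagged_not_clipped(self):
        vo2, _, _, flagged = compute_vo2_vco2(0.2000, 0.0004, 0.2095, 0.0004, 150.0)
        assert vo2 < 0 and flagged


class TestMassSpecificEnergy:
    def test_caloric_equivalent(self):
        df = pd.DataFrame({"time_s": [0.0], "vo2_ml_h": [100.0], "vco2_ml_h": [80.0], "rer": [0.8]})
        met = mass_specific_and_energy(df, 27.4, 27.4)
        assert met.data["ee_kj_h"].iloc[0] == pytest.approx(2.0083)

    def test_mass_specific_uses_mean_mass(self):
        df = pd.DataFrame({"time_s": [0.0], "vo2_ml_h": [27.4], "vco2_ml_h": [22.0], "rer": [0.8]})
        met = mass_specific_and_energy(df, 27.0, 27.8)
        assert met.body_mass_g == pytest.approx(27.4)
        assert met.data["vo2_ml_g_h"].iloc[0] == pytest.approx(1.0)

    def test_zero_vo2_zero_ee(self):
        df = pd.DataFrame({"time_s": [0.0], "vo2_ml_h": [0.0], "vco2_ml_h": [0.0], "rer": [np.nan]})
        met = mass_specific_and_energy(df, 27.0, 27.8)
        assert met.data["ee_kj_h"].iloc[0] == 0.0

    def test_nonpositive_mass_rejected(self):
        df = pd.DataFrame({"time_s": [0.0], "vo2_ml_h": [1.0], "vco2_ml_h": [1.0], "rer": [1.0]})
        with pytest.raises(ValueError, match="mass"):
            mass_specific_and_energy(df, 0.0, 27.0)


class TestEndToEnd:
    def test_piecewise_schedule_recovered_at_steady_state(self):
        """Full chain on clean simulator output recovers a piecewise-constant
        VO2 schedule within 1% once each level has settled (3 washout taus)."""
        cfg = synth.ChamberConfig()
        sched = lambda tm: 20.0 if tm < 60 else 45.0
        trace, _ = synth.gen_respirometry({"ch1": sched}, cfg, duration_min=120)
        rates = recover_metabolic_rates(trace)
        ch1 = rates.loc[rates["channel"] == "ch1"]
        settled_lo = ch1.loc[(ch1["time_s"] > 20 * 60) & (ch1["time_s"] < 60 * 60)]
        settled_hi = ch1.loc[ch1["time_s"] > 80 * 60]
        assert settled_lo["vo2_ml_h"].mean() == pytest.approx(20.0, rel=0.01)
        assert settled_hi["vo2_ml_h"].mean() == pytest.approx(45.0, rel=0.01)

    def test_recovery_independent_of_chamber_volume(self):
        results = []
        for volume in (400.0, 800.0, 1600.0):
            cfg = synth.ChamberConfig(volume_ml=volume)
            trace, _ = synth.gen_respirometry({"ch1": 30.0}, cfg, duration_min=60)
            rates = recover_metabolic_rates(trace)
            results.append(rates.loc[rates["channel"] == "ch1", "vo2_ml_h"].mean())
        assert np.allclose(results, 30.0, rtol=0.01)

    def test_dry_path_identity_on_water_free_data(self):
        trace, _ = _trace(duration_min=40, wvp_kpa=0.0)
        rates_raw = recover_metabolic_rates(trace)
        # dry_correct with wvp=0 is the identity, so results coincide
        assert (trace.data["wvp_kpa"] == 0.0).all()
        vo2 = rates_raw.loc[rates_raw["channel"] == "ch1", "vo2_ml_h"].mean()
        assert vo2 == pytest.approx(30.0, rel=0.01)
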