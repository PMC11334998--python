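"""Synthetic biologging data with known ground truth.

Every input the pipeline consumes can be generated here, labelled with the
truth that produced it, so the downstream stages (beat detection,
respirometry inversion, calibration, budget integration) are testable
end-to-end without any field data.

The generators emulate a temperate-zone insectivorous bat study system:

* spring heart-rate profiles with multi-hour daytime torpor bouts around
  26 b.p.m., brief midday arousals, and dusk foraging flights;
* summer profiles that avoid torpor entirely, fluctuating between 200 and
  400 b.p.m. during daytime roosting;
* flight bouts at 600-900 b.p.m. in both seasons;
* carrier-interruption audio (a continuous tone gated off for ~15 ms per
  heartbeat) at configurable SNR and dropout;
* open-flow respirometry chamber washout dynamics (800 ml chambers pulled
  at 150 ml/min through a multiplexed analyzer) with drift, analyzer lag
  and water-vapour dilution;
* per-individual log-log heart-rate/VO2 calibration pairs;
* sinusoidal diel ambient-temperature series per season.

All generators take a ``seed`` and are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hrsignal import AudioTrace, HeartRateSeries
from .respirometry import GasTrace
from .solar import solar_times

__all__ = [
    "BeatSchedule",
    "StateTruthTrack",
    "ChamberConfig",
    "SeasonParams",
    "SEASON_DEFAULTS",
    "STUDY_SITE",
    "gen_hr_profile",
    "gen_carrier_audio",
    "gen_respirometry",
    "gen_calibration_pairs",
    "gen_temperature",
    "apply_gaps",
]

#: roost coordinates used for solar anchoring (Lake Constance region)
STUDY_SITE = (47.6666, 9.1816)

#: incurrent dry-air composition used by the respirometry forward model
INCURRENT_O2 = 0.2095
INCURRENT_CO2 = 0.0004

STATES = ("torpid", "resting", "entry", "arousal", "flight")


@dataclass
class BeatSchedule:
    """Ground-truth heartbeat times for audio synthesis.

    ``beat_times`` are seconds from trace start, strictly increasing;
    ``true_hr`` records the instantaneous rate (b.p.m.) each interval was
    drawn from, aligned with ``beat_times``.
    """

    beat_times: np.ndarray
    true_hr: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.true_hr = np.asarray(self.true_hr, dtype=float)
        if self.beat_times.size > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("beat times must be strictly increasing")
        if self.beat_times.size and (
            self.beat_times[0] < 0 or self.beat_times[-1] > self.duration_s
        ):
            raise ValueError("beat times must lie within the trace duration")

    @classmethod
    def constant(cls, bpm: float, duration_s: float, t0: float = 0.0) -> "BeatSchedule":
        """Evenly spaced beats at a constant rate."""
        ibi = 60.0 / bpm
        times = np.arange(t0, duration_s, ibi)
        return cls(times, np.full(times.size, float(bpm)), duration_s)

    @classmethod
    def from_rate(cls, times_s: np.ndarray, bpm: np.ndarray, duration_s: float) -> "BeatSchedule":
        """Beats drawn from a piecewise rate function by integrating it.

        Beat k occurs when the integrated rate reaches k beats.
        """
        times_s = np.asarray(times_s, dtype=float)
        bpm = np.asarray(bpm, dtype=float)
        grid = np.linspace(0.0, duration_s, max(int(duration_s * 10), 2))
        rate_per_s = np.interp(grid, times_s, bpm) / 60.0
        cum = np.concatenate([[0.0], np.cumsum(np.diff(grid) * (rate_per_s[:-1] + rate_per_s[1:]) / 2)])
        n_beats = int(math.floor(cum[-1]))
        beat_idx = np.arange(1, n_beats + 1, dtype=float)
        beats = np.interp(beat_idx, cum, grid)
        hr = np.interp(beats, times_s, bpm)
        return cls(beats, hr, duration_s)


@dataclass
class StateTruthTrack:
    """Ground-truth physiological-state intervals for one simulated bat.

    ``intervals`` has columns ``state`` (torpid/resting/entry/arousal/
    flight), ``start``, ``end`` (UTC timestamps).  Intervals partition the
    simulated period and adjacent intervals never share a state.
    """

    intervals: pd.DataFrame
    season: str

    def __post_init__(self) -> None:
        iv = self.intervals.reset_index(drop=True)
        if len(iv):
            bad = ~iv["state"].isin(STATES)
            if bad.any():
                raise ValueError(f"unknown states: {sorted(iv.loc[bad, 'state'].unique())}")
            starts = iv["start"].to_numpy()
            ends = iv["end"].to_numpy()
            if not (ends > starts).all():
                raise ValueError("intervals must have positive length")
            if len(iv) > 1:
                if not (starts[1:] == ends[:-1]).all():
                    raise ValueError("intervals must partition the period")
                same = iv["state"].to_numpy()[1:] == iv["state"].to_numpy()[:-1]
                if same.any():
                    raise ValueError("adjacent intervals must not share a state")
        self.intervals = iv

    def state_at(self, timestamps: pd.DatetimeIndex) -> np.ndarray:
        """Vectorized state lookup for a set of timestamps."""
        iv = self.intervals
        out = np.full(len(timestamps), "", dtype=object)
        ts = pd.DatetimeIndex(timestamps)
        idx = np.searchsorted(iv["start"].to_numpy(), ts.to_numpy(), side="right") - 1
        valid = idx >= 0
        inside = np.zeros(len(ts), dtype=bool)
        inside[valid] = ts.to_numpy()[valid] < iv["end"].to_numpy()[idx[valid]]
        out[inside] = iv["state"].to_numpy()[idx[inside]]
        return out

    def minutes_in_state(self, state: str) -> float:
        iv = self.intervals
        sel = iv["state"] == state
        return float((iv.loc[sel, "end"] - iv.loc[sel, "start"]).sum() / pd.Timedelta(minutes=1))


@dataclass
class ChamberConfig:
    """Open-flow respirometry chamber and multiplexer geometry."""

    volume_ml: float = 800.0
    flow_ml_min: float = 150.0
    n_chambers: int = 4
    dwell_s: float = 120.0
    baseline_channel: bool = True
    bp_kpa: float = 101.3

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("chamber volume must be positive")
        if self.flow_ml_min <= 0:
            raise ValueError("flow rate must be positive")
        if self.dwell_s <= 30.0:
            raise ValueError("channel dwell must exceed 30 s (washout discard)")

    @property
    def washout_tau_s(self) -> float:
        """First-order washout time constant V / flow, in seconds."""
        return self.volume_ml / self.flow_ml_min * 60.0


@dataclass
class SeasonParams:
    """State-level heart-rate distributions and bout structure per season.

    Heart-rate means/SDs (b.p.m.) are the study conditions; bout-structure
    parameters are tuned so the long-run truth fractions hit the seasonal
    targets (spring bats torpid for ~84% of daytime and ~22% of nighttime
    roosting; summer bats never torpid).
    """

    season: str
    torpid_hr: tuple[float, float] = (26.0, 9.0)
    # spring daytime arousals plateau near normothermic night levels
    rest_day_hr: tuple[float, float] = (340.0, 70.0)
    rest_night_hr: tuple[float, float] = (360.0, 80.0)
    flight_hr: tuple[float, float] = (743.0, 44.0)
    uses_daytime_torpor: bool = True
    # bout probability is set above the target fraction ratio because bouts
    # are truncated to fit their roosting stretch
    night_torpor_prob: float = 0.8
    night_torpid_frac: float = 0.22
    mean_flights_per_night: float = 1.4
    flight_bout_min: tuple[float, float] = (42.0, 12.0)  # lognormal mean/sd, minutes
    ramp_tau_min: float = 20.0
    ramp_dur_min: float = 30.0
    midday_arousal_prob: float = 0.9
    midday_rest_min: tuple[float, float] = (20.0, 10.0)
    emergence_delay_min: tuple[float, float] = (20.0, 5.0)
    temp_mean_c: float = 13.5
    temp_diel_amp_c: float = 5.0
    temp_noise_sd_c: float = 1.5
    temp_clip_c: tuple[float, float] = (-2.0, 26.0)
    start_date: str = "2020-04-10"


SEASON_DEFAULTS = {
    "spring": SeasonParams(season="spring"),
    "summer": SeasonParams(
        season="summer",
        rest_day_hr=(252.0, 49.0),
        rest_night_hr=(350.0, 57.0),
        flight_hr=(722.0, 95.0),
        uses_daytime_torpor=False,
        night_torpor_prob=0.0,
        night_torpid_frac=0.0,
        mean_flights_per_night=2.5,
        flight_bout_min=(42.0, 15.0),
        temp_mean_c=18.5,
        temp_diel_amp_c=4.0,
        temp_noise_sd_c=1.2,
        temp_clip_c=(10.0, 32.0),
        start_date="2020-06-20",
    ),
}


def _season_params(season: str, params: SeasonParams | None) -> SeasonParams:
    if params is not None:
        return params
    if season not in SEASON_DEFAULTS:
        raise ValueError(f"unknown season {season!r}: expected one of {sorted(SEASON_DEFAULTS)}")
    return SEASON_DEFAULTS[season]


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from a log-normal parameterized by its arithmetic mean and SD."""
    var = sd**2
    sigma2 = math.log(1.0 + var / mean**2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _ramp_hr(rng, start_hr, end_hr, n_min, tau_min, sd):
    """Exponential transition from start_hr toward end_hr over n_min minutes."""
    t = np.arange(n_min, dtype=float)
    base = end_hr + (start_hr - end_hr) * np.exp(-t / tau_min)
    return np.clip(base + rng.normal(0.0, sd, n_min), 10.0, 1100.0)


def gen_hr_profile(
    season: str,
    duration_h: float,
    seed: int,
    params: SeasonParams | None = None,
    site: tuple[float, float] = STUDY_SITE,
    force_no_flight: bool = False,
) -> tuple[HeartRateSeries, StateTruthTrack]:
    """Simulate a bat's minute-resolution heart-rate profile with truth.

    The simulated period starts at local sunrise on the season's default
    start date and is structured sunrise-to-sunrise: daytime roosting
    (torpid with brief midday arousals in spring, resting 200-400 b.p.m.
    in summer), emergence shortly after sunset, one to five foraging
    flights per night, and nighttime roosting in between.  Torpor entry
    and arousal are exponential ramps of configurable time constant and
    are labelled as their own states in the truth track.

    Parameters
    ----------
    season
        ``spring`` or ``summer``.
    duration_h
        Simulated span in hours (>= 24 recommended for budget work).
    seed
        Seed for the local random generator.
    params
        Override the seasonal defaults.
    force_no_flight
        Suppress all flight bouts (used for degenerate-case tests).

    Returns
    -------
    (HeartRateSeries, StateTruthTrack)
    """
    p = _season_params(season, params)
    rng = np.random.default_rng(seed)

    date0 = pd.Timestamp(p.start_date).date()
    st0 = solar_times(site[0], site[1], date0)
    if st0.sunrise is None:
        raise ValueError("study site/date has no sunrise; cannot anchor bat-days")
    start = pd.Timestamp(st0.sunrise).ceil("min")
    n_min = int(round(duration_h * 60))
    end = start + pd.Timedelta(minutes=n_min)

    # build (state, start_min, end_min) intervals day by day
    ivs: list[tuple[str, int, int]] = []

    def add(state: str, a: int, b: int) -> None:
        a, b = max(a, 0), min(b, n_min)
        if b > a:
            ivs.append((state, a, b))

    day_start = start
    day_idx = 0
    while (day_start - start) < pd.Timedelta(minutes=n_min):
        date = day_start.date()
        st = solar_times(site[0], site[1], date)
        st_next = solar_times(site[0], site[1], date + pd.Timedelta(days=1))
        sunset = pd.Timestamp(st.sunset)
        next_sunrise = pd.Timestamp(st_next.sunrise)
        t0 = int(round((day_start - start) / pd.Timedelta(minutes=1)))
        t_sunset = int(round((sunset - start) / pd.Timedelta(minutes=1)))
        t_next = int(round((next_sunrise - start) / pd.Timedelta(minutes=1)))

        delay = max(5.0, rng.normal(*p.emergence_delay_min))
        t_emerge = t_sunset + int(round(delay))

        ramp = int(round(p.ramp_dur_min))
        if p.uses_daytime_torpor:
            # daytime: entry -> torpor -> (midday arousal) -> torpor -> arousal
            cur = t0
            add("entry", cur, cur + ramp)
            cur += ramp
            day_end_arousal = t_emerge - ramp
            if rng.random() < p.midday_arousal_prob:
                mid = t0 + int(round(0.55 * (t_emerge - t0) + rng.normal(0, 30)))
                rest_len = int(round(max(5.0, _lognormal(rng, *p.midday_rest_min))))
                a0 = max(cur + 30, mid - rest_len // 2 - ramp)
                add("torpid", cur, a0)
                add("arousal", a0, a0 + ramp)
                add("resting", a0 + ramp, a0 + ramp + rest_len)
                add("entry", a0 + ramp + rest_len, a0 + 2 * ramp + rest_len)
                cur = a0 + 2 * ramp + rest_len
            add("torpid", cur, day_end_arousal)
            add("arousal", day_end_arousal, t_emerge)
        else:
            add("resting", t0, t_emerge)

        # night: flights interleaved with roosting (and spring night torpor)
        if force_no_flight:
            n_fl = 0
        elif p.mean_flights_per_night <= 1.5:
            n_fl = 1 + int(rng.random() < (p.mean_flights_per_night - 1.0))
        else:
            n_fl = int(np.clip(1 + rng.poisson(p.mean_flights_per_night - 1.0), 1, 5))
        night_len = t_next - t_emerge
        fl_bouts = []
        cur = t_emerge
        for k in range(n_fl):
            dur = int(round(np.clip(_lognormal(rng, *p.flight_bout_min), 5, 90)))
            if k == 0:
                fl_start = t_emerge
            else:
                lo = fl_bouts[-1][1] + 60
                hi = t_next - dur - 30
                if lo >= hi:
                    break
                fl_start = int(rng.integers(lo, hi))
            fl_bouts.append((fl_start, min(fl_start + dur, t_next)))

        # roosting stretches between flights
        roost: list[tuple[int, int]] = []
        cur = t_emerge
        for a, b in fl_bouts:
            if a > cur:
                roost.append((cur, a))
            cur = b
        if t_next > cur:
            roost.append((cur, t_next))

        night_states: list[tuple[str, int, int]] = [("flight", a, b) for a, b in fl_bouts]
        roost_min = sum(b - a for a, b in roost)
        torpor_here = (
            p.night_torpid_frac > 0
            and rng.random() < p.night_torpor_prob
            and roost_min > 120
        )
        if torpor_here and roost:
            target = p.night_torpid_frac * roost_min / max(p.night_torpor_prob, 1e-9)
            bout = int(round(np.clip(_lognormal(rng, target, 0.4 * target), 30, roost_min - 90)))
            a, b = max(roost, key=lambda r: r[1] - r[0])
            mid = (a + b) // 2
            tb0 = max(a + ramp, mid - bout // 2)
            tb1 = min(b - ramp, tb0 + bout)
            if tb1 - tb0 >= 20:
                for ra, rb in roost:
                    if (ra, rb) != (a, b):
                        night_states.append(("resting", ra, rb))
                night_states.append(("resting", a, tb0 - ramp))
                night_states.append(("entry", tb0 - ramp, tb0))
                night_states.append(("torpid", tb0, tb1))
                night_states.append(("arousal", tb1, tb1 + ramp))
                night_states.append(("resting", tb1 + ramp, b))
            else:
                night_states.extend(("resting", ra, rb) for ra, rb in roost)
        else:
            night_states.extend(("resting", ra, rb) for ra, rb in roost)

        for state, a, b in sorted(night_states, key=lambda s: s[1]):
            add(state, a, b)

        day_start = next_sunrise
        day_idx += 1

    # sort, clip to duration, and fill any arithmetic cracks with the
    # neighbouring state
    ivs.sort(key=lambda s: s[1])
    clean: list[tuple[str, int, int]] = []
    cursor = 0
    for state, a, b in ivs:
        a = max(a, cursor)
        if b <= a:
            continue
        if a > cursor and clean:
            prev = clean[-1]
            clean[-1] = (prev[0], prev[1], a)
        clean.append((state, a, b))
        cursor = b
    if clean and clean[-1][2] < n_min:
        clean[-1] = (clean[-1][0], clean[-1][1], n_min)

    # per-minute heart rate from the state sequence
    hr = np.empty(n_min)
    state_arr = np.empty(n_min, dtype=object)
    dists = {
        "torpid": p.torpid_hr,
        "resting_day": p.rest_day_hr,
        "resting_night": p.rest_night_hr,
        "flight": p.flight_hr,
    }
    # recover sunset boundaries for day/night resting distinction
    ts_grid = start + pd.to_timedelta(np.arange(n_min), unit="min")
    is_day = np.zeros(n_min, dtype=bool)
    d = start
    while (d - start) < pd.Timedelta(minutes=n_min):
        st = solar_times(site[0], site[1], d.date())
        a = int(max(0, round((pd.Timestamp(st.sunrise) - start) / pd.Timedelta(minutes=1))))
        b = int(min(n_min, round((pd.Timestamp(st.sunset) - start) / pd.Timedelta(minutes=1))))
        if b > a:
            is_day[a:b] = True
        d += pd.Timedelta(days=1)

    prev_level = p.rest_day_hr[0] if not p.uses_daytime_torpor else p.rest_night_hr[0]
    for i, (state, a, b) in enumerate(clean):
        n = b - a
        state_arr[a:b] = state
        if state == "torpid":
            mean, sd = dists["torpid"]
            hr[a:b] = np.clip(rng.normal(mean, sd, n), 10.0, 80.0)
            prev_level = mean
        elif state == "resting":
            key = "resting_day" if is_day[a:b].mean() > 0.5 else "resting_night"
            mean, sd = dists[key]
            hr[a:b] = np.clip(rng.normal(mean, sd, n), 120.0, 599.0)
            prev_level = mean
        elif state == "flight":
            mean, sd = dists["flight"]
            hr[a:b] = np.clip(rng.normal(mean, sd, n), 600.0, 900.0)
            prev_level = mean
        elif state == "entry":
            hr[a:b] = _ramp_hr(rng, prev_level, p.torpid_hr[0], n, p.ramp_tau_min, 5.0)
            prev_level = p.torpid_hr[0]
        else:  # arousal ramps to normothermic resting; take-off is abrupt
            key = "resting_day" if is_day[a:b].mean() > 0.5 else "resting_night"
            target = dists[key][0]
            hr[a:b] = _ramp_hr(rng, prev_level, target, n, p.ramp_tau_min, 10.0)
            prev_level = target

    series = HeartRateSeries(
        pd.DataFrame(
            {
                "timestamp": ts_grid,
                "hr_bpm": hr,
                "quality": 1.0,
                "source": "auto",
            }
        )
    )
    iv_df = pd.DataFrame(
        {
            "state": [s for s, _, _ in clean],
            "start": [start + pd.Timedelta(minutes=a) for _, a, _ in clean],
            "end": [start + pd.Timedelta(minutes=b) for _, _, b in clean],
        }
    )
    # merge any adjacent duplicates created by crack filling
    keep = [0] + [k for k in range(1, len(iv_df)) if iv_df["state"].iloc[k] != iv_df["state"].iloc[k - 1]]
    merged = iv_df.iloc[keep].copy()
    merged["end"] = list(merged["start"].iloc[1:]) + [iv_df["end"].iloc[-1]]
    track = StateTruthTrack(merged.reset_index(drop=True), season=p.season)
    return series, track


def gen_carrier_audio(
    schedule: BeatSchedule,
    sample_rate: float = 16000.0,
    carrier_freq: float = 4000.0,
    interruption_ms: float = 15.0,
    snr_db: float = math.inf,
    dropout_fraction: float = 0.0,
    seed: int = 0,
) -> AudioTrace:
    """Synthesize carrier-interruption audio from a beat schedule.

    A unit-amplitude carrier tone is gated to near zero for
    ``interruption_ms`` at every scheduled beat (1 ms cosine edges), white
    Gaussian noise is added at ``snr_db`` relative to carrier power, and a
    ``dropout_fraction`` of beats is deleted to emulate un-scorable audio.
    """
    if carrier_freq >= sample_rate / 2:
        raise ValueError(
            f"carrier {carrier_freq} Hz violates Nyquist at {sample_rate} Hz sampling"
        )
    beats = schedule.beat_times
    if beats.size > 1:
        min_ibi_ms = float(np.min(np.diff(beats))) * 1000.0
        if interruption_ms >= min_ibi_ms:
            raise ValueError(
                f"interruption {interruption_ms} ms >= minimum inter-beat "
                f"interval {min_ibi_ms:.1f} ms"
            )
    rng = np.random.default_rng(seed)
    if dropout_fraction > 0 and beats.size:
        keep = rng.random(beats.size) >= dropout_fraction
        beats = beats[keep]

    n = int(round(schedule.duration_s * sample_rate))
    env = np.ones(n)
    gap = int(round(interruption_ms * 1e-3 * sample_rate))
    edge = max(int(round(1e-3 * sample_rate)), 1)
    ramp = 0.5 * (1 + np.cos(np.linspace(0, math.pi, edge)))
    for t in beats:
        i = int(round(t * sample_rate))
        j = min(i + gap, n)
        if i >= n:
            continue
        env[i:j] = 0.0
        if i - edge >= 0:
            env[i - edge:i] = np.minimum(env[i - edge:i], ramp)
        if j + edge <= n:
            env[j:j + edge] = np.minimum(env[j:j + edge], ramp[::-1])

    t_axis = np.arange(n) / sample_rate
    samples = env * np.sin(2 * math.pi * carrier_freq * t_axis)
    if math.isfinite(snr_db):
        carrier_rms = 1.0 / math.sqrt(2.0)
        noise_sd = carrier_rms / (10.0 ** (snr_db / 20.0))
        samples = samples + rng.normal(0.0, noise_sd, n)
    return AudioTrace(sample_rate=sample_rate, samples=samples)


def gen_respirometry(
    true_vo2: dict[str, float] | dict[str, object],
    chamber: ChamberConfig | None = None,
    duration_min: float = 60.0,
    rer: float = 0.85,
    drift_o2=None,
    drift_co2=None,
    noise_sd: float = 0.0,
    lag_co2_s: float = 0.0,
    wvp_kpa: float = 0.0,
    seed: int = 0,
) -> tuple[GasTrace, dict]:
    """Forward-simulate a multiplexed open-flow respirometry recording.

    Each chamber's excurrent dry fractions follow first-order washout
    driven by the animal's O2 consumption (``true_vo2``, ml O2/h, scalar or
    callable of time in minutes) and CO2 production (``rer`` times VO2).
    The metered flow is excurrent (pull mode); the incurrent flow differs
    by the net respiratory gas exchange.  The analyzer sees the chambers
    through a multiplexer (baseline channel first when configured), with
    the CO2 signal delayed by ``lag_co2_s``, optional additive drift on
    either gas, water-vapour dilution at ``wvp_kpa``, and Gaussian
    analyzer noise.

    Returns the trace and a truth dict with the VO2 schedules and RER.
    """
    if not 0.7 < rer < 1.0:
        raise ValueError("RER must lie in (0.7, 1.0)")
    chamber = chamber or ChamberConfig()
    rng = np.random.default_rng(seed)
    dt = 1.0  # s
    n = int(round(duration_min * 60 / dt))
    t_s = np.arange(n) * dt

    def as_fn(v):
        return v if callable(v) else (lambda tm, v=v: v)

    vo2_fns = {ch: as_fn(v) for ch, v in true_vo2.items()}
    for ch, fn in vo2_fns.items():
        if np.any(np.asarray([fn(tm) for tm in (0.0, duration_min / 2)]) < 0):
            raise ValueError(f"VO2 schedule for {ch!r} must be non-negative")

    flow_ex = chamber.flow_ml_min
    vol = chamber.volume_ml
    chamber_o2: dict[str, np.ndarray] = {}
    chamber_co2: dict[str, np.ndarray] = {}
    for ch, fn in vo2_fns.items():
        fo2 = np.empty(n)
        fco2 = np.empty(n)
        o2, co2 = INCURRENT_O2, INCURRENT_CO2
        # start chambers at their own steady state so short simulations
        # reflect the schedule's initial level
        vdot0 = fn(0.0) / 60.0
        vdot0_c = rer * vdot0
        fin0 = flow_ex + vdot0 - vdot0_c
        o2 = (fin0 * INCURRENT_O2 - vdot0) / flow_ex
        co2 = (fin0 * INCURRENT_CO2 + vdot0_c) / flow_ex
        for i in range(n):
            tm = t_s[i] / 60.0
            vdot = fn(tm) / 60.0  # ml O2 / min
            vdot_c = rer * vdot
            fin = flow_ex + vdot - vdot_c
            do2 = (fin * INCURRENT_O2 - flow_ex * o2 - vdot) / vol
            dco2 = (fin * INCURRENT_CO2 - flow_ex * co2 + vdot_c) / vol
            fo2[i], fco2[i] = o2, co2
            o2 += do2 * dt / 60.0
            co2 += dco2 * dt / 60.0
        chamber_o2[ch] = fo2
        chamber_co2[ch] = fco2

    # analyzer-side CO2 transit lag
    lag_n = int(round(lag_co2_s / dt))
    if lag_n:
        for ch in chamber_co2:
            s = chamber_co2[ch]
            chamber_co2[ch] = np.r_[np.full(lag_n, s[0]), s[:-lag_n]]

    channels = (["baseline"] if chamber.baseline_channel else []) + [
        f"ch{i + 1}" for i in range(chamber.n_chambers)
    ]
    dwell_n = int(round(chamber.dwell_s / dt))
    cycle = np.repeat(np.arange(len(channels)), dwell_n)
    chan_seq = np.array(channels, dtype=object)[np.resize(cycle, n)]

    d_o2 = as_fn(drift_o2 if drift_o2 is not None else 0.0)
    d_co2 = as_fn(drift_co2 if drift_co2 is not None else 0.0)
    drift_o2_arr = np.asarray([d_o2(ts) for ts in t_s], dtype=float)
    drift_co2_arr = np.asarray([d_co2(ts) for ts in t_s], dtype=float)

    fo2_meas = np.empty(n)
    fco2_meas = np.empty(n)
    for i, ch in enumerate(chan_seq):
        if ch == "baseline":
            o2_dry, co2_dry = INCURRENT_O2, INCURRENT_CO2
        else:
            o2_dry = chamber_o2.get(ch, np.full(n, INCURRENT_O2))[i]
            co2_dry = chamber_co2.get(ch, np.full(n, INCURRENT_CO2))[i]
        wet = (chamber.bp_kpa - wvp_kpa) / chamber.bp_kpa
        fo2_meas[i] = o2_dry * wet + drift_o2_arr[i]
        fco2_meas[i] = co2_dry * wet + drift_co2_arr[i]
    if noise_sd > 0:
        fo2_meas = fo2_meas + rng.normal(0, noise_sd, n)
        fco2_meas = np.clip(fco2_meas + rng.normal(0, noise_sd, n), 0.0, 1.0)

    trace = GasTrace(
        pd.DataFrame(
            {
                "time_s": t_s,
                "channel": chan_seq,
                "fo2": np.clip(fo2_meas, 0.0, 1.0),
                "fco2": np.clip(fco2_meas, 0.0, 1.0),
                "wvp_kpa": wvp_kpa,
                "bp_kpa": chamber.bp_kpa,
                "flow_ml_min": flow_ex,
            }
        )
    )
    truth = {"vo2_ml_h": {ch: vo2_fns[ch] for ch in vo2_fns}, "rer": rer, "lag_co2_s": lag_co2_s}
    return trace, truth


def gen_calibration_pairs(
    intercept: float,
    slope: float,
    noise_sd: float,
    hr_range: tuple[float, float] = (40.0, 800.0),
    n: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired (heart rate, mass-specific VO2) laboratory observations.

    ``log(VO2) = intercept + slope * log(HR) + N(0, noise_sd)`` with
    natural logs; heart rates are drawn log-uniformly over ``hr_range``.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if n < 3:
        raise ValueError("need at least 3 pairs for a downstream fit")
    lo, hi = hr_range
    if not (10.0 < lo < hi < 1100.0):
        raise ValueError("hr_range must be non-degenerate and within (10, 1100) b.p.m.")
    rng = np.random.default_rng(seed)
    hr = np.exp(rng.uniform(math.log(lo), math.log(hi), n))
    log_vo2 = intercept + slope * np.log(hr) + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"hr_bpm": hr, "vo2_ml_g_h": np.exp(log_vo2)})


def gen_temperature(
    season: str,
    days: int,
    seed: int = 0,
    params: SeasonParams | None = None,
    amplitude: float | None = None,
) -> pd.DataFrame:
    """Hourly ambient temperature: sinusoidal diel cycle plus noise.

    The long-run mean and range match the seasonal envelope (spring mean
    13.5 C, summer 18.5 C); ``amplitude=0`` gives a constant series at the
    seasonal mean.  Values are clipped to the season's configured range.
    """
    p = _season_params(season, params)
    rng = np.random.default_rng(seed)
    amp = p.temp_diel_amp_c if amplitude is None else amplitude
    idx = pd.date_range(
        pd.Timestamp(p.start_date, tz="UTC"), periods=days * 24, freq="h"
    )
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    base = p.temp_mean_c + amp * np.sin(2 * math.pi * (hour - 9.0) / 24.0)
    noise = rng.normal(0.0, p.temp_noise_sd_c, len(idx)) if p.temp_noise_sd_c > 0 else 0.0
    temp = base + noise
    if amp > 0 or p.temp_noise_sd_c > 0:
        temp = np.clip(temp, *p.temp_clip_c)
    return pd.DataFrame({"timestamp": idx, "temp_c": temp})


def apply_gaps(
    series: HeartRateSeries,
    gap_fraction: float,
    seed: int = 0,
    mean_gap_min: float = 30.0,
) -> HeartRateSeries:
    """Knock out contiguous chunks of a heart-rate series as gaps.

    Gap starts are placed uniformly at random (missing completely at
    random) with exponential lengths of mean ``mean_gap_min`` until the
    requested fraction of windows is gap-flagged.  Emulates receiver
    dropouts and un-scorable audio.
    """
    if not 0.0 <= gap_fraction < 1.0:
        raise ValueError("gap_fraction must lie in [0, 1)")
    out = series.copy()
    if gap_fraction == 0.0 or len(out) == 0:
        return out
    rng = np.random.default_rng(seed)
    n = len(out)
    target = int(round(gap_fraction * n))
    is_gap = np.zeros(n, dtype=bool)
    guard = 0
    while is_gap.sum() < target and guard < 10000:
        guard += 1
        start = int(rng.integers(0, n))
        length = max(1, int(round(rng.exponential(mean_gap_min))))
        is_gap[start:start + length] = True
    # trim overshoot from the end of the last-placed runs
    excess = int(is_gap.sum()) - target
    if excess > 0:
        idx = np.flatnonzero(is_gap)
        is_gap[idx[rng.choice(idx.size, excess, replace=False)]] = False
    df = out.data
    df.loc[is_gap, "hr_bpm"] = np.nan
    df.loc[is_gap, "quality"] = 0.0
    df.loc[is_gap, "source"] = "gap"
    return HeartRateSeries(df)
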