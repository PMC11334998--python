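"""Day-phase segmentation, torpor classification and daily energy budgets.

A *bat-day* runs sunrise to sunrise and is partitioned into three
day-phases:

``daytime``
    sunrise until emergence from the roost (the first flight after
    sunset),
``flight``
    the time the bat was flying (from a flight log, or auto-detected as
    sustained heart rate >= 500 b.p.m.),
``nighttime``
    roosting after sunset and before the next sunrise, excluding flights.

Within roosting phases a hysteresis state machine labels each minute
torpid, resting, or transitional (entry into / arousal from torpor);
transitional minutes never contribute to torpid or resting means.

Daily energy expenditure (DEE, kJ/day) integrates the heart-rate-derived
energy-expenditure series over each bat-day, filling recording gaps with
the bat-day's phase-mean rate times the gap duration.  Bat-days with more
than 35% gaps are excluded, as are partial deployment days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hrsignal import HeartRateSeries
from .solar import SolarTimes, solar_times

__all__ = [
    "PHASES",
    "STATES",
    "BatDayBudget",
    "segment_phases",
    "classify_states",
    "annotate_minutes",
    "phase_state_means",
    "gap_filled_dee",
    "summarize_groups",
    "solar_times",
]

PHASES = ("daytime", "nighttime", "flight")
STATES = ("torpid", "resting", "entry", "arousal")

#: shortest flight retained for heart-rate/energy summaries (min)
MIN_FLIGHT_MIN = 3.0
#: bat-days with more than this gap fraction are excluded
MAX_GAP_FRACTION = 0.35
#: partial first/last deployment days need at least this coverage
MIN_DAY_COVERAGE = 0.65


@dataclass
class BatDayBudget:
    """Energy bookkeeping for one bat-day (sunrise to sunrise)."""

    bat_id: str
    date: dt.date
    phase_measured_min: dict[str, float]
    phase_gap_min: dict[str, float]
    phase_measured_kj: dict[str, float]
    phase_filled_kj: dict[str, float]
    gap_fraction: float
    dee_kj: float
    excluded: bool = False
    exclude_reason: str | None = None

    @property
    def total_minutes(self) -> float:
        return sum(self.phase_measured_min.values()) + sum(self.phase_gap_min.values())

    def phase_energy_kj(self, phase: str) -> float:
        return self.phase_measured_kj.get(phase, 0.0) + self.phase_filled_kj.get(phase, 0.0)


def _detect_flights(
    series: HeartRateSeries,
    hr_thresh: float = 500.0,
    min_bout_min: float = MIN_FLIGHT_MIN,
) -> pd.DataFrame:
    """Auto-detect flight bouts as sustained high heart rate."""
    ts = series.timestamps
    hr = series.hr
    step_min = series.step / pd.Timedelta(minutes=1)
    flying = np.where(np.isfinite(hr), hr >= hr_thresh, False)
    rows = []
    i = 0
    n = len(flying)
    while i < n:
        if flying[i]:
            j = i
            while j < n and flying[j]:
                j += 1
            dur = (j - i) * step_min
            if dur >= min_bout_min:
                rows.append((ts[i], ts[j - 1] + series.step, dur))
            i = j
        else:
            i += 1
    return pd.DataFrame(rows, columns=["start", "end", "duration_min"])


def segment_phases(
    series: HeartRateSeries,
    site: tuple[float, float],
    flights: pd.DataFrame | None = None,
    drop_before_first_flight: bool = True,
    flight_hr_thresh: float = 500.0,
    bat_id: str = "bat",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a heart-rate series into bat-days and day-phases.

    Flight intervals come from the supplied log when present, otherwise
    they are auto-detected as heart rate >= ``flight_hr_thresh`` sustained
    for at least 3 min.  Emergence is the start of the first flight after
    sunset; with no flight that night, daytime ends at sunset.  Data
    before the first flight of the whole deployment are dropped by
    default, mirroring the field protocol of discarding the
    post-handling period.

    Returns
    -------
    (phases, flights)
        ``phases``: columns ``bat_id, bat_day, phase, start, end,
        retained`` (flights shorter than 3 min keep their phase but are
        not retained for summaries).  ``flights``: the flight bouts used.
    """
    if len(series) == 0:
        raise ValueError("empty heart-rate series")
    ts = series.timestamps
    if flights is None:
        flights = _detect_flights(series, hr_thresh=flight_hr_thresh)
    else:
        flights = flights.copy()
        flights["start"] = pd.to_datetime(flights["start"], utc=True)
        flights["end"] = pd.to_datetime(flights["end"], utc=True)
        flights["duration_min"] = (flights["end"] - flights["start"]) / pd.Timedelta(minutes=1)

    t_begin, t_end = ts[0], ts[-1] + series.step
    if drop_before_first_flight and len(flights):
        t_begin = max(t_begin, flights["start"].iloc[0])

    # solar events for every covered civil date (plus one margin day each side)
    dates = pd.date_range(t_begin.normalize() - pd.Timedelta(days=1),
                          t_end.normalize() + pd.Timedelta(days=1), freq="D")
    solar: dict[dt.date, SolarTimes] = {}
    for d in dates:
        st = solar_times(site[0], site[1], d.date())
        if st.sunrise is None or st.sunset is None:
            raise ValueError(f"no sunrise/sunset at {site} on {d.date()}: cannot define day-phases")
        solar[d.date()] = st

    sunrises = sorted(pd.Timestamp(st.sunrise) for st in solar.values())
    # bat-day boundaries overlapping the record
    bounds = [sr for sr in sunrises if t_begin - pd.Timedelta(days=1) <= sr <= t_end + pd.Timedelta(days=1)]

    rows = []
    for k in range(len(bounds) - 1):
        day_a, day_b = bounds[k], bounds[k + 1]
        if day_b <= t_begin or day_a >= t_end:
            continue
        sunset = pd.Timestamp(solar[day_a.date()].sunset)
        day_flights = flights.loc[(flights["start"] < day_b) & (flights["end"] > day_a)]
        after_sunset = day_flights.loc[day_flights["start"] >= sunset]
        emergence = after_sunset["start"].iloc[0] if len(after_sunset) else sunset

        def clip(a, b):
            return max(a, t_begin, day_a), min(b, t_end, day_b)

        segs: list[tuple[str, pd.Timestamp, pd.Timestamp, bool]] = []
        a, b = clip(day_a, emergence)
        if b > a:
            segs.append(("daytime", a, b, True))
        # night span minus flights
        cursor = max(emergence, day_a, t_begin)
        night_end = min(day_b, t_end)
        for fr in day_flights.sort_values("start").itertuples():
            fa, fb = clip(fr.start, fr.end)
            if fb <= fa:
                continue
            if fa > cursor:
                segs.append(("nighttime", cursor, fa, True))
            segs.append(("flight", fa, fb, fr.duration_min >= MIN_FLIGHT_MIN))
            cursor = max(cursor, fb)
        if night_end > cursor:
            segs.append(("nighttime", cursor, night_end, True))

        for phase, a, b, retained in segs:
            if b > a:
                rows.append((bat_id, day_a.date(), phase, a, b, retained))

    phases = pd.DataFrame(rows, columns=["bat_id", "bat_day", "phase", "start", "end", "retained"])
    return phases, flights


def classify_states(
    series: HeartRateSeries,
    low_thresh: float = 100.0,
    high_thresh: float = 150.0,
    min_bout_min: float = 10.0,
    slope_limit_bpm_min: float = 10.0,
    smooth_min: int = 5,
) -> pd.DataFrame:
    """Label each minute torpid / resting / entry / arousal by hysteresis.

    The heart rate is smoothed with a short rolling median, then minutes
    below ``low_thresh`` are torpid candidates and minutes above
    ``high_thresh`` resting candidates; minutes between thresholds or
    changing faster than ``slope_limit_bpm_min`` are transitional.  Stable
    bouts shorter than ``min_bout_min`` are demoted to transitional, and
    transitional runs are named ``entry`` (towards torpor) or ``arousal``
    (towards normothermy) from their neighbouring stable states.  Gaps
    split bouts.

    Returns a frame with columns ``state, start, end``.
    """
    if low_thresh >= high_thresh:
        raise ValueError("low_thresh must be below high_thresh")
    ts = series.timestamps
    hr = series.hr.copy()
    step_min = series.step / pd.Timedelta(minutes=1)
    smooth_n = max(int(round(smooth_min / step_min)), 1)
    hr_s = pd.Series(hr).rolling(smooth_n, min_periods=1, center=True).median().to_numpy()
    slope = np.gradient(hr_s) / step_min

    n = len(hr)
    lab = np.full(n, "", dtype=object)
    valid = np.isfinite(hr)
    fast = np.abs(slope) > slope_limit_bpm_min
    lab[valid & (hr_s < low_thresh) & ~fast] = "torpid"
    lab[valid & (hr_s > high_thresh) & ~fast] = "resting"
    lab[valid & (lab == "")] = "trans"

    # demote short stable bouts (gap-split) to transitional
    min_n = int(round(min_bout_min / step_min))
    i = 0
    while i < n:
        if lab[i] in ("torpid", "resting"):
            j = i
            while j < n and lab[j] == lab[i]:
                j += 1
            if j - i < min_n:
                lab[i:j] = "trans"
            i = j
        else:
            i += 1

    # name transitional runs by direction
    i = 0
    while i < n:
        if lab[i] == "trans":
            j = i
            while j < n and lab[j] == "trans":
                j += 1
            prev_state = lab[i - 1] if i > 0 and lab[i - 1] in ("torpid", "resting") else None
            next_state = lab[j] if j < n and lab[j] in ("torpid", "resting") else None
            if next_state == "torpid" or (next_state is None and prev_state == "resting"):
                name = "entry"
            elif next_state == "resting" or (next_state is None and prev_state == "torpid"):
                name = "arousal"
            else:
                name = "entry" if np.nanmean(slope[i:j]) < 0 else "arousal"
            lab[i:j] = name
            i = j
        else:
            i += 1

    rows = []
    i = 0
    while i < n:
        if lab[i] == "":
            i += 1
            continue
        j = i
        while j < n and lab[j] == lab[i]:
            j += 1
        rows.append((lab[i], ts[i], ts[j - 1] + series.step))
        i = j
    return pd.DataFrame(rows, columns=["state", "start", "end"])


def _interval_label(timestamps: pd.DatetimeIndex, intervals: pd.DataFrame, col: str) -> np.ndarray:
    """Label each timestamp with the interval (if any) that contains it."""
    out = np.full(len(timestamps), "", dtype=object)
    if not len(intervals):
        return out
    iv = intervals.sort_values("start").reset_index(drop=True)
    starts = iv["start"].to_numpy()
    ends = iv["end"].to_numpy()
    t = pd.DatetimeIndex(timestamps).to_numpy()
    idx = np.searchsorted(starts, t, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(len(t), dtype=bool)
    inside[ok] = t[ok] < ends[idx[ok]]
    out[inside] = iv[col].to_numpy()[idx[inside]]
    return out


def annotate_minutes(
    series: HeartRateSeries,
    phases: pd.DataFrame,
    states: pd.DataFrame | None = None,
    ee: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-minute frame joining heart rate, phase, state and energy rate.

    Columns: ``timestamp, hr_bpm, is_gap, phase, bat_day, state,
    ee_kj_h`` (state blank outside roosting; ee NaN when not supplied).
    """
    ts = series.timestamps
    out = pd.DataFrame(
        {
            "timestamp": ts,
            "hr_bpm": series.hr,
            "is_gap": series.is_gap,
            "phase": _interval_label(ts, phases, "phase"),
            "bat_day": _interval_label(ts, phases, "bat_day"),
        }
    )
    if states is not None:
        out["state"] = _interval_label(ts, states, "state")
        out.loc[~out["phase"].isin(["daytime", "nighttime"]), "state"] = ""
    else:
        out["state"] = ""
    if ee is not None:
        e = ee.set_index("timestamp")["ee_kj_h"]
        out["ee_kj_h"] = e.reindex(ts).to_numpy()
    else:
        out["ee_kj_h"] = np.nan
    return out


def phase_state_means(
    minutes: pd.DataFrame, bat_id: str = "bat", min_phase_min: float = 30.0
) -> pd.DataFrame:
    """Two-stage (within-day, then across-day) means per phase and state.

    For each bat-day, mean heart rate and energy rate are computed per
    day-phase and per physiological state (entry/arousal excluded from
    state means by construction); the across-day mean of those daily
    means is returned, along with relative time torpid per day-phase
    (torpid minutes over roosting minutes).  Days with no minutes in a
    category contribute nothing to that category (absence is not zero),
    and daily contributions with under ``min_phase_min`` observed minutes
    (partial deployment edges) are dropped rather than letting a sliver
    of a day carry the weight of a full one.
    """
    m = minutes.loc[minutes["phase"] != ""].copy()
    if m.empty:
        return pd.DataFrame(
            columns=["bat_id", "category", "kind", "mean_hr_bpm", "mean_ee_kj_h", "time_frac", "n_days"]
        )
    rows = []
    meas = m.loc[~m["is_gap"]]
    step_min = 1.0
    if len(minutes) > 1:
        step_min = float(
            (minutes["timestamp"].iloc[1] - minutes["timestamp"].iloc[0]) / pd.Timedelta(minutes=1)
        )
    min_n = max(int(round(min_phase_min / step_min)), 1)

    def daily_means(grp):
        daily = grp.groupby("bat_day").agg(
            hr=("hr_bpm", "mean"), ee=("ee_kj_h", "mean"), n=("hr_bpm", "size")
        )
        return daily.loc[daily["n"] >= min_n]

    for phase, grp in meas.groupby("phase"):
        daily = daily_means(grp)
        if daily.empty:
            continue
        rows.append((bat_id, phase, "phase", daily["hr"].mean(), daily["ee"].mean(), np.nan, len(daily)))
    roost = meas.loc[meas["phase"].isin(["daytime", "nighttime"])]
    for state in ("torpid", "resting"):
        sel = roost.loc[roost["state"] == state]
        if sel.empty:
            continue
        daily = daily_means(sel)
        if daily.empty:
            continue
        rows.append((bat_id, state, "state", daily["hr"].mean(), daily["ee"].mean(), np.nan, len(daily)))
    # relative time torpid, per phase, roosting-minute denominator
    for phase in ("daytime", "nighttime"):
        sel = roost.loc[roost["phase"] == phase]
        if sel.empty:
            continue
        counts = sel.groupby("bat_day").size()
        frac = sel.groupby("bat_day").apply(
            lambda g: (g["state"] == "torpid").mean(), include_groups=False
        )
        frac = frac.loc[counts >= min_n]
        if frac.empty:
            continue
        rows.append((bat_id, f"torpid_frac_{phase}", "fraction", np.nan, np.nan, frac.mean(), len(frac)))
    return pd.DataFrame(
        rows, columns=["bat_id", "category", "kind", "mean_hr_bpm", "mean_ee_kj_h", "time_frac", "n_days"]
    )


def gap_filled_dee(
    minutes: pd.DataFrame,
    bat_id: str = "bat",
    max_gap_fraction: float = MAX_GAP_FRACTION,
    min_day_coverage: float = MIN_DAY_COVERAGE,
) -> list[BatDayBudget]:
    """Integrate energy expenditure per bat-day with phase-mean gap filling.

    Measured energy is the time-integral of the kJ/h series over observed
    minutes; each phase's gap minutes are filled at that phase's mean
    observed rate for the same bat-day.  A bat-day is excluded (returned
    with ``excluded=True``) when its gap fraction exceeds
    ``max_gap_fraction``, when any phase with positive duration has no
    observed minutes (its mean rate is undefined), or when the day spans
    less than ``min_day_coverage`` of a full sunrise-to-sunrise cycle
    (partial deployment days).
    """
    budgets: list[BatDayBudget] = []
    m = minutes.loc[minutes["phase"] != ""]
    step_min = 1.0
    if len(minutes) > 1:
        step_min = float(
            (minutes["timestamp"].iloc[1] - minutes["timestamp"].iloc[0]) / pd.Timedelta(minutes=1)
        )
    for day, grp in m.groupby("bat_day"):
        measured_min: dict[str, float] = {}
        gap_min: dict[str, float] = {}
        measured_kj: dict[str, float] = {}
        filled_kj: dict[str, float] = {}
        reason = None
        total_min = len(grp) * step_min
        if total_min < min_day_coverage * 1440.0:
            reason = f"partial day: {total_min:.0f} of 1440 min covered"
        gap_frac = float(grp["is_gap"].mean())
        if reason is None and gap_frac > max_gap_fraction:
            reason = f"gap fraction {gap_frac:.2f} exceeds {max_gap_fraction:.2f}"
        for phase, pg in grp.groupby("phase"):
            obs = pg.loc[~pg["is_gap"] & np.isfinite(pg["ee_kj_h"])]
            measured_min[phase] = len(obs) * step_min
            gap_min[phase] = (len(pg) - len(obs)) * step_min
            measured_kj[phase] = float(obs["ee_kj_h"].sum()) * step_min / 60.0
            if len(obs):
                mean_rate = float(obs["ee_kj_h"].mean())
                filled_kj[phase] = mean_rate * gap_min[phase] / 60.0
            else:
                filled_kj[phase] = 0.0
                if reason is None and len(pg):
                    reason = f"phase {phase!r} entirely gap: mean rate undefined"
        dee = sum(measured_kj.values()) + sum(filled_kj.values())
        budgets.append(
            BatDayBudget(
                bat_id=bat_id,
                date=day,
                phase_measured_min=measured_min,
                phase_gap_min=gap_min,
                phase_measured_kj=measured_kj,
                phase_filled_kj=filled_kj,
                gap_fraction=gap_frac,
                dee_kj=dee,
                excluded=reason is not None,
                exclude_reason=reason,
            )
        )
    return budgets


def summarize_groups(
    budgets_by_group: dict[str, list[BatDayBudget]],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Group means of DEE, per-phase energy shares and time budgets.

    Excluded bat-days are ignored.  Per-bat-day percent-of-DEE and time
    fractions are computed first, then averaged within group.  Percent
    changes between the two groups (in iteration order: reference first)
    are reported at integer precision.

    Returns
    -------
    (summary, changes)
        ``summary``: one row per group with ``dee_mean_kj, dee_sd_kj,
        n_bat_days`` and per-phase ``pct_dee_<phase>`` /
        ``time_frac_<phase>`` columns.  ``changes``: percent change of
        mean DEE relative to the first group, keyed by group.
    """
    rows = []
    for group, budgets in budgets_by_group.items():
        kept = [b for b in budgets if not b.excluded]
        if not kept:
            raise ValueError(f"group {group!r} has no retained bat-days")
        dee = np.array([b.dee_kj for b in kept])
        row = {
            "group": group,
            "n_bat_days": len(kept),
            "dee_mean_kj": float(dee.mean()),
            "dee_sd_kj": float(dee.std(ddof=1)) if len(kept) > 1 else 0.0,
        }
        for phase in PHASES:
            pct = np.array([100.0 * b.phase_energy_kj(phase) / b.dee_kj for b in kept])
            tfrac = np.array(
                [
                    (b.phase_measured_min.get(phase, 0.0) + b.phase_gap_min.get(phase, 0.0))
                    / b.total_minutes
                    for b in kept
                ]
            )
            row[f"pct_dee_{phase}"] = float(pct.mean())
            row[f"time_frac_{phase}"] = float(tfrac.mean())
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("group")
    ref = summary["dee_mean_kj"].iloc[0]
    changes = {
        g: float(round(100.0 * (summary["dee_mean_kj"].loc[g] - ref) / ref))
        for g in summary.index
    }
    return summary, changes


def percent_change(reference: float, value: float) -> int:
    """Integer percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return int(round(100.0 * (value - reference) / reference))
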