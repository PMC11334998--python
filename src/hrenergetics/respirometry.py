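"""Open-flow (pull-mode) respirometry: gas traces to metabolic rates.

A multiplexed analyzer samples the excurrent air of several animal
chambers plus a baseline (incurrent air) channel.  Processing follows the
standard flow-through respirometry recipe:

1. :func:`split_and_discard` — drop the washout period after each channel
   switch (the analyzer cell still holds the previous channel's gas),
2. :func:`drift_correct` — subtract a smoothing-spline fit of the baseline
   channel's deviation from nominal incurrent composition,
3. :func:`lag_align` — phase-match CO2 to O2 (the CO2 analyzer sits
   further down the plumbing and lags),
4. :func:`dry_correct` — remove water-vapour dilution,
5. :func:`compute_vo2_vco2` — nitrogen-balance algebra for excurrent-
   metered (pull-mode) flow,
6. :func:`mass_specific_and_energy` — standardize by body mass and convert
   to energy expenditure with the caloric equivalent of oxygen.

Only pull-mode (excurrent-metered) systems are supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "GasTrace",
    "MetabolicSeries",
    "ChamberSegment",
    "split_and_discard",
    "drift_correct",
    "lag_align",
    "dry_correct",
    "compute_vo2_vco2",
    "mass_specific_and_energy",
    "recover_metabolic_rates",
    "OXYGEN_CALORIC_EQUIV_J_PER_ML",
    "BASELINE_CHANNEL",
]

#: caloric equivalent of oxygen: joules released per ml O2 consumed
OXYGEN_CALORIC_EQUIV_J_PER_ML = 20.083

#: channel id of the reference (incurrent air) line
BASELINE_CHANNEL = "baseline"

#: nominal incurrent dry-air composition used as the drift anchor
NOMINAL_INCURRENT_O2 = 0.2095
NOMINAL_INCURRENT_CO2 = 0.0004

_GAS_COLUMNS = ["time_s", "channel", "fo2", "fco2", "wvp_kpa", "bp_kpa", "flow_ml_min"]


@dataclass
class GasTrace:
    """Raw multiplexed analyzer output.

    ``data`` columns: ``time_s`` (seconds, regular sampling), ``channel``
    (chamber id or ``baseline``), ``fo2``/``fco2`` (fractional
    concentrations), ``wvp_kpa`` (water vapour pressure), ``bp_kpa``
    (barometric pressure), ``flow_ml_min`` (metered excurrent flow).
    """

    data: pd.DataFrame
    start_time: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2020-01-01", tz="UTC"))

    def __post_init__(self) -> None:
        missing = set(_GAS_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        d = self.data
        for col in ("fo2", "fco2"):
            bad = (d[col] < 0) | (d[col] > 1)
            if bad.any():
                raise ValueError(f"{col} outside [0, 1] at {int(bad.sum())} rows")
        if (d["flow_ml_min"] <= 0).any():
            raise ValueError("flow must be positive")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, start_time=None) -> "GasTrace":
        df = pd.read_csv(path)
        kw = {} if start_time is None else {"start_time": pd.Timestamp(start_time)}
        return cls(df, **kw)


@dataclass
class ChamberSegment:
    """One chamber visit after washout discard."""

    channel: str
    cycle: int
    data: pd.DataFrame  # same columns as GasTrace.data
    switch_time_s: float


@dataclass
class MetabolicSeries:
    """Derived metabolic rates for one animal.

    ``data`` columns: ``time_s``, ``vo2_ml_h``, ``vco2_ml_h``, ``rer``,
    ``vo2_ml_g_h``, ``ee_kj_h``, plus a ``flagged`` boolean for samples
    whose computed VO2 was negative beyond noise tolerance.
    """

    data: pd.DataFrame
    body_mass_g: float | None = None
    start_time: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2020-01-01", tz="UTC"))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def split_and_discard(trace: GasTrace, discard_s: float = 30.0) -> list[ChamberSegment]:
    """Split a multiplexed trace at channel switches, dropping washout.

    The first ``discard_s`` seconds after every switch are removed because
    the analyzer cell is still flushing the previous channel's gas.  The
    channel dwell must exceed the discard or nothing would remain.
    """
    d = trace.data.reset_index(drop=True)
    ch = d["channel"].to_numpy()
    switch = np.r_[True, ch[1:] != ch[:-1]]
    run_id = np.cumsum(switch) - 1

    segments: list[ChamberSegment] = []
    cycle_count: dict[str, int] = {}
    for rid in range(run_id[-1] + 1 if len(d) else 0):
        run = d.loc[run_id == rid]
        t_switch = float(run["time_s"].iloc[0])
        dwell = float(run["time_s"].iloc[-1]) - t_switch
        if discard_s > 0 and dwell <= discard_s:
            raise ValueError(
                f"channel {run['channel'].iloc[0]!r} cycle at t={t_switch:.0f}s: "
                f"dwell {dwell:.0f}s does not exceed discard {discard_s:.0f}s"
            )
        kept = run.loc[run["time_s"] >= t_switch + discard_s]
        name = str(run["channel"].iloc[0])
        cyc = cycle_count.get(name, 0)
        cycle_count[name] = cyc + 1
        segments.append(ChamberSegment(name, cyc, kept.copy(), t_switch))
    return segments


def drift_correct(
    segments: list[ChamberSegment],
    spline_smoothing: float | None = None,
) -> list[ChamberSegment]:
    """Remove slow analyzer drift using the baseline channel.

    A cubic smoothing spline (lambda chosen by generalized cross-validation
    unless ``spline_smoothing`` is given) is fitted per gas to the baseline
    channel's deviation from the nominal incurrent composition, and the
    fitted drift is subtracted from every channel.  At least two baseline
    visits are required so the drift is identified across the animal
    segments rather than extrapolated from one anchor.
    """
    base = [s for s in segments if s.channel == BASELINE_CHANNEL]
    if len(base) < 2:
        raise ValueError(
            f"need >=2 baseline visits to identify drift, got {len(base)}"
        )
    t_base = np.concatenate([s.data["time_s"].to_numpy() for s in base])
    order = np.argsort(t_base)
    t_base = t_base[order]
    corrections = {}
    for col, nominal in (("fo2", NOMINAL_INCURRENT_O2), ("fco2", NOMINAL_INCURRENT_CO2)):
        dev = np.concatenate([s.data[col].to_numpy() for s in base])[order] - nominal
        t_fit, idx = np.unique(t_base, return_index=True)
        spl = make_smoothing_spline(t_fit, dev[idx], lam=spline_smoothing)
        corrections[col] = spl

    out: list[ChamberSegment] = []
    t_lo, t_hi = t_base[0], t_base[-1]
    for seg in segments:
        d = seg.data.copy()
        t = np.clip(d["time_s"].to_numpy(), t_lo, t_hi)  # no extrapolation
        for col, spl in corrections.items():
            d[col] = np.clip(d[col].to_numpy() - spl(t), 0.0, 1.0)
        out.append(ChamberSegment(seg.channel, seg.cycle, d, seg.switch_time_s))
    return out


def lag_align(
    o2_series: pd.Series,
    co2_series: pd.Series,
    max_lag_s: float = 60.0,
    sample_period_s: float = 1.0,
) -> tuple[pd.Series, float]:
    """Phase-match CO2 to O2 and return the shifted series with the lag.

    The lag is the arg-max of the cross-correlation between the negated
    first difference of O2 (consumption pulls fO2 down) and the first
    difference of CO2, searched within ``+/- max_lag_s``.  Flat series give
    an undefined lag; 0 is returned with a warning.  A true lag beyond the
    search window saturates at the window edge, with a warning.
    """
    o2 = np.asarray(o2_series, dtype=float)
    co2 = np.asarray(co2_series, dtype=float)
    n = min(o2.size, co2.size)
    max_lag = int(round(max_lag_s / sample_period_s))
    if n < 10 * max_lag:
        raise ValueError(
            f"overlap of {n} samples is below 10x the maximum lag window "
            f"({10 * max_lag} samples)"
        )
    do2 = -np.diff(o2[:n])
    dco2 = np.diff(co2[:n])
    if np.ptp(do2) == 0 or np.ptp(dco2) == 0:
        warnings.warn("flat series: lag undefined, returning 0", stacklevel=2)
        return co2_series.copy(), 0.0
    do2 = do2 - do2.mean()
    dco2 = dco2 - dco2.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    cc = np.array([np.dot(do2[max(0, -k):n - 1 - max(0, k)],
                          dco2[max(0, k):n - 1 - max(0, -k)]) for k in lags])
    best = int(lags[int(np.argmax(cc))])
    if abs(best) == max_lag:
        warnings.warn("lag estimate saturated at search-window edge", stacklevel=2)
    lag_s = best * sample_period_s
    shifted = pd.Series(np.asarray(co2_series, dtype=float)).shift(-best)
    shifted = shifted.ffill().bfill()
    shifted.index = co2_series.index
    return shifted, float(lag_s)


def dry_correct(f_measured, barometric, wvp):
    """Remove water-vapour dilution from a measured gas fraction.

    ``f_dry = f_measured * BP / (BP - WVP)`` with barometric pressure BP
    and water vapour pressure WVP in the same units.
    """
    bp = np.asarray(barometric, dtype=float)
    w = np.asarray(wvp, dtype=float)
    if np.any(w >= bp):
        raise ValueError("water vapour pressure must be below barometric pressure")
    return np.asarray(f_measured, dtype=float) * bp / (bp - w)


def compute_vo2_vco2(
    fi_o2,
    fi_co2,
    fe_o2,
    fe_co2,
    flow_ml_min,
    noise_tolerance_ml_h: float = 1.0,
):
    """Nitrogen-balance VO2/VCO2 for excurrent-metered (pull-mode) flow.

    With the flow meter downstream of the chamber, the metered flow is the
    excurrent one; the incurrent flow follows from nitrogen conservation:

        flow_in = flow_ex * (1 - FeO2 - FeCO2) / (1 - FiO2 - FiCO2)
        VO2  = flow_in * FiO2  - flow_ex * FeO2
        VCO2 = flow_ex * FeCO2 - flow_in * FiCO2

    All fractions are dry.  Rates are returned in ml/h.  Samples whose VO2
    is negative beyond ``noise_tolerance_ml_h`` are flagged, not clipped.

    Returns
    -------
    (vo2_ml_h, vco2_ml_h, rer, flagged)
    """
    fi_o2 = np.asarray(fi_o2, dtype=float)
    fi_co2 = np.asarray(fi_co2, dtype=float)
    fe_o2 = np.asarray(fe_o2, dtype=float)
    fe_co2 = np.asarray(fe_co2, dtype=float)
    flow = np.asarray(flow_ml_min, dtype=float)
    for name, f in (("FiO2", fi_o2), ("FiCO2", fi_co2), ("FeO2", fe_o2), ("FeCO2", fe_co2)):
        if np.any((f <= 0) | (f >= 1)):
            # CO2-free incurrent air is a legitimate configuration
            if name == "FiCO2" and np.all((f >= 0) & (f < 1)):
                continue
            raise ValueError(f"{name} must lie in (0, 1)")
    if np.any(flow <= 0):
        raise ValueError("flow must be positive")

    flow_in = flow * (1.0 - fe_o2 - fe_co2) / (1.0 - fi_o2 - fi_co2)
    vo2 = (flow_in * fi_o2 - flow * fe_o2) * 60.0
    vco2 = (flow * fe_co2 - flow_in * fi_co2) * 60.0
    flagged = vo2 < -noise_tolerance_ml_h
    with np.errstate(divide="ignore", invalid="ignore"):
        rer = np.where(vo2 > 0, vco2 / vo2, np.nan)
    return vo2, vco2, rer, flagged


def mass_specific_and_energy(
    series: pd.DataFrame,
    mass_before_g: float,
    mass_after_g: float,
    start_time: pd.Timestamp | None = None,
) -> MetabolicSeries:
    """Standardize VO2 by body mass and convert to energy expenditure.

    The body mass used is the mean of the pre- and post-experiment masses.
    Energy expenditure uses the caloric equivalent of oxygen
    (20.083 J per ml O2), giving kJ/h.
    """
    if mass_before_g <= 0 or mass_after_g <= 0:
        raise ValueError("body masses must be positive")
    mass = 0.5 * (mass_before_g + mass_after_g)
    d = series.copy()
    d["vo2_ml_g_h"] = d["vo2_ml_h"] / mass
    d["ee_kj_h"] = d["vo2_ml_h"] * OXYGEN_CALORIC_EQUIV_J_PER_ML / 1000.0
    kw = {} if start_time is None else {"start_time": start_time}
    return MetabolicSeries(d, body_mass_g=mass, **kw)


def recover_metabolic_rates(
    trace: GasTrace,
    discard_s: float = 30.0,
    max_lag_s: float = 60.0,
    spline_smoothing: float | None = None,
    apply_drift_correction: bool = True,
    apply_lag_alignment: bool = True,
) -> pd.DataFrame:
    """Full chain: multiplexed trace to per-sample VO2/VCO2 per chamber.

    Splits, drift-corrects, dry-corrects, phase-matches CO2, and applies
    the nitrogen-balance algebra with incurrent fractions interpolated
    from the (corrected) baseline channel.  Returns a tidy frame with
    columns ``time_s, channel, cycle, vo2_ml_h, vco2_ml_h, rer, flagged``.
    """
    segments = split_and_discard(trace, discard_s=discard_s)
    if apply_lag_alignment:
        d = trace.data
        dt_s = float(np.median(np.diff(np.unique(d["time_s"]))))
        _, lag = lag_align(d["fo2"], d["fco2"], max_lag_s=max_lag_s, sample_period_s=dt_s)
        if lag != 0:
            shift_rows = int(round(lag / dt_s))
            shifted = d["fco2"].shift(-shift_rows).ffill().bfill()
            trace = GasTrace(d.assign(fco2=shifted), start_time=trace.start_time)
            segments = split_and_discard(trace, discard_s=discard_s)
    if apply_drift_correction:
        segments = drift_correct(segments, spline_smoothing=spline_smoothing)

    base = [s for s in segments if s.channel == BASELINE_CHANNEL]
    if base:
        tb = np.concatenate([s.data["time_s"].to_numpy() for s in base])
        o2b = np.concatenate(
            [dry_correct(s.data["fo2"], s.data["bp_kpa"], s.data["wvp_kpa"]) for s in base]
        )
        co2b = np.concatenate(
            [dry_correct(s.data["fco2"], s.data["bp_kpa"], s.data["wvp_kpa"]) for s in base]
        )
        order = np.argsort(tb)
        tb, o2b, co2b = tb[order], o2b[order], co2b[order]
    else:
        tb = None

    frames = []
    for seg in segments:
        if seg.channel == BASELINE_CHANNEL:
            continue
        d = seg.data
        t = d["time_s"].to_numpy()
        fe_o2 = dry_correct(d["fo2"], d["bp_kpa"], d["wvp_kpa"])
        fe_co2 = dry_correct(d["fco2"], d["bp_kpa"], d["wvp_kpa"])
        if tb is not None:
            fi_o2 = np.interp(t, tb, o2b)
            fi_co2 = np.interp(t, tb, co2b)
        else:
            fi_o2 = np.full_like(t, NOMINAL_INCURRENT_O2)
            fi_co2 = np.full_like(t, NOMINAL_INCURRENT_CO2)
        vo2, vco2, rer, flagged = compute_vo2_vco2(
            fi_o2, fi_co2, fe_o2, fe_co2, d["flow_ml_min"].to_numpy()
        )
        frames.append(
            pd.DataFrame(
                {
                    "time_s": t,
                    "channel": seg.channel,
                    "cycle": seg.cycle,
                    "vo2_ml_h": vo2,
                    "vco2_ml_h": vco2,
                    "rer": rer,
                    "flagged": flagged,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["time_s", "channel", "cycle", "vo2_ml_h", "vco2_ml_h", "rer", "flagged"]
        )
    return pd.concat(frames, ignore_index=True).sort_values("time_s").reset_index(drop=True)
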