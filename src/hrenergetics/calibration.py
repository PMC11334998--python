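"""Per-individual heart-rate to oxygen-consumption calibration.

The heart-rate method estimates field energy expenditure by calibrating
each individual's oxygen consumption against its simultaneously recorded
heart rate in the laboratory, then applying the calibration to the field
heart-rate series.  Following standard practice for this method the
relationship is fitted as ordinary least squares of log(VO2) on log(HR)
(natural logs), per individual — metabolic scaling with heart rate is
close to a power law over the physiological range.

VO2 here is mass-specific (ml O2 g^-1 h^-1); body mass is re-multiplied
at prediction time, and the caloric equivalent of oxygen (20.083 J/ml)
converts to energy expenditure in kJ/h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .hrsignal import HeartRateSeries
from .respirometry import OXYGEN_CALORIC_EQUIV_J_PER_ML

__all__ = [
    "CalibrationModel",
    "pair_observations",
    "fit_calibration",
    "predict_ee",
    "validate_predictions",
    "models_to_csv",
    "models_from_csv",
]


@dataclass
class CalibrationModel:
    """One individual's log-log heart-rate/VO2 regression.

    ``intercept`` is in log(ml O2 g^-1 h^-1), ``slope`` per log(b.p.m.),
    both natural-log scale.  ``hr_range`` is the calibrated heart-rate
    span; predictions outside it are flagged as extrapolation.
    """

    bat_id: str
    intercept: float
    slope: float
    n: int
    r2: float
    residual_sd: float
    hr_range: tuple[float, float]
    intercept_ci: tuple[float, float] | None = None
    slope_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a calibration needs at least 3 pairs")
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must lie in [0, 1]")

    def predict_vo2(self, hr_bpm) -> np.ndarray:
        """Mass-specific VO2 (ml O2 g^-1 h^-1) at the given heart rate."""
        hr = np.asarray(hr_bpm, dtype=float)
        return np.exp(self.intercept + self.slope * np.log(hr))


def pair_observations(
    hr: HeartRateSeries,
    met: pd.DataFrame,
    window_s: float = 60.0,
    met_time_col: str = "timestamp",
    met_value_col: str = "vo2_ml_g_h",
    min_quality: float = 0.5,
) -> pd.DataFrame:
    """Time-align laboratory heart-rate and metabolic streams into pairs.

    Both streams are averaged over common half-open windows of
    ``window_s``; windows where the heart-rate series is gap-flagged or
    below ``min_quality``, or where a metabolic sample is flagged, are
    excluded.  Returns a frame with ``window``, ``hr_bpm``,
    ``vo2_ml_g_h`` — one row per usable window.
    """
    step = pd.Timedelta(seconds=window_s)
    hdf = hr.data.copy()
    hdf["window"] = hdf["timestamp"].dt.floor(step)
    ok = (~hr.is_gap) & (hr.quality >= min_quality)
    hr_win = hdf.loc[ok].groupby("window")["hr_bpm"].mean()

    mdf = met.copy()
    mdf[met_time_col] = pd.to_datetime(mdf[met_time_col], utc=True)
    if "flagged" in mdf.columns:
        mdf = mdf.loc[~mdf["flagged"].astype(bool)]
    mdf["window"] = mdf[met_time_col].dt.floor(step)
    met_win = mdf.groupby("window")[met_value_col].mean()

    pairs = pd.concat([hr_win, met_win], axis=1, join="inner").reset_index()
    pairs.columns = ["window", "hr_bpm", "vo2_ml_g_h"]
    if pairs.empty:
        warnings.warn("no overlapping windows between HR and metabolic streams", stacklevel=2)
    return pairs


def fit_calibration(pairs: pd.DataFrame, bat_id: str = "bat") -> CalibrationModel:
    """OLS fit of log(VO2) on log(HR) for one individual.

    Requires at least three pairs of strictly positive values and a
    non-degenerate heart-rate design (at least two distinct rates).
    """
    if len(pairs) < 3:
        raise ValueError(f"{bat_id}: need >=3 pairs, got {len(pairs)}")
    hr = pairs["hr_bpm"].to_numpy(dtype=float)
    vo2 = pairs["vo2_ml_g_h"].to_numpy(dtype=float)
    bad = (hr <= 0) | (vo2 <= 0) | ~np.isfinite(hr) | ~np.isfinite(vo2)
    if bad.any():
        raise ValueError(
            f"{bat_id}: non-positive or non-finite values at rows {np.flatnonzero(bad).tolist()}"
        )
    x = np.log(hr)
    if np.ptp(x) == 0:
        raise ValueError(f"{bat_id}: rank-deficient design (all heart rates equal)")
    res = sm.OLS(np.log(vo2), sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return CalibrationModel(
        bat_id=bat_id,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        n=int(res.nobs),
        r2=float(np.clip(res.rsquared, 0.0, 1.0)),
        residual_sd=float(np.sqrt(res.scale)),
        hr_range=(float(hr.min()), float(hr.max())),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
    )


def predict_ee(
    model: CalibrationModel,
    hr: HeartRateSeries,
    body_mass_g: float,
) -> pd.DataFrame:
    """Field energy expenditure from heart rate via the calibration.

    Per window: ``VO2 = exp(a + b log HR)`` (ml O2 g^-1 h^-1), multiplied
    by body mass and the caloric equivalent of oxygen to kJ/h.  Gap
    windows propagate as NaN; windows outside the calibrated heart-rate
    range are predicted but flagged ``extrapolated``.
    """
    if body_mass_g <= 0:
        raise ValueError("body mass must be positive")
    df = hr.data.copy()
    hr_vals = df["hr_bpm"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        vo2 = model.predict_vo2(np.where(hr_vals > 0, hr_vals, np.nan))
    ee = vo2 * body_mass_g * OXYGEN_CALORIC_EQUIV_J_PER_ML / 1000.0
    lo, hi = model.hr_range
    extrapolated = ((hr_vals < lo) | (hr_vals > hi)) & np.isfinite(hr_vals)
    out = pd.DataFrame(
        {
            "timestamp": df["timestamp"],
            "hr_bpm": hr_vals,
            "vo2_ml_g_h": vo2,
            "ee_kj_h": ee,
            "source": df["source"],
            "extrapolated": extrapolated,
        }
    )
    out.loc[df["source"] == "gap", ["vo2_ml_g_h", "ee_kj_h"]] = np.nan
    return out


def validate_predictions(predicted, observed) -> float:
    """Pooled coefficient of determination of predictions vs observations.

    ``r2 = 1 - SS_res / SS_tot`` on the supplied (held-out) pairs, pooled
    across individuals; predictions identical to the observations give 1,
    predicting the observed mean gives 0.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    mask = np.isfinite(p) & np.isfinite(o)
    p, o = p[mask], o[mask]
    if o.size < 2:
        raise ValueError("need at least 2 finite pairs")
    ss_res = float(np.sum((o - p) ** 2))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def models_to_csv(models: list[CalibrationModel], path) -> None:
    """Persist fitted calibrations, one CSV row per individual."""
    pd.DataFrame(
        [
            {
                "bat_id": m.bat_id,
                "intercept": m.intercept,
                "slope": m.slope,
                "n": m.n,
                "r2": m.r2,
                "residual_sd": m.residual_sd,
                "hr_range_min": m.hr_range[0],
                "hr_range_max": m.hr_range[1],
            }
            for m in models
        ]
    ).to_csv(path, index=False)


def models_from_csv(path) -> list[CalibrationModel]:
    df = pd.read_csv(path)
    return [
        CalibrationModel(
            bat_id=str(r.bat_id),
            intercept=float(r.intercept),
            slope=float(r.slope),
            n=int(r.n),
            r2=float(r.r2),
            residual_sd=float(r.residual_sd),
            hr_range=(float(r.hr_range_min), float(r.hr_range_max)),
        )
        for r in df.itertuples()
    ]
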