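"""CPET summary indexes characterizing each recording and phenogroup.

Peak VO2 and the end-tidal pressures are taken as the highest of the
last three consecutive 30-second interval averages (windows anchored at
test end); peak HR, VE, RER and load are plain recording maxima.  The
O2 pulse is peak VO2 over peak HR, the ventilatory-efficiency slope is
the OLS slope of VE on VCO2 up to the respiratory compensation point
(VT2), and VT2 itself is located on the smoothed VE/VCO2
ventilatory-equivalent curve as the first sustained rise after its
minimum.  Percent-predicted values use a pluggable equation table
(defaults: HR 220 - age; VO2 by the Hansen/Wasserman cycle equations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .preprocessing import moving_average
from .records import CleanRecording, Participant


@dataclass
class SummaryMetrics:
    id: str
    peak_load: float
    peak_VO2: float
    peak_HR: float
    peak_VE: float
    peak_RER: float
    peak_PETO2: float
    peak_PETCO2: float
    O2_pulse: float
    peak_VO2_per_kg: float | None
    O2_pulse_per_kg: float | None
    VE_VCO2_slope: float | None
    VT2_index: int | None
    pct_pred_HR: float | None
    pct_pred_VO2: float | None
    rest_values: dict[str, float]


def _hr_predicted(p: Participant) -> float:
    return 220.0 - p.age


def _vo2_predicted(p: Participant) -> float | None:
    """Hansen/Wasserman cycle-ergometry peak-VO2 prediction, mL/min."""
    if p.weight is None:
        return None
    if p.sex == "male":
        return p.weight * (50.72 - 0.372 * p.age)
    return (p.weight + 43.0) * (22.78 - 0.17 * p.age)


DEFAULT_PREDICTION_EQUATIONS: dict[str, Callable] = {
    "HR": _hr_predicted,
    "VO2": _vo2_predicted,
}


def interval_averages(
    series: np.ndarray, t: np.ndarray, interval_s: float = 30.0
) -> list[float]:
    """Window means over consecutive intervals anchored at test end.

    The last window covers ``(t_end - interval, t_end]``, the one before
    ``(t_end - 2*interval, t_end - interval]`` and so on; the earliest
    window may be partial.  Returned in chronological order.
    """
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    x = np.asarray(series, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time axis must be strictly increasing")
    t_end = t[-1]
    if t_end - t[0] <= interval_s:
        return [float(x.mean())]
    means: list[float] = []
    hi = t_end
    while hi > t[0]:
        lo = hi - interval_s
        mask = (t > lo) & (t <= hi)
        if lo <= t[0]:  # earliest (possibly partial) window includes t[0]
            mask |= t == t[0]
        if mask.any():
            means.append(float(x[mask].mean()))
        hi = lo
    means.reverse()
    return means


def peak_by_last3(series: np.ndarray, t: np.ndarray) -> float:
    """Highest of the last three consecutive 30-s interval averages.

    Recordings shorter than three windows fall back to the maximum of
    the available window means.
    """
    means = interval_averages(series, t, 30.0)
    return float(max(means[-3:]))


def detect_vt2(
    ve: np.ndarray,
    vco2: np.ndarray,
    t: np.ndarray,
    smooth_window: int = 5,
) -> int | None:
    """Respiratory compensation point by the ventilatory-equivalent method.

    The VE/VCO2 ratio falls early in exercise, flattens, and rises again
    once ventilation outpaces CO2 output.  The ratio is smoothed, its
    minimum located, and VT2 is the first index after the minimum from
    which the smoothed ratio is non-decreasing over the following
    ``smooth_window`` samples.  Returns ``None`` when no sustained rise
    exists (no compensation point reached).
    """
    ve = np.asarray(ve, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    valid = vco2 > 0
    if not valid.all():
        # exclude nonpositive VCO2 samples from the ratio
        idx_map = np.flatnonzero(valid)
        ve, vco2 = ve[valid], vco2[valid]
    else:
        idx_map = np.arange(len(ve))
    if len(ve) < 2 * smooth_window + 1:
        return None
    ratio = ve / vco2
    w = smooth_window if smooth_window % 2 == 1 else smooth_window + 1
    smoothed = moving_average(ratio, max(3, w))
    m = int(np.argmin(smoothed))
    n = len(smoothed)
    for i in range(m, n - smooth_window):
        window = smoothed[i : i + smooth_window + 1]
        if np.all(np.diff(window) >= 0) and smoothed[-1] > smoothed[m]:
            return int(idx_map[i])
    return None


def ve_vco2_slope(
    ve: np.ndarray, vco2: np.ndarray, vt2_index: int | None
) -> float | None:
    """OLS slope of VE on VCO2 up to (and including) VT2.

    With no detected VT2 the whole recording is used.  Returns ``None``
    for degenerate (zero-variance) VCO2.
    """
    ve = np.asarray(ve, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    stop = len(ve) if vt2_index is None else vt2_index + 1
    x, y = vco2[:stop], ve[:stop]
    if len(x) < 3 or np.ptp(x) == 0:
        return None
    return float(stats.linregress(x, y).slope)


def compute_summary(
    rec: CleanRecording,
    participant: Participant | None = None,
    prediction_equations: dict[str, Callable] | None = None,
    vt2_smooth_window: int = 5,
) -> SummaryMetrics:
    """All summary indexes of one cleaned recording.

    Anthropometric-dependent fields (per-kg ratios, percent-predicted)
    are ``None`` when the participant record is absent or incomplete.
    """
    eqs = prediction_equations or DEFAULT_PREDICTION_EQUATIONS
    v = rec.values
    t = rec.t
    peak_vo2 = peak_by_last3(v["VO2"], t)
    peak_hr = float(np.max(v["HR"]))
    o2_pulse = peak_vo2 / peak_hr

    vt2 = slope = None
    if "VE" in v and "VCO2" in v:
        vt2 = detect_vt2(v["VE"], v["VCO2"], t, vt2_smooth_window)
        slope = ve_vco2_slope(v["VE"], v["VCO2"], vt2)

    weight = participant.weight if participant else None
    pct_hr = pct_vo2 = None
    if participant is not None:
        hr_pred = eqs["HR"](participant)
        if hr_pred:
            pct_hr = 100.0 * peak_hr / hr_pred
        vo2_pred = eqs["VO2"](participant)
        if vo2_pred:
            pct_vo2 = 100.0 * peak_vo2 / vo2_pred

    rest = {ch: float(np.mean(v[ch][:3])) for ch in rec.channels}
    return SummaryMetrics(
        id=rec.id,
        peak_load=float(np.max(v["load"])) if "load" in v else float("nan"),
        peak_VO2=peak_vo2,
        peak_HR=peak_hr,
        peak_VE=float(np.max(v["VE"])) if "VE" in v else float("nan"),
        peak_RER=float(np.max(v["RER"])),
        peak_PETO2=peak_by_last3(v["PETO2"], t),
        peak_PETCO2=peak_by_last3(v["PETCO2"], t),
        O2_pulse=o2_pulse,
        peak_VO2_per_kg=peak_vo2 / weight if weight else None,
        O2_pulse_per_kg=o2_pulse / weight if weight else None,
        VE_VCO2_slope=slope,
        VT2_index=vt2,
        pct_pred_HR=pct_hr,
        pct_pred_VO2=pct_vo2,
        rest_values=rest,
    )
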