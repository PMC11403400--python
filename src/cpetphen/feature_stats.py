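"""Stationarity and correlation diagnostics of the CPET channel set.

CPET channels trend strongly during a ramp test, so correlation measures
are computed on stationarized (repeatedly differenced) series: each
channel is first-differenced until an Augmented Dickey-Fuller test
rejects the unit-root null.  The cohort-level diagnostics — an 8x8
temporal cross-correlation grid over lags and a Spearman rank matrix at
lag zero — are what motivates clustering on the reduced channel set
{HR, VO2, RER, PETO2, PETCO2}: VO2, VCO2, VE and load are mutually
near-redundant at lag zero, and PETO2/PETCO2 are strongly negatively
coupled.  The channel selection itself stays a configuration default;
this module only reports the evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import adfuller

from .records import CHANNELS, CleanRecording


@dataclass
class StationarityResult:
    d: int  # differencing order applied
    p_value_final: float
    series_out: np.ndarray
    stationary: bool
    degenerate: bool = False  # constant input


@dataclass
class CorrelationGrid:
    channels: tuple[str, ...]
    lags: np.ndarray  # -max_lag ... max_lag
    grid: np.ndarray  # (n_ch, n_ch, n_lags) cohort-averaged
    spearman: np.ndarray  # (n_ch, n_ch) at lag 0
    n_recordings_used: int = 0
    excluded: list[str] = field(default_factory=list)


def adf_stationarize(
    series: np.ndarray, alpha: float = 0.05, max_d: int = 3
) -> StationarityResult:
    """Difference a series until the ADF unit-root null is rejected.

    The ADF regression includes a constant with automatic (AIC) lag
    selection.  A constant series has no unit root to test and is
    returned unchanged, flagged degenerate.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    x = np.asarray(series, dtype=float)
    if x.size < 12:
        raise ValueError("series too short for a meaningful ADF fit")
    if np.allclose(x, x[0]):
        return StationarityResult(
            d=0, p_value_final=0.0, series_out=x.copy(),
            stationary=True, degenerate=True,
        )
    d = 0
    while True:
        if np.allclose(x, x[0]):  # differencing produced a constant
            return StationarityResult(
                d=d, p_value_final=0.0, series_out=x.copy(),
                stationary=True, degenerate=True,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(adfuller(x, regression="c", autolag="AIC")[1])
        if p < alpha or d >= max_d:
            return StationarityResult(
                d=d, p_value_final=p, series_out=x.copy(),
                stationary=p < alpha,
            )
        x = np.diff(x)
        d += 1


def stationarize_recording(
    rec: CleanRecording,
    channels: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    max_d: int = 3,
) -> dict[str, np.ndarray]:
    """Difference all channels of a recording to a common order.

    Channels must stay time-aligned for cross-correlation, so every
    channel is differenced to the maximum order any channel required.
    """
    channels = channels or rec.channels
    orders = {
        ch: adf_stationarize(rec.values[ch], alpha, max_d).d for ch in channels
    }
    d = max(orders.values()) if orders else 0
    return {ch: np.diff(rec.values[ch], n=d) for ch in channels}


def _norm_xcorr(x: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized cross-correlation of de-meaned series over +/- max_lag."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    out = np.zeros(2 * max_lag + 1)
    if denom == 0:
        return out
    n = len(xc)
    for k, lag in enumerate(range(-max_lag, max_lag + 1)):
        if lag >= 0:
            out[k] = np.sum(xc[: n - lag] * yc[lag:]) / denom
        else:
            out[k] = np.sum(xc[-lag:] * yc[: n + lag]) / denom
    return out


def temporal_cross_correlation(
    cohort: list[CleanRecording],
    channels: tuple[str, ...] = CHANNELS,
    max_lag: int = 30,
    alpha: float = 0.05,
    max_d: int = 3,
) -> CorrelationGrid:
    """Cohort-averaged cross-correlation grid over time lags.

    Per recording the channels are stationarized to a common differencing
    order, then every channel pair's normalized cross-correlation is
    computed over lags ``-max_lag..max_lag``; the cohort grid is the
    unweighted mean over recordings.  Recordings too short for the lag
    range are excluded and listed.
    """
    n_ch = len(channels)
    lags = np.arange(-max_lag, max_lag + 1)
    acc = np.zeros((n_ch, n_ch, len(lags)))
    used = 0
    excluded: list[str] = []
    pooled: list[np.ndarray] = []
    for rec in cohort:
        stat = stationarize_recording(rec, channels, alpha, max_d)
        length = len(next(iter(stat.values())))
        if length < max_lag + 2:
            excluded.append(rec.id)
            continue
        for a in range(n_ch):
            for b in range(a, n_ch):
                cc = _norm_xcorr(stat[channels[a]], stat[channels[b]], max_lag)
                acc[a, b] += cc
                if a != b:
                    acc[b, a] += cc[::-1]  # c_yx(lag) = c_xy(-lag)
        pooled.append(np.column_stack([stat[ch] for ch in channels]))
        used += 1
    if used == 0:
        raise ValueError("no recording long enough for the requested max_lag")
    grid = acc / used

    spearman = spearman_matrix_from_samples(np.vstack(pooled))
    return CorrelationGrid(
        channels=tuple(channels),
        lags=lags,
        grid=grid,
        spearman=spearman,
        n_recordings_used=used,
        excluded=excluded,
    )


def spearman_matrix_from_samples(samples: np.ndarray) -> np.ndarray:
    """Spearman rank-correlation matrix of pooled samples (rows)."""
    n_ch = samples.shape[1]
    if n_ch == 1:
        return np.ones((1, 1))
    rho = stats.spearmanr(samples).statistic
    if np.isscalar(rho) or np.ndim(rho) == 0:  # two-channel case
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    # constant channels yield NaN off-diagonals: reported as missing
    np.fill_diagonal(rho, 1.0)
    return rho


def spearman_matrix(
    cohort: list[CleanRecording],
    channels: tuple[str, ...] = CHANNELS,
    alpha: float = 0.05,
    max_d: int = 3,
) -> np.ndarray:
    """Rank correlation pooled over all samples of all recordings."""
    pooled = [
        np.column_stack(
            [stationarize_recording(r, channels, alpha, max_d)[ch] for ch in channels]
        )
        for r in cohort
    ]
    return spearman_matrix_from_samples(np.vstack(pooled))
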