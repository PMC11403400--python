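"""Distinctive-region extraction: which part of the curves drives assignment.

For each cluster, the cohort is split into the in-cluster recordings
(subset 1) and everything else (subset 2).  Each subset-1 recording's
per-sample DTW distance to subset 2 highlights where along the test it
differs most; the top-q-quantile samples are kept, votes are pooled on a
normalized time axis, and bins supported by at least a frequency
threshold of subset 1 are merged into contiguous distinctive regions.

The per-sample DTW distance is defined here as the mean local cost over
all warping-path cells touching a given sample of the query recording —
a decomposition whose multiplicity-weighted sum reconstructs the total
DTW distance exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dtw import DtwConfig, _as_2d, dtw_path


@dataclass(frozen=True)
class InterpretConfig:
    q: float = 0.5  # quantile of per-bin distance kept per recording
    freq_threshold: float = 0.5  # fraction of subset 1 that must vote
    min_run: int = 2  # minimum contiguous bins per region
    time_axis_bins: int = 100  # normalized-time pooling resolution

    def __post_init__(self) -> None:
        if not 0.0 <= self.q < 1.0:
            raise ValueError("q must be in [0, 1)")
        if not 0.0 < self.freq_threshold <= 1.0:
            raise ValueError("freq_threshold must be in (0, 1]")
        if self.min_run < 1 or self.time_axis_bins < 1:
            raise ValueError("min_run and time_axis_bins must be >= 1")


@dataclass
class DistinctiveRegion:
    """Contiguous distinctive segments of one cluster's curves."""

    cluster: int
    segments: list[tuple[int, int]]  # half-open [start_bin, end_bin)
    support: list[float]  # per-segment mean voting fraction
    time_axis_bins: int = 100

    def segments_normalized(self) -> list[tuple[float, float]]:
        b = self.time_axis_bins
        return [(s / b, e / b) for s, e in self.segments]


def per_sample_distance(
    a: np.ndarray, b: np.ndarray, config: DtwConfig | None = None
) -> np.ndarray:
    """Per-sample decomposition of the DTW distance from ``a``'s side.

    Sample ``t`` of ``a`` receives the mean local cost over all optimal-
    path cells whose ``a``-index is ``t``.  The multiplicity-weighted sum
    of the vector equals ``dtw_distance(a, b)``.
    """
    a2, b2 = _as_2d(a), _as_2d(b)
    path = dtw_path(a2, b2, config)
    total = np.zeros(a2.shape[0])
    count = np.zeros(a2.shape[0])
    for i, j in path:
        total[i] += float(np.sum((a2[i] - b2[j]) ** 2))
        count[i] += 1
    return total / count  # every a-index is on the path at least once


def _bin_profile(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Average a per-sample profile into normalized-time bins.

    Sample ``i`` of an ``n``-sample recording maps to bin
    ``floor(i / n * n_bins)``; empty bins (recordings shorter than the
    bin axis) inherit the nearest filled bin to the left.
    """
    n = len(values)
    bins = np.minimum((np.arange(n) * n_bins) // n, n_bins - 1)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        mask = bins == b
        if mask.any():
            out[b] = values[mask].mean()
    # forward/backward fill for bins no sample landed in
    last = np.nan
    for b in range(n_bins):
        if np.isnan(out[b]):
            out[b] = last
        else:
            last = out[b]
    last = np.nan
    for b in range(n_bins - 1, -1, -1):
        if np.isnan(out[b]):
            out[b] = last
        else:
            last = out[b]
    return out


def distinctive_timestamps(
    a: np.ndarray,
    others: list[np.ndarray],
    q: float = 0.5,
    config: DtwConfig | None = None,
    time_axis_bins: int = 100,
) -> set[int]:
    """Normalized-time bins where ``a`` differs most from ``others``.

    Averages the per-sample DTW distance of ``a`` against every
    out-of-cluster recording, pools it on the normalized time axis, and
    retains the bins at or above the recording's own q-quantile (ties at
    the quantile included, so ``q = 0`` keeps every bin).
    """
    if not others:
        raise ValueError("subset 2 must be non-empty")
    profile = np.mean(
        [per_sample_distance(a, b, config) for b in others], axis=0
    )
    binned = _bin_profile(profile, time_axis_bins)
    threshold = float(np.quantile(binned, q))
    return set(np.flatnonzero(binned >= threshold).tolist())


def extract_regions(
    cluster_recordings: list[np.ndarray],
    others: list[np.ndarray],
    cluster: int = 0,
    interpret: InterpretConfig | None = None,
    dtw: DtwConfig | None = None,
) -> DistinctiveRegion:
    """Distinctive contiguous regions of one cluster versus the rest.

    A bin survives when it is distinctive for at least ``freq_threshold``
    of the in-cluster recordings; surviving bins are merged into maximal
    consecutive runs and runs shorter than ``min_run`` are dropped.
    An empty segment list is a valid outcome (no distinctive signal).
    """
    cfg = interpret or InterpretConfig()
    if not cluster_recordings or not others:
        raise ValueError("both subsets must be non-empty")
    votes = np.zeros(cfg.time_axis_bins)
    for a in cluster_recordings:
        bins = distinctive_timestamps(
            a, others, cfg.q, dtw, cfg.time_axis_bins
        )
        for b in bins:
            votes[b] += 1
    frac = votes / len(cluster_recordings)
    surviving = frac >= cfg.freq_threshold

    segments: list[tuple[int, int]] = []
    support: list[float] = []
    start = None
    for b in range(cfg.time_axis_bins + 1):
        on = b < cfg.time_axis_bins and surviving[b]
        if on and start is None:
            start = b
        elif not on and start is not None:
            if b - start >= cfg.min_run:
                segments.append((start, b))
                support.append(float(frac[start:b].mean()))
            start = None
    return DistinctiveRegion(
        cluster=cluster,
        segments=segments,
        support=support,
        time_axis_bins=cfg.time_axis_bins,
    )


def extract_all_regions(
    scaled_series: list[np.ndarray],
    labels: list[int],
    interpret: InterpretConfig | None = None,
    dtw: DtwConfig | None = None,
) -> dict[int, DistinctiveRegion]:
    """Iterate region extraction with every cluster as the investigated group."""
    labels_arr = np.asarray(labels)
    out: dict[int, DistinctiveRegion] = {}
    for g in np.unique(labels_arr):
        inside = [s for s, l in zip(scaled_series, labels_arr) if l == g]
        outside = [s for s, l in zip(scaled_series, labels_arr) if l != g]
        out[int(g)] = extract_regions(
            inside, outside, cluster=int(g), interpret=interpret, dtw=dtw
        )
    return out


def overlap_coefficient(
    segments: list[tuple[float, float]], window: tuple[float, float]
) -> float:
    """Overlap of extracted segments with a reference window.

    Intersection length divided by the smaller of (total segment length,
    window length); zero when no segments exist.
    """
    total = sum(e - s for s, e in segments)
    if total <= 0:
        return 0.0
    inter = sum(
        max(0.0, min(e, window[1]) - max(s, window[0])) for s, e in segments
    )
    return inter / min(total, window[1] - window[0])
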