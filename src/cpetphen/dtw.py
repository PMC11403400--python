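"""Dynamic time warping for multichannel breath-by-breath series.

DTW aligns two series of possibly different length by a monotone,
contiguous warping path and sums a local cost over the aligned sample
pairs.  Here the local cost is the squared Euclidean distance between the
channel vectors of the two aligned samples ("dependent" multivariate DTW:
one shared path for all channels).  The reported distance is the total
local cost along the optimal path — this additive form is what the
per-sample decomposition in :mod:`cpetphen.interpretability` reconstructs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # noqa: D103
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@dataclass(frozen=True)
class DtwConfig:
    """Configuration of the DTW distance.

    Parameters
    ----------
    variant : {"dependent", "independent"}
        ``dependent`` uses one warping path over the joint channel vector;
        ``independent`` sums single-channel DTW distances.
    band : int or None
        Optional Sakoe–Chiba radius on ``|i - j|``.  Must be at least the
        length difference of the two series, otherwise no complete path
        exists.  ``None`` (default) disables the constraint.
    """

    variant: str = "dependent"
    band: int | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("dependent", "independent"):
            raise ValueError(f"unknown DTW variant: {self.variant!r}")
        if self.band is not None and self.band < 0:
            raise ValueError("band radius must be non-negative")


def _as_2d(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("series must be 1-D or 2-D (n_samples, n_channels)")
    if arr.shape[0] == 0:
        raise ValueError("empty series")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    return arr


def _validate_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a2, b2 = _as_2d(a), _as_2d(b)
    if a2.shape[1] != b2.shape[1]:
        raise ValueError(
            f"channel mismatch: {a2.shape[1]} vs {b2.shape[1]} channels"
        )
    return a2, b2


@njit(cache=True)
def _accumulated_cost(a, b, band):  # pragma: no cover - numba kernel
    n, m = a.shape[0], b.shape[0]
    d = a.shape[1]
    acc = np.full((n, m), np.inf)
    for i in range(n):
        j_lo, j_hi = 0, m
        if band >= 0:
            j_lo = max(0, i - band)
            j_hi = min(m, i + band + 1)
        for j in range(j_lo, j_hi):
            cost = 0.0
            for c in range(d):
                diff = a[i, c] - b[j, c]
                cost += diff * diff
            if i == 0 and j == 0:
                acc[i, j] = cost
            elif i == 0:
                acc[i, j] = cost + acc[i, j - 1]
            elif j == 0:
                acc[i, j] = cost + acc[i - 1, j]
            else:
                best = acc[i - 1, j - 1]
                if acc[i - 1, j] < best:
                    best = acc[i - 1, j]
                if acc[i, j - 1] < best:
                    best = acc[i, j - 1]
                acc[i, j] = cost + best
    return acc


def _band_value(config: DtwConfig, n: int, m: int) -> int:
    if config.band is None:
        return -1
    if config.band < abs(n - m):
        raise ValueError(
            f"band {config.band} smaller than length difference {abs(n - m)}"
        )
    return config.band


def dtw_distance(a, b, config: DtwConfig | None = None) -> float:
    """Total local cost of the optimal warping path between ``a`` and ``b``.

    Symmetric and non-negative; zero exactly when the two series are
    identical after collapsing immediate repetitions onto each other
    (in practice: zero iff ``a == b`` for generic real-valued data).
    """
    config = config or DtwConfig()
    a2, b2 = _validate_pair(a, b)
    if config.variant == "independent":
        dep = DtwConfig(variant="dependent", band=config.band)
        return float(
            sum(
                dtw_distance(a2[:, c], b2[:, c], dep)
                for c in range(a2.shape[1])
            )
        )
    band = _band_value(config, a2.shape[0], b2.shape[0])
    acc = _accumulated_cost(a2, b2, band)
    return float(acc[-1, -1])


def dtw_path(a, b, config: DtwConfig | None = None) -> list[tuple[int, int]]:
    """Optimal warping path as index pairs from ``(0, 0)`` to the corner.

    Ties in the backtracking prefer the diagonal step, then the step that
    advances ``a``.
    """
    config = config or DtwConfig()
    if config.variant != "dependent":
        raise ValueError("warping paths are defined for the dependent variant")
    a2, b2 = _validate_pair(a, b)
    band = _band_value(config, a2.shape[0], b2.shape[0])
    acc = _accumulated_cost(a2, b2, band)
    i, j = a2.shape[0] - 1, b2.shape[0] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            candidates = (
                (acc[i - 1, j - 1], i - 1, j - 1),
                (acc[i - 1, j], i - 1, j),
                (acc[i, j - 1], i, j - 1),
            )
            _, i, j = min(candidates, key=lambda t: t[0])
        path.append((i, j))
    path.reverse()
    return path


def path_cost(a, b, path) -> float:
    """Summed local cost along an explicit path (diagnostic helper)."""
    a2, b2 = _validate_pair(a, b)
    return float(
        sum(np.sum((a2[i] - b2[j]) ** 2) for i, j in path)
    )


def distance_matrix(
    series: list, config: DtwConfig | None = None
) -> np.ndarray:
    """Symmetric pairwise DTW distance matrix with a zero diagonal."""
    config = config or DtwConfig()
    n = len(series)
    arrays = [_as_2d(s) for s in series]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(arrays[i], arrays[j], config)
    return D
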