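"""Breath-by-breath signal cleaning cascade.

Raw CPET exports contain invalid tokens (mask leaks, dropped breaths) and
spike artefacts from movement.  The cascade is:

1. token sanitation — invalid cells ("-", ">>", unparsable) become 0;
2. correction of the zeroed cells from their two predecessors:
   ``corrected_t = x_{t-1} + 0.5 * |x_{t-1} - x_{t-2}|``,
   applied left to right so chained invalid cells use already-corrected
   predecessors; a zeroed cell at t < 2 is back-filled from the first
   subsequent valid cell (the formula has no predecessors there);
3. quality checks — the load ramp must be non-decreasing (optionally
   repaired by isotonic regression) and the recording must exceed a
   minimum duration, else the recording is rejected;
4. a local-statistics despike filter: a sample outside mu +/- sigma of
   its four surrounding neighbours is replaced by the mean of its two
   immediate neighbours;
5. an 11-sample centred moving average if the recording has at least 30
   samples, otherwise a second pass of the local filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .records import CleanRecording, RawRecording

_INVALID_TOKENS = {"-", ">>", ""}


@dataclass(frozen=True)
class PreprocessConfig:
    min_duration_samples: int = 10  # reject if n_samples <= this
    ma_threshold_samples: int = 30  # moving average needs at least this
    ma_window: int = 11
    neighbor_halfwidth: int = 2
    sigma_multiplier: float = 1.0
    repair_load: bool = False  # isotonic repair instead of rejection

    def __post_init__(self) -> None:
        if self.ma_window < 3 or self.ma_window % 2 == 0:
            raise ValueError("ma_window must be odd and >= 3")
        if self.neighbor_halfwidth < 1:
            raise ValueError("neighbor_halfwidth must be >= 1")


@dataclass
class Rejection:
    """Typed rejection outcome of the cleaning cascade."""

    id: str
    reason: str  # "min_duration" | "load_not_monotone"
    detail: dict = field(default_factory=dict)


def sanitize_tokens(tokens: list[str]) -> tuple[np.ndarray, set[int]]:
    """Parse device tokens to floats; invalid cells become 0 and are logged."""
    values = np.zeros(len(tokens))
    zeroed: set[int] = set()
    for i, tok in enumerate(tokens):
        s = str(tok).strip()
        if s in _INVALID_TOKENS:
            zeroed.add(i)
            continue
        try:
            v = float(s)
        except ValueError:
            zeroed.add(i)
            continue
        if not np.isfinite(v):
            zeroed.add(i)
        else:
            values[i] = v
    return values, zeroed


def correct_zeroed(
    series: np.ndarray, zeroed: set[int]
) -> tuple[np.ndarray, list[int]]:
    """Replace zeroed cells from their two predecessors.

    Cells at index >= 2 get ``x_{t-1} + 0.5 * |x_{t-1} - x_{t-2}|``,
    in increasing index order (chains use corrected values).  The formula
    always extrapolates upward by half the last step, even on decreasing
    trends; this is deliberate and documented.  Returns the corrected
    series and the list of leading-edge indices (t < 2) that had to be
    back-filled from the first subsequent valid value instead.
    """
    x = np.asarray(series, dtype=float).copy()
    leading = sorted(i for i in zeroed if i < 2)
    if leading:
        valid_after = [i for i in range(len(x)) if i not in zeroed]
        if valid_after:
            fill = x[valid_after[0]]
        else:  # nothing valid at all; leave zeros
            fill = 0.0
        for i in leading:
            x[i] = fill
    for t in sorted(i for i in zeroed if i >= 2):
        x[t] = x[t - 1] + 0.5 * abs(x[t - 1] - x[t - 2])
    return x, leading


def check_load_monotone(load: np.ndarray) -> bool:
    """True iff the load ramp never decreases."""
    load = np.asarray(load, dtype=float)
    if load.size == 0:
        raise ValueError("missing load channel")
    return bool(np.all(np.diff(load) >= 0))


def repair_load_isotonic(load: np.ndarray) -> np.ndarray:
    """Closest (least-squares) non-decreasing sequence to the load series."""
    load = np.asarray(load, dtype=float)
    iso = IsotonicRegression(increasing=True)
    return iso.fit_transform(np.arange(load.size), load)


def local_stats_filter(
    series: np.ndarray,
    neighbor_halfwidth: int = 2,
    sigma_multiplier: float = 1.0,
) -> tuple[np.ndarray, set[int]]:
    """Replace samples outside the mu +/- sigma band of their neighbours.

    For each interior sample, mu and sigma (population SD) are computed
    over the ``halfwidth`` samples before and after it, excluding the
    sample itself.  Out-of-band samples are replaced by the mean of the
    immediately preceding and following sample.  All statistics and
    replacements read the *original* series (single pass); edge samples
    with incomplete neighbourhoods are left untouched.
    """
    x = np.asarray(series, dtype=float)
    h = neighbor_halfwidth
    if x.size < 2 * h + 1:
        return x.copy(), set()
    out = x.copy()
    corrected: set[int] = set()
    for i in range(h, x.size - h):
        nb = np.concatenate([x[i - h : i], x[i + 1 : i + h + 1]])
        mu = nb.mean()
        sigma = nb.std()  # population SD: sigma=0 band means exact equality
        if abs(x[i] - mu) > sigma_multiplier * sigma:
            out[i] = 0.5 * (x[i - 1] + x[i + 1])
            corrected.add(i)
    return out, corrected


def moving_average(series: np.ndarray, window: int = 11) -> np.ndarray:
    """Centred moving average, window truncated at the edges."""
    if window < 3:
        raise ValueError("window must be >= 3")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    x = np.asarray(series, dtype=float)
    kernel = np.ones(window)
    # full convolution then a centred slice: robust for series shorter
    # than the window (numpy's "same" mode returns max(n, window) values)
    start = (window - 1) // 2
    sums = np.convolve(x, kernel, mode="full")[start : start + x.size]
    counts = np.convolve(np.ones_like(x), kernel, mode="full")[
        start : start + x.size
    ]
    return sums / counts


def preprocess_recording(
    raw: RawRecording, config: PreprocessConfig | None = None
) -> CleanRecording | Rejection:
    """Run the full cleaning cascade on one raw recording.

    Returns a :class:`CleanRecording` with per-stage QC bookkeeping, or a
    :class:`Rejection` when the recording is too short or its load ramp
    decreases and repair is disabled.
    """
    config = config or PreprocessConfig()
    n = raw.n_samples
    if n <= config.min_duration_samples:
        return Rejection(
            id=raw.id,
            reason="min_duration",
            detail={"n_samples": n, "required": config.min_duration_samples + 1},
        )

    qc: dict = {
        "zeroed": {},
        "leading_backfilled": {},
        "local_filter_pass1": {},
        "local_filter_pass2": {},
        "load_monotone": True,
        "load_repaired": False,
        "moving_average_applied": False,
    }
    values: dict[str, np.ndarray] = {}
    for ch, tokens in raw.tokens.items():
        x, zeroed = sanitize_tokens(tokens)
        x, leading = correct_zeroed(x, zeroed)
        values[ch] = x
        if zeroed:
            qc["zeroed"][ch] = sorted(zeroed)
        if leading:
            qc["leading_backfilled"][ch] = leading

    if "load" in values:
        if not check_load_monotone(values["load"]):
            qc["load_monotone"] = False
            if not config.repair_load:
                return Rejection(
                    id=raw.id, reason="load_not_monotone", detail={}
                )
            values["load"] = repair_load_isotonic(values["load"])
            qc["load_repaired"] = True

    for ch in values:
        values[ch], idx1 = local_stats_filter(
            values[ch], config.neighbor_halfwidth, config.sigma_multiplier
        )
        if idx1:
            qc["local_filter_pass1"][ch] = sorted(idx1)

    if n >= config.ma_threshold_samples:
        qc["moving_average_applied"] = True
        for ch in values:
            values[ch] = moving_average(values[ch], config.ma_window)
    else:
        for ch in values:
            values[ch], idx2 = local_stats_filter(
                values[ch], config.neighbor_halfwidth, config.sigma_multiplier
            )
            if idx2:
                qc["local_filter_pass2"][ch] = sorted(idx2)

    return CleanRecording(
        id=raw.id, sex=raw.sex, t=raw.t.copy(), values=values, qc=qc
    )


def preprocess_cohort(
    recordings: list[RawRecording], config: PreprocessConfig | None = None
) -> tuple[list[CleanRecording], list[Rejection]]:
    """Clean every recording, separating accepted from rejected."""
    accepted: list[CleanRecording] = []
    rejected: list[Rejection] = []
    for raw in recordings:
        out = preprocess_recording(raw, config)
        if isinstance(out, Rejection):
            rejected.append(out)
        else:
            accepted.append(out)
    return accepted, rejected
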