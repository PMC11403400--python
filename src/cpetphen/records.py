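"""Core data containers shared across the pipeline stages.

A CPET (cardiopulmonary exercise test) recording is a short multichannel
time series sampled breath by breath on a cycle ergometer: the mechanical
load, heart rate and six gas-exchange channels.  Raw device exports are
token-valued (cells may hold invalid markers such as ``"-"`` or ``">>"``);
cleaned recordings are numeric and quality-checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical channel order of a breath-by-breath export
CHANNELS: tuple[str, ...] = (
    "load", "HR", "VO2", "VCO2", "VE", "RER", "PETO2", "PETCO2",
)

#: channels used for phenogroup clustering (load, VCO2 and VE are dropped
#: as near-duplicates of VO2 in both the temporal and peak domain)
CLUSTER_CHANNELS: tuple[str, ...] = ("HR", "VO2", "RER", "PETO2", "PETCO2")

SEXES = ("male", "female")


@dataclass
class RawRecording:
    """Token-valued multichannel breath-by-breath series."""

    id: str
    sex: str
    t: np.ndarray  # elapsed seconds, strictly increasing
    tokens: dict[str, list[str]]  # channel -> string tokens

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        lengths = {ch: len(v) for ch, v in self.tokens.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"ragged channels: {lengths}")
        if lengths and next(iter(lengths.values())) != len(self.t):
            raise ValueError("channel length differs from time axis length")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.tokens)

    @property
    def n_samples(self) -> int:
        return len(self.t)


@dataclass
class CleanRecording:
    """Numeric, quality-checked multichannel series."""

    id: str
    sex: str
    t: np.ndarray
    values: dict[str, np.ndarray]  # channel -> float series
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = {
            ch: np.asarray(v, dtype=float) for ch, v in self.values.items()
        }
        for ch, v in self.values.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in channel {ch}")
            if len(v) != len(self.t):
                raise ValueError(f"channel {ch} length mismatch")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.values)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def matrix(self, channels: tuple[str, ...]) -> np.ndarray:
        """Stack the requested channels into an (n_samples, n_ch) array."""
        missing = [c for c in channels if c not in self.values]
        if missing:
            raise KeyError(f"missing channels: {missing}")
        return np.column_stack([self.values[c] for c in channels])


@dataclass
class Participant:
    """Clinical covariates of one cohort member."""

    id: str
    sex: str
    age: float
    height: float | None = None  # cm
    weight: float | None = None  # kg
    bmi: float | None = None  # kg/m^2
    sbp_rest: float | None = None  # mmHg
    dbp_rest: float | None = None  # mmHg
    hr_rest: float | None = None  # bpm
    fasting_glucose: float | None = None  # mmol/L
    antihypertensive_meds: bool = False
    antidiabetic_meds: bool = False
    cv_disease_history: bool = False
    self_report_dm: bool = False

    def __post_init__(self) -> None:
        if self.bmi is None and self.weight is not None and self.height:
            self.bmi = self.weight / (self.height / 100.0) ** 2


@dataclass
class SurvivalRecord:
    """Follow-up of one participant for the outcome analysis.

    ``event_offsets_days`` lists every adverse-event date (days since the
    CPET); the blanking rule in :mod:`cpetphen.clinical_validation` decides
    which one counts as the first qualifying event.
    """

    id: str
    time_years: float  # follow-up to first counted event or censoring
    event: bool
    event_offsets_days: list[float] = field(default_factory=list)
    censor_days: float | None = None  # administrative censoring date
    blanked: bool = False

    def __post_init__(self) -> None:
        if self.time_years < 0:
            raise ValueError("follow-up time must be non-negative")
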