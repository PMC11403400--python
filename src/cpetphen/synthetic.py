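"""Synthetic CPET cohort generator with known cluster structure.

The generator emulates an incremental cycle-ergometer ramp protocol
(target exhaustion in 8–12 minutes, 20 W + 20 W/min ramp) recorded breath
by breath, with five per-sex phenogroup archetypes whose peak and rest
values follow the gradient reported for clinical CPET phenogroups: peak
VO2, HR, VE and ventilatory efficiency decline from archetype 1 to 5,
age and comorbidity burden increase.  Recordings are contaminated with
the two artefact kinds real exports show — invalid tokens (``"-"``,
``">>"``) and large spikes — and every altered cell is logged so the
cleaning cascade can be tested against an exact oracle.  Survival
outcomes are drawn from per-cluster exponential hazards calibrated to
the event rates of the same gradient.

The generator is the test bed for the pipeline, not a physiological
model: it produces the qualitative curve shapes (monotone VO2/HR/VE
rises, RER rising through ~1.1, PETO2 dipping then rising, PETCO2 rising
then falling) without alveolar gas-exchange equations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .records import (
    CHANNELS,
    CleanRecording,
    Participant,
    RawRecording,
    SurvivalRecord,
)

# ---------------------------------------------------------------------------
# archetype parameters
# ---------------------------------------------------------------------------

#: Per-cluster curve parameters, male scale, clusters 1..5.  Peak and rest
#: levels follow the declining-fitness gradient of clinical phenogroups;
#: shape coefficients (exponents, dips) are free knobs chosen once to give
#: the qualitative shapes: cluster 3 has a late RER surge, clusters 4-5
#: reach high RER early, clusters 1 and 3 have shallow end-tidal curves.
DEFAULT_ARCHETYPES: dict[str, dict] = {
    "rest_VO2": {"values": [679.0, 604.0, 547.0, 507.0, 432.0]},
    "peak_VO2": {"values": [2866.0, 2268.0, 1846.0, 1587.0, 1218.0]},
    "rest_HR": {"values": [73.5, 73.3, 73.9, 71.6, 71.5]},
    "peak_HR": {"values": [171.7, 158.7, 148.9, 138.6, 125.1]},
    "rest_VE": {"values": [12.0, 11.0, 10.5, 10.0, 9.0]},
    "peak_VE": {"values": [102.6, 85.1, 71.7, 64.1, 52.1]},
    "rise_exp_VO2": {"values": [1.05, 1.0, 0.95, 0.9, 0.78]},
    "rise_exp_HR": {"values": [1.0, 0.95, 0.9, 0.85, 0.72]},
    "rise_exp_VE": {"values": [1.3, 1.25, 1.2, 1.15, 1.1]},
    "rer_start": {"values": [0.81, 0.82, 0.82, 0.83, 0.85]},
    "rer_peak": {"values": [1.14, 1.17, 1.17, 1.18, 1.18]},
    "rer_exp": {"values": [1.3, 1.1, 1.6, 0.85, 0.55]},
    "peto2_rest": {"values": [106.0, 107.1, 107.3, 108.1, 110.2]},
    "peto2_end": {"values": [113.6, 114.8, 115.0, 115.6, 116.2]},
    "peto2_dip": {"values": [2.0, 5.0, 2.5, 6.0, 8.5]},
    "petco2_rest": {"values": [35.5, 35.1, 34.6, 34.2, 32.9]},
    "petco2_end": {"values": [39.7, 38.8, 37.9, 37.3, 36.0]},
    "petco2_rise": {"values": [3.0, 5.0, 3.5, 5.5, 7.0]},
    "load_start_W": {"values": [20.0] * 5},
    "load_ramp_W_per_min": {"values": [20.0] * 5},
}

#: breath-to-breath measurement noise SD per channel (channel units)
DEFAULT_NOISE_SD: dict[str, float] = {
    "load": 0.0,
    "HR": 2.0,
    "VO2": 60.0,
    "VCO2": 60.0,
    "VE": 3.0,
    "RER": 0.025,
    "PETO2": 1.2,
    "PETCO2": 1.0,
}

#: per-cluster yearly hazards mirroring the 28.1/19.8/39.8/55.9/88.1 per
#: 1,000 person-year gradient of clinical phenogroups (ordered variant)
DEFAULT_HAZARDS: tuple[float, ...] = (0.020, 0.025, 0.040, 0.056, 0.088)

_AGE_MEAN = [43.2, 49.5, 54.7, 60.1, 65.0]
_WEIGHT_MEAN = [92.8, 87.8, 82.3, 79.6, 75.3]
_HEIGHT_MEAN = [178.5, 174.6, 170.8, 169.4, 167.6]
_SBP_MEAN = [118.4, 122.6, 125.8, 128.4, 130.9]
_GLUCOSE_SHIFT = [0.0, 0.1, 0.2, 0.35, 0.6]
_P_ANTIHYPERTENSIVE = [0.28, 0.48, 0.58, 0.69, 0.83]
_P_ANTIDIABETIC = [0.06, 0.10, 0.10, 0.13, 0.21]
_P_CVD = [0.31, 0.47, 0.52, 0.69, 0.81]
_P_SELF_DM = [0.03, 0.05, 0.06, 0.08, 0.12]


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort."""

    n_per_sex: int = 100
    k_true: int = 5
    duration_range_s: tuple[float, float] = (480.0, 720.0)
    sample_interval_s: float = 3.0
    archetypes: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_ARCHETYPES.items()
        }
    )
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    subject_sd: float = 0.01  # between-subject scale jitter on peaks
    female_scale: float = 0.7  # female VO2/VCO2/VE scale factor
    pet_offset_sd: float = 0.4  # between-subject end-tidal offset, mmHg
    invalid_token_rate: float = 0.01
    spike_rate: float = 0.01
    spike_magnitude_sd: float = 2.0  # extra SD multiples beyond the 3-SD floor
    planted_window_frac: tuple[float, float] = (0.6, 0.8)
    hazards: tuple[float, ...] = DEFAULT_HAZARDS
    censor_horizon_years: tuple[float, float] = (3.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("invalid_token_rate", "spike_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        lo, hi = self.duration_range_s
        if not (0 < lo <= hi):
            raise ValueError("duration_range_s must be positive and ordered")
        if self.k_true < 2:
            raise ValueError("k_true must be at least 2")
        if len(self.hazards) < self.k_true:
            raise ValueError("need one hazard per cluster")
        if lo / self.sample_interval_s < 2:
            raise ValueError("duration shorter than two samples")


@dataclass
class GroundTruth:
    """Oracle bookkeeping for everything the generator planted."""

    labels: dict[str, int]  # recording id -> true cluster (1-based)
    contamination_log: dict[str, list[tuple[str, int, str]]]
    planted_regions: dict[int, tuple[float, float, str]]
    survival_params: dict[int, float]
    clean_series: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# noiseless archetype curves
# ---------------------------------------------------------------------------

def _get(archetypes: dict, key: str, cluster: int) -> float:
    try:
        return float(archetypes[key]["values"][cluster - 1])
    except (KeyError, IndexError) as exc:
        raise ValueError(f"unknown cluster {cluster} or parameter {key}") from exc


def archetype_curve(
    cluster_id: int,
    channel: str,
    n_samples: int,
    archetypes: dict | None = None,
    sex: str = "male",
    sample_interval_s: float = 3.0,
    female_scale: float = 0.7,
) -> np.ndarray:
    """Noiseless template curve of one channel for one cluster archetype.

    ``load`` is a strictly increasing ramp; VO2/HR/VE rise monotonically
    from rest to the cluster peak; RER rises from ~0.8 past 1.05; PETO2
    falls to a mid-test dip then rises; PETCO2 rises then falls; VCO2 is
    RER × VO2 so the gas-exchange channels stay mutually consistent.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    arch = archetypes if archetypes is not None else DEFAULT_ARCHETYPES
    c = cluster_id
    _get(arch, "peak_VO2", c)  # validates cluster id
    u = np.linspace(0.0, 1.0, n_samples)
    t_min = np.arange(n_samples) * sample_interval_s / 60.0
    sex_scale = 1.0 if sex == "male" else female_scale

    if channel == "load":
        return _get(arch, "load_start_W", c) + _get(
            arch, "load_ramp_W_per_min", c
        ) * t_min
    if channel in ("HR", "VO2", "VE"):
        rest = _get(arch, f"rest_{channel}", c)
        peak = _get(arch, f"peak_{channel}", c)
        if channel in ("VO2", "VE"):
            rest, peak = rest * sex_scale, peak * sex_scale
        e = _get(arch, f"rise_exp_{channel}", c)
        return rest + (peak - rest) * u**e
    if channel == "RER":
        start = _get(arch, "rer_start", c)
        peak = _get(arch, "rer_peak", c)
        return start + (peak - start) * u ** _get(arch, "rer_exp", c)
    if channel == "VCO2":
        vo2 = archetype_curve(
            c, "VO2", n_samples, arch, sex, sample_interval_s, female_scale
        )
        rer = archetype_curve(
            c, "RER", n_samples, arch, sex, sample_interval_s, female_scale
        )
        return vo2 * rer
    if channel == "PETO2":
        rest = _get(arch, "peto2_rest", c)
        end = _get(arch, "peto2_end", c)
        dip = _get(arch, "peto2_dip", c)
        return rest + (end - rest) * u - dip * 4.0 * u * (1.0 - u)
    if channel == "PETCO2":
        rest = _get(arch, "petco2_rest", c)
        end = _get(arch, "petco2_end", c)
        rise = _get(arch, "petco2_rise", c)
        return rest + (end - rest) * u + rise * 4.0 * u * (1.0 - u)
    raise ValueError(f"unknown channel {channel!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# contamination
# ---------------------------------------------------------------------------

def contaminate(
    series: np.ndarray,
    invalid_token_rate: float,
    spike_rate: float,
    spike_magnitude_sd: float,
    rng: np.random.Generator,
) -> tuple[list[str], list[tuple[int, str]]]:
    """Turn a numeric series into device-export tokens with planted faults.

    Each cell (except the first two, which the downstream correction
    formula needs intact as predecessors) is independently replaced by an
    invalid token (``"-"`` or ``">>"``) or perturbed by a spike of
    magnitude at least 3 channel-SD.  Returns the token series and a log
    of ``(index, kind)`` for every altered cell.
    """
    if not 0.0 <= invalid_token_rate <= 1.0 or not 0.0 <= spike_rate <= 1.0:
        raise ValueError("contamination rates must be in [0, 1]")
    x = np.asarray(series, dtype=float)
    sd = float(np.std(x))
    tokens = [repr(float(v)) for v in x]
    log: list[tuple[int, str]] = []
    u = rng.random(len(x))
    for i in range(len(x)):
        if i < 2:
            continue
        if u[i] < invalid_token_rate:
            tokens[i] = "-" if rng.random() < 0.5 else ">>"
            log.append((i, "invalid_token"))
        elif u[i] < invalid_token_rate + spike_rate:
            mag = sd * (3.0 + abs(rng.normal(0.0, spike_magnitude_sd)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            tokens[i] = repr(float(x[i] + sign * mag))
            log.append((i, "spike"))
    return tokens, log


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _clean_channels(
    cluster: int,
    n_samples: int,
    sex: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Noisy but token-free channel set for one subject."""
    scale = {
        ch: max(0.0, 1.0 + rng.normal(0.0, config.subject_sd))
        for ch in ("HR", "VO2", "VE")
    }
    # end-tidal pressures vary between subjects by a few mmHg of offset,
    # not by a scale factor on the absolute pressure
    offset = {
        ch: rng.normal(0.0, config.pet_offset_sd)
        for ch in ("PETO2", "PETCO2")
    }
    values: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        curve = archetype_curve(
            cluster, ch, n_samples, config.archetypes, sex,
            config.sample_interval_s, config.female_scale,
        )
        if ch in ("HR", "VO2", "VE"):
            curve = curve * scale[ch]
        elif ch == "VCO2":
            curve = curve * scale["VO2"]
        elif ch in ("PETO2", "PETCO2"):
            curve = curve + offset[ch]
        sd = config.noise_sd.get(ch, 0.0)
        if sd > 0:
            curve = curve + rng.normal(0.0, sd, n_samples)
        values[ch] = curve
    return values


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[RawRecording], list[Participant], list[SurvivalRecord], GroundTruth]:
    """Simulate a full two-sex cohort with contamination and outcomes.

    Returns raw token-valued recordings, the clinical covariate table,
    survival follow-up (all event offsets retained so the blanking rule
    can be exercised) and the ground truth used by the test oracles.
    The uncontaminated numeric series of every recording is stashed in
    the ground truth log alongside the cell-level contamination diff.
    """
    rng = np.random.default_rng(config.seed)
    recordings: list[RawRecording] = []
    participants: list[Participant] = []
    survivals: list[SurvivalRecord] = []
    labels: dict[str, int] = {}
    contamination: dict[str, list[tuple[str, int, str]]] = {}
    clean_store: dict[str, dict[str, np.ndarray]] = {}

    lo, hi = config.duration_range_s
    cens_lo, cens_hi = config.censor_horizon_years
    for sex in ("male", "female"):
        prefix = "M" if sex == "male" else "F"
        # balanced cluster assignment, shuffled
        base = np.tile(
            np.arange(1, config.k_true + 1),
            config.n_per_sex // config.k_true + 1,
        )[: config.n_per_sex]
        clusters = rng.permutation(base)
        for idx, cluster in enumerate(clusters):
            rid = f"{prefix}{idx + 1:04d}"
            duration = rng.uniform(lo, hi)
            n_samples = max(2, int(duration / config.sample_interval_s))
            t = np.arange(n_samples) * config.sample_interval_s
            clean = _clean_channels(int(cluster), n_samples, sex, config, rng)
            tokens: dict[str, list[str]] = {}
            log: list[tuple[str, int, str]] = []
            for ch in CHANNELS:
                if ch == "load":
                    # ergometer-controlled ramp: exported clean
                    tokens[ch] = [repr(float(v)) for v in clean[ch]]
                    continue
                tk, ch_log = contaminate(
                    clean[ch],
                    config.invalid_token_rate,
                    config.spike_rate,
                    config.spike_magnitude_sd,
                    rng,
                )
                tokens[ch] = tk
                log.extend((ch, i, kind) for i, kind in ch_log)
            recordings.append(RawRecording(id=rid, sex=sex, t=t, tokens=tokens))
            labels[rid] = int(cluster)
            contamination[rid] = log
            clean_store[rid] = clean

            participants.append(
                _draw_participant(rid, sex, int(cluster), rng)
            )
            survivals.append(
                _draw_survival(
                    rid,
                    config.hazards[int(cluster) - 1],
                    rng,
                    cens_lo,
                    cens_hi,
                )
            )

    truth = GroundTruth(
        labels=labels,
        contamination_log=contamination,
        planted_regions={},
        survival_params={
            c + 1: config.hazards[c] for c in range(config.k_true)
        },
        clean_series=clean_store,
    )
    return recordings, participants, survivals, truth


def _draw_participant(
    rid: str, sex: str, cluster: int, rng: np.random.Generator
) -> Participant:
    c = cluster - 1
    age = float(np.clip(rng.normal(_AGE_MEAN[c], 10.0), 18.0, 90.0))
    height = rng.normal(_HEIGHT_MEAN[c] - (13.0 if sex == "female" else 0.0), 7.0)
    weight = max(
        40.0,
        rng.normal(_WEIGHT_MEAN[c] * (0.8 if sex == "female" else 1.0), 12.0),
    )
    return Participant(
        id=rid,
        sex=sex,
        age=age,
        height=float(height),
        weight=float(weight),
        sbp_rest=float(rng.normal(_SBP_MEAN[c], 18.0)),
        dbp_rest=float(rng.normal(78.0, 11.0)),
        hr_rest=float(rng.normal(73.0, 13.0)),
        fasting_glucose=float(
            max(3.0, rng.normal(5.3 + _GLUCOSE_SHIFT[c], 0.9))
        ),
        antihypertensive_meds=bool(rng.random() < _P_ANTIHYPERTENSIVE[c]),
        antidiabetic_meds=bool(rng.random() < _P_ANTIDIABETIC[c]),
        cv_disease_history=bool(rng.random() < _P_CVD[c]),
        self_report_dm=bool(rng.random() < _P_SELF_DM[c]),
    )


def _draw_survival(
    rid: str,
    hazard: float,
    rng: np.random.Generator,
    cens_lo: float,
    cens_hi: float,
) -> SurvivalRecord:
    censor_years = rng.uniform(cens_lo, cens_hi)
    # recurrent exponential event process up to censoring
    offsets: list[float] = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / hazard) if hazard > 0 else np.inf
        if t >= censor_years:
            break
        offsets.append(t * 365.25)
    if offsets:
        return SurvivalRecord(
            id=rid,
            time_years=offsets[0] / 365.25,
            event=True,
            event_offsets_days=offsets,
            censor_days=censor_years * 365.25,
        )
    return SurvivalRecord(
        id=rid,
        time_years=censor_years,
        event=False,
        event_offsets_days=[],
        censor_days=censor_years * 365.25,
    )


# ---------------------------------------------------------------------------
# planted-window cohort for the interpretability oracle
# ---------------------------------------------------------------------------

def generate_planted_cohort(
    n_per_cluster: int = 15,
    channel: str = "RER",
    window: tuple[float, float] | None = None,
    delta: float = 0.2,
    base_cluster: int = 3,
    seed: int = 0,
    config: SyntheticConfig | None = None,
) -> tuple[list[CleanRecording], dict[str, int], GroundTruth]:
    """Two-cluster cohort whose only difference is one channel's window.

    Both clusters share the ``base_cluster`` archetype; cluster 2 adds an
    offset of ``delta`` channel units to ``channel`` inside the normalized
    time ``window`` (default from the config's planted_window_frac).
    This is the oracle cohort for distinctive-region localization.
    """
    config = config or SyntheticConfig(seed=seed)
    window = window or config.planted_window_frac
    rng = np.random.default_rng(seed)
    lo, hi = config.duration_range_s
    recordings: list[CleanRecording] = []
    labels: dict[str, int] = {}
    for cluster in (1, 2):
        for idx in range(n_per_cluster):
            rid = f"P{cluster}{idx + 1:03d}"
            duration = rng.uniform(lo, hi)
            n = max(2, int(duration / config.sample_interval_s))
            t = np.arange(n) * config.sample_interval_s
            values = _clean_channels(base_cluster, n, "male", config, rng)
            if cluster == 2:
                u = np.linspace(0.0, 1.0, n)
                mask = (u >= window[0]) & (u <= window[1])
                values[channel] = values[channel] + delta * mask
            recordings.append(
                CleanRecording(id=rid, sex="male", t=t, values=values)
            )
            labels[rid] = cluster
    truth = GroundTruth(
        labels=labels,
        contamination_log={},
        planted_regions={2: (window[0], window[1], channel)},
        survival_params={},
    )
    return recordings, labels, truth


def config_with(config: SyntheticConfig, **overrides) -> SyntheticConfig:
    """Copy a config with some fields replaced."""
    return dataclasses.replace(config, **overrides)
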