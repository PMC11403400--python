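"""Readers, writers and the run manifest.

One CSV per recording (matching per-test device exports and keeping
variable lengths natural), a cohort-level ``participants.csv`` and
``survival.csv``, a ``ground_truth.json`` for synthetic cohorts, models
as JSON with the medoid series inline, and a deterministic run manifest
with per-artifact checksums.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterModel
from .records import CHANNELS, Participant, RawRecording, SurvivalRecord
from .synthetic import GroundTruth

#: header dialect map: lowercase, stripped of units/punctuation -> channel
_CHANNEL_ALIASES = {
    "load": "load", "work": "load", "watt": "load", "watts": "load",
    "power": "load",
    "hr": "HR", "heartrate": "HR",
    "vo2": "VO2", "v'o2": "VO2",
    "vco2": "VCO2", "v'co2": "VCO2",
    "ve": "VE", "v'e": "VE",
    "rer": "RER",
    "peto2": "PETO2", "petco2": "PETCO2",
    "t": "t_s", "ts": "t_s", "time": "t_s", "times": "t_s",
}


def _normalize_header(name: str) -> str | None:
    base = re.sub(r"\(.*?\)", "", str(name)).strip().lower()
    base = re.sub(r"[^a-z0-9']", "", base)
    return _CHANNEL_ALIASES.get(base)


def read_recording_csv(
    path: str | Path, rec_id: str | None = None, sex: str = "male"
) -> RawRecording:
    """Tolerant parse of one breath-by-breath export.

    Invalid cells ("-", ">>", blanks) are preserved verbatim as string
    tokens for the cleaning cascade.  Header aliases (e.g. ``vo2
    (ml/min)``) are normalized via a dialect map.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {}
    for col in df.columns:
        target = _normalize_header(col)
        if target is not None:
            colmap[target] = col
    missing = [ch for ch in CHANNELS if ch not in colmap]
    if missing:
        raise ValueError(f"{path.name}: missing mandatory channels {missing}")
    n = len(df)
    if "t_s" in colmap:
        t = pd.to_numeric(df[colmap["t_s"]]).to_numpy(dtype=float)
    else:
        t = np.arange(n, dtype=float)
    tokens = {ch: df[colmap[ch]].astype(str).tolist() for ch in CHANNELS}
    return RawRecording(
        id=rec_id or path.stem, sex=sex, t=t, tokens=tokens
    )


def write_recording_csv(rec, path: str | Path) -> None:
    """Write a recording (raw tokens or clean values) as one CSV."""
    path = Path(path)
    data: dict[str, list] = {"t_s": [f"{v:g}" for v in rec.t]}
    if isinstance(rec, RawRecording):
        for ch in rec.channels:
            data[ch] = rec.tokens[ch]
    else:
        for ch in rec.channels:
            data[ch] = [repr(float(v)) for v in rec.values[ch]]
    pd.DataFrame(data).to_csv(path, index=False)


def write_participants_csv(
    participants: list[Participant], path: str | Path
) -> None:
    rows = [
        {
            "id": p.id, "sex": p.sex, "age": p.age, "height": p.height,
            "weight": p.weight, "bmi": p.bmi, "sbp_rest": p.sbp_rest,
            "dbp_rest": p.dbp_rest, "hr_rest": p.hr_rest,
            "fasting_glucose": p.fasting_glucose,
            "antihypertensive_meds": int(p.antihypertensive_meds),
            "antidiabetic_meds": int(p.antidiabetic_meds),
            "cv_disease_history": int(p.cv_disease_history),
            "self_report_dm": int(p.self_report_dm),
        }
        for p in participants
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_participants_csv(path: str | Path) -> list[Participant]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            Participant(
                id=str(r["id"]), sex=str(r["sex"]), age=float(r["age"]),
                height=_opt(r, "height"), weight=_opt(r, "weight"),
                bmi=_opt(r, "bmi"), sbp_rest=_opt(r, "sbp_rest"),
                dbp_rest=_opt(r, "dbp_rest"), hr_rest=_opt(r, "hr_rest"),
                fasting_glucose=_opt(r, "fasting_glucose"),
                antihypertensive_meds=bool(r.get("antihypertensive_meds", 0)),
                antidiabetic_meds=bool(r.get("antidiabetic_meds", 0)),
                cv_disease_history=bool(r.get("cv_disease_history", 0)),
                self_report_dm=bool(r.get("self_report_dm", 0)),
            )
        )
    return out


def _opt(row, key) -> float | None:
    v = row.get(key)
    return None if v is None or pd.isna(v) else float(v)


def write_survival_csv(records: list[SurvivalRecord], path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "time_years": r.time_years,
            "event": int(r.event),
            "event_offsets_days": ";".join(
                f"{o:.4f}" for o in r.event_offsets_days
            ),
            "censor_days": r.censor_days,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_survival_csv(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, dtype={"event_offsets_days": str})
    out = []
    for _, r in df.iterrows():
        offsets_raw = r.get("event_offsets_days")
        offsets = (
            [float(x) for x in str(offsets_raw).split(";") if x]
            if isinstance(offsets_raw, str) and offsets_raw
            else []
        )
        out.append(
            SurvivalRecord(
                id=str(r["id"]),
                time_years=float(r["time_years"]),
                event=bool(r["event"]),
                event_offsets_days=offsets,
                censor_days=_opt(r, "censor_days"),
            )
        )
    return out


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "labels": truth.labels,
        "contamination_log": {
            rid: [[ch, int(i), kind] for ch, i, kind in log]
            for rid, log in truth.contamination_log.items()
        },
        "planted_regions": {
            str(k): list(v) for k, v in truth.planted_regions.items()
        },
        "survival_params": {
            str(k): v for k, v in truth.survival_params.items()
        },
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def write_model_json(
    models: dict[str, ClusterModel], path: str | Path
) -> None:
    payload = {sex: m.to_dict() for sex, m in models.items()}
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_model_json(path: str | Path) -> dict[str, ClusterModel]:
    payload = json.loads(Path(path).read_text())
    return {sex: ClusterModel.from_dict(d) for sex, d in payload.items()}


def write_cohort(
    out_dir: str | Path,
    recordings: list[RawRecording],
    participants: list[Participant],
    survivals: list[SurvivalRecord],
    truth: GroundTruth | None = None,
) -> None:
    """Write a cohort as one CSV per recording plus the cohort tables."""
    out = Path(out_dir)
    rec_dir = out / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording_csv(rec, rec_dir / f"{rec.id}.csv")
    write_participants_csv(participants, out / "participants.csv")
    write_survival_csv(survivals, out / "survival.csv")
    if truth is not None:
        write_ground_truth_json(truth, out / "ground_truth.json")


def read_cohort(
    in_dir: str | Path,
) -> tuple[list[RawRecording], list[Participant], list[SurvivalRecord]]:
    """Read a cohort directory written by :func:`write_cohort`."""
    root = Path(in_dir)
    participants = read_participants_csv(root / "participants.csv")
    sex_by_id = {p.id: p.sex for p in participants}
    survival_path = root / "survival.csv"
    survivals = (
        read_survival_csv(survival_path) if survival_path.exists() else []
    )
    recordings = []
    for path in sorted((root / "recordings").glob("*.csv")):
        rid = path.stem
        recordings.append(
            read_recording_csv(path, rid, sex_by_id.get(rid, "male"))
        )
    return recordings, participants, survivals


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    accepted: list[str] = field(default_factory=list)
    rejected: dict[str, str] = field(default_factory=dict)  # id -> reason

    def record_stage(self, name: str, outputs: dict[str, str]) -> None:
        self.stages[name] = {"outputs": outputs}

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "version": self.version,
                "seed": self.seed,
                "stages": self.stages,
                "accepted": sorted(self.accepted),
                "rejected": dict(sorted(self.rejected.items())),
            },
            sort_keys=True,
            indent=1,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())
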