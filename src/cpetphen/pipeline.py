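"""End-to-end orchestration: simulate -> clean -> cluster -> explain ->
summarize -> validate, with a deterministic manifest.

Every stage reads from and writes to an output directory; all
randomness flows from the single config seed.  Running twice with the
same config and seed produces byte-identical artifacts and manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical_validation import (
    blank_early_events,
    build_covariate_frame,
    cox_hr,
    group_compare,
    km_incidence,
)
from .clustering import SexFitResult, assign_cohort, fit_sex_models, scale_with_model
from .interpretability import InterpretConfig, extract_all_regions
from .io import (
    RunManifest,
    read_cohort,
    sha256_file,
    write_cohort,
    write_model_json,
)
from .preprocessing import PreprocessConfig, preprocess_cohort
from .records import CLUSTER_CHANNELS
from .summary_metrics import compute_summary
from .synthetic import SyntheticConfig, generate_cohort


@dataclass
class PipelineConfig:
    out_dir: str = "cpet_run"
    seed: int = 0
    synthetic: SyntheticConfig | None = None  # None: read existing cohort
    in_dir: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    channels: tuple[str, ...] = CLUSTER_CHANNELS
    k: int | None = 5
    k_range: tuple[int, int] = (2, 8)
    interpret: InterpretConfig = field(default_factory=InterpretConfig)
    blanking_days: float = 90.0
    band: int | None = None
    run_interpretability: bool = True

    def hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return float(o)
            return str(o)

        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # hash the science, not the paths
        payload.pop("in_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=enc)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full phenogrouping pipeline and write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.hash(), version=__version__, seed=config.seed
    )

    # --- cohort -----------------------------------------------------------
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        recordings, participants, survivals, truth = generate_cohort(syn)
        write_cohort(out / "cohort", recordings, participants, survivals, truth)
        manifest.record_stage(
            "simulate",
            {
                "participants.csv": sha256_file(
                    out / "cohort" / "participants.csv"
                ),
                "survival.csv": sha256_file(out / "cohort" / "survival.csv"),
            },
        )
    elif config.in_dir is not None:
        recordings, participants, survivals = read_cohort(config.in_dir)
    else:
        raise ValueError("config needs either synthetic or in_dir")

    # --- preprocessing ----------------------------------------------------
    cleaned, rejections = preprocess_cohort(recordings, config.preprocess)
    manifest.accepted = [r.id for r in cleaned]
    manifest.rejected = {r.id: r.reason for r in rejections}
    manifest.record_stage(
        "preprocess",
        {"n_accepted": str(len(cleaned)), "n_rejected": str(len(rejections))},
    )

    # --- clustering -------------------------------------------------------
    fits: dict[str, SexFitResult] = fit_sex_models(
        cleaned,
        participants,
        channels=config.channels,
        k=config.k,
        k_range=range(config.k_range[0], config.k_range[1] + 1),
        seed=config.seed,
        band=config.band,
    )
    write_model_json(
        {sex: f.model for sex, f in fits.items()}, out / "model.json"
    )
    assignments = assign_cohort(fits, cleaned)
    adf = pd.DataFrame(
        [
            {
                "id": a.id,
                "phenogroup": a.phenogroup,
                "distance": a.distance_to_medoid,
            }
            for a in assignments
        ]
    ).sort_values("id")
    adf.to_csv(out / "assignments.csv", index=False)
    manifest.record_stage(
        "fit",
        {
            "model.json": sha256_file(out / "model.json"),
            "assignments.csv": sha256_file(out / "assignments.csv"),
        },
    )
    labels = {a.id: a.phenogroup for a in assignments}

    # --- interpretability -------------------------------------------------
    if config.run_interpretability:
        regions_payload: dict[str, dict] = {}
        for sex, fit in fits.items():
            stratum = [r for r in cleaned if r.sex == sex]
            scaled = [scale_with_model(fit.model, r) for r in stratum]
            sex_labels = [labels[r.id] for r in stratum]
            regions = extract_all_regions(
                scaled, sex_labels, interpret=config.interpret
            )
            regions_payload[sex] = {
                str(g): {
                    "segments": reg.segments_normalized(),
                    "support": reg.support,
                }
                for g, reg in regions.items()
            }
        (out / "regions.json").write_text(
            json.dumps(regions_payload, sort_keys=True, indent=1)
        )
        manifest.record_stage(
            "explain", {"regions.json": sha256_file(out / "regions.json")}
        )

    # --- summary metrics --------------------------------------------------
    part_by_id = {p.id: p for p in participants}
    summaries = [compute_summary(r, part_by_id.get(r.id)) for r in cleaned]
    sdf = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    sdf = sdf.drop(columns=["rest_values"]).sort_values("id")
    sdf.to_csv(out / "summary.csv", index=False)
    manifest.record_stage(
        "summarize", {"summary.csv": sha256_file(out / "summary.csv")}
    )

    # --- clinical validation ----------------------------------------------
    if survivals:
        blanked = blank_early_events(survivals, config.blanking_days)
        rates = km_incidence(blanked, labels)
        rates_df = pd.DataFrame(
            [
                {
                    "phenogroup": g,
                    "n": v["n"],
                    "events": v["events"],
                    "person_years": v["person_years"],
                    "rate_per_1000py": v["rate_per_1000py"],
                }
                for g, v in sorted(rates.items())
            ]
        )
        rates_df.to_csv(out / "rates.csv", index=False)
        peak_vo2 = {s.id: s.peak_VO2 for s in summaries}
        cov = build_covariate_frame(participants, peak_vo2, include_sex=True)
        try:
            hr = cox_hr(blanked, labels, cov)
            hr.to_csv(out / "hazard_ratios.csv")
            hr_hash = sha256_file(out / "hazard_ratios.csv")
        except ValueError:
            hr_hash = "fit_failed"
        comp = group_compare(
            cov.drop(columns=["sex_male"], errors="ignore"), labels
        )
        comp.to_csv(out / "comparison.csv", index=False)
        manifest.record_stage(
            "validate",
            {
                "rates.csv": sha256_file(out / "rates.csv"),
                "hazard_ratios.csv": hr_hash,
                "comparison.csv": sha256_file(out / "comparison.csv"),
            },
        )

    manifest.write(out / "manifest.json")
    return manifest
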