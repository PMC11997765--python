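"""End-to-end orchestration: synth -> detect -> classify -> localize -> outcome.

Every stage persists its intermediates (events.csv, rates.csv, ROC and
metric tables) under the output directory, and a manifest records the
config hash, seed and package version so a rerun with the same config
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cooccur import rates_to_frame
from .localization import (
    SPEC_LEVELS,
    compare_rates_in_out,
    patient_pauc,
    pooled_roc,
    partial_auc,
)
from .outcome import (
    association_with_outcome,
    loocv_outcome,
    pseudo_prospective,
)
from .synth import CohortParams, SynthParams, synth_cohort
from .types import CATEGORIES, ValidationError

logger = logging.getLogger(__name__)

#: categories evaluated in the localization / outcome reports
REPORT_CATEGORIES = list(CATEGORIES)


@dataclass
class PipelineConfig:
    output_dir: str = "hfomark_output"
    seed: int = 0
    n_patients: int = 10
    n_good: int = 6
    label_noise: float = 0.1
    outcome_cutoff: float = 0.5
    window_ms: float = 50.0
    duration_s: float = 600.0
    n_channels: int = 32
    spec_levels: tuple = SPEC_LEVELS
    region: str = "RA"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValidationError("config must set a seed for reproducibility")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, persisting every intermediate.

    Returns a manifest dict (also written as manifest.json).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "version": __version__,
        "outputs": [],
        "stages_completed": [],
    }

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        manifest["outputs"].append(name)

    try:
        # --- synth ---------------------------------------------------
        params = CohortParams(
            n_patients=config.n_patients,
            n_good=config.n_good,
            label_noise=config.label_noise,
            outcome_threshold=config.outcome_cutoff,
            patient_params=SynthParams(
                n_channels=config.n_channels, duration=config.duration_s
            ),
            duration_range=(config.duration_s, config.duration_s),
            seed=config.seed,
        )
        cohort, truths = synth_cohort(params)
        cohort_rows = [
            {
                "patient_id": pr.patient_id,
                "duration_min": pr.rates.recording_duration,
                "engel": pr.engel,
                "outcome": pr.outcome,
                "follow_up": round(pr.follow_up, 2),
            }
            for pr in cohort
        ]
        save(pd.DataFrame(cohort_rows), "cohort.csv")
        ev_rows = []
        for pid, events in truths.items():
            for ev in events:
                ev_rows.append(
                    {
                        "patient_id": pid,
                        "channel_id": ev.channel_id,
                        "onset": ev.onset,
                        "offset": ev.offset,
                        "peak_time": ev.peak_time,
                        "event_type": ev.event_type.value,
                    }
                )
        save(pd.DataFrame(ev_rows), "events.csv")
        chan_rows = []
        for pr in cohort:
            for c in pr.channels:
                chan_rows.append(
                    {
                        "patient_id": pr.patient_id,
                        "channel_id": c.channel_id,
                        "lobe": c.lobe.value,
                        "is_soz": int(c.is_soz),
                        "is_resected": int(c.is_resected),
                        "electrode_kind": c.electrode_kind.value,
                    }
                )
        save(pd.DataFrame(chan_rows), "channels.csv")
        manifest["stages_completed"].append("synth")

        # --- classify ------------------------------------------------
        rate_frames = []
        for pr in cohort:
            df = rates_to_frame(pr.rates).reset_index()
            df.insert(0, "patient_id", pr.patient_id)
            rate_frames.append(df)
        save(pd.concat(rate_frames, ignore_index=True), "rates.csv")
        manifest["stages_completed"].append("classify")

        # --- localize ------------------------------------------------
        good = [pr for pr in cohort if pr.good_outcome]
        loc_rows = []
        pauc_rows = []
        for cat in REPORT_CATEGORIES:
            roc = pooled_roc(good, cat, config.region)
            score = partial_auc(roc)
            row = {
                "category": cat,
                "pauc_raw": score.pauc_raw,
                "pauc_norm": score.pauc_norm,
            }
            row.update(
                {f"sens_at_{int(100 * k)}": v for k, v in score.sens_at_spec.items()}
            )
            loc_rows.append(row)
            for pr in good:
                ps = patient_pauc(pr, cat, config.region)
                if ps is not None:
                    pauc_rows.append(
                        {
                            "patient_id": pr.patient_id,
                            "category": cat,
                            "pauc_norm": ps.pauc_norm,
                        }
                    )
        save(pd.DataFrame(loc_rows), "localization_group.csv")
        save(pd.DataFrame(pauc_rows), "localization_patient.csv")
        inout_rows = []
        for cat in ("All_S", "All_R", "All_FR", "S+R"):
            try:
                res = compare_rates_in_out(cohort, cat, config.region, "good")
            except ValidationError:
                continue
            inout_rows.append(
                {
                    "category": cat,
                    "inside_median": res["inside_median_iqr"][0],
                    "outside_median": res["outside_median_iqr"][0],
                    "p": res["p"],
                }
            )
        save(pd.DataFrame(inout_rows), "rates_in_out.csv")
        manifest["stages_completed"].append("localize")

        # --- outcome -------------------------------------------------
        outcome_rows = []
        for cat in REPORT_CATEGORIES + ["SOZ"]:
            try:
                cv = loocv_outcome(cohort, cat)
                pp = pseudo_prospective(cohort, cat, config.outcome_cutoff)
                assoc = association_with_outcome(cohort, cat, config.outcome_cutoff)
            except ValidationError as exc:
                logger.info("outcome analysis skipped for %s: %s", cat, exc)
                continue
            outcome_rows.append(
                {
                    "category": cat,
                    "auc": cv["auc"][0],
                    "sensitivity": cv["sensitivity"][0],
                    "specificity": cv["specificity"][0],
                    "ppv": cv["ppv"][0],
                    "npv": cv["npv"][0],
                    "markedness": cv["markedness"][0],
                    "accuracy": cv["accuracy"][0],
                    "youden_j": cv["youden_j"][0],
                    "pp_accuracy": pp["accuracy"][0],
                    "barnard_p": assoc["p"],
                    "n_excluded": assoc["n_excluded"],
                }
            )
        save(pd.DataFrame(outcome_rows), "outcome_metrics.csv")
        manifest["stages_completed"].append("outcome")
    except Exception as exc:
        stage = (
            manifest["stages_completed"][-1]
            if manifest["stages_completed"]
            else "(none)"
        )
        manifest["error"] = f"failed after stage {stage}: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["outputs"].append("manifest.json")
    return manifest
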