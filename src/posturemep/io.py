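"""Dataset layout on disk: one directory per subject, one CSV + JSON sidecar
per trial, and a cohort-level manifest.

Trial CSVs hold ``time_s`` plus one column per muscle (volts) and optionally
``platform_cm``.  The sidecar records condition, trial kind, perturbation
label, event times (seconds) and the sample rate.  ``manifest.csv`` at the
dataset root lists every trial file with its metadata, and each subject
directory stores the generating model parameters in ``subject.json``
(generator ground truth, kept for validation and recovery experiments).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import MUSCLES, TMS_LEAD_S
from .synth import BurstParams, SubjectDataset, SubjectModel, TrialRecording
from .protocol import TrialSchedule, ScheduleEntry, ConditionName, TrialKind

__all__ = ["write_dataset", "read_dataset", "validate_dataset"]


def _model_to_json(model: SubjectModel) -> dict:
    d = dataclasses.asdict(model)
    d["mep_mean_pct"] = {f"{m}|{c}": v for (m, c), v in model.mep_mean_pct.items()}
    d["burst_params"] = {
        f"{m}|{lab}|{pred}": dataclasses.asdict(bp)
        for (m, lab, pred), bp in model.burst_params.items()
    }
    return d


def _model_from_json(d: dict) -> SubjectModel:
    d = dict(d)
    d["mep_mean_pct"] = {
        tuple(k.split("|")): v for k, v in d["mep_mean_pct"].items()
    }
    d["burst_params"] = {
        tuple(k.split("|")): BurstParams(**v) for k, v in d["burst_params"].items()
    }
    return SubjectModel(**d)


def _write_trial(path: Path, trial: TrialRecording) -> None:
    n = trial.n_samples
    cols = {"time_s": np.arange(n) / trial.sample_rate}
    cols.update(trial.channels)
    if trial.platform_displacement is not None:
        cols["platform_cm"] = trial.platform_displacement
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8g")
    meta = {
        "subject_id": trial.subject_id,
        "condition": trial.condition,
        "kind": trial.kind,
        "perturbation": trial.perturbation,
        "sample_rate": trial.sample_rate,
        "tms_time": trial.tms_time,
        "perturbation_onset": trial.perturbation_onset,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def _read_trial(path: Path) -> TrialRecording:
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    channels = {m: df[m].to_numpy() for m in df.columns if m in MUSCLES}
    platform = df["platform_cm"].to_numpy() if "platform_cm" in df.columns else None
    return TrialRecording(
        subject_id=meta["subject_id"],
        condition=meta["condition"],
        kind=meta["kind"],
        perturbation=meta["perturbation"],
        sample_rate=meta["sample_rate"],
        channels=channels,
        tms_time=meta["tms_time"],
        perturbation_onset=meta["perturbation_onset"],
        platform_displacement=platform,
    )


def write_dataset(datasets: list[SubjectDataset], out_dir: str | Path) -> Path:
    """Write a cohort to disk; returns the dataset root."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for ds in datasets:
        sdir = root / ds.model.subject_id
        sdir.mkdir(exist_ok=True)
        (sdir / "subject.json").write_text(json.dumps(_model_to_json(ds.model), indent=1))
        sched = [
            {"condition": e.condition.value, "kind": e.kind.value, "perturbation": e.perturbation}
            for e in ds.schedule.entries
        ]
        (sdir / "schedule.json").write_text(json.dumps(sched, indent=1))
        for i, trial in enumerate(ds.trials):
            fname = f"trial-{i:03d}.csv"
            _write_trial(sdir / fname, trial)
            manifest_rows.append(
                {
                    "subject_id": ds.model.subject_id,
                    "file": f"{ds.model.subject_id}/{fname}",
                    "condition": trial.condition,
                    "kind": trial.kind,
                    "perturbation": trial.perturbation or "",
                    "tms_time": trial.tms_time,
                    "perturbation_onset": trial.perturbation_onset,
                }
            )
        for muscle, sweep in ds.mmax_sweeps.items():
            for i, trial in enumerate(sweep):
                fname = f"mmax-{muscle}-{i:02d}.csv"
                _write_trial(sdir / fname, trial)
                manifest_rows.append(
                    {
                        "subject_id": ds.model.subject_id,
                        "file": f"{ds.model.subject_id}/{fname}",
                        "condition": "Mmax",
                        "kind": "mmax",
                        "perturbation": muscle,  # sweep target muscle
                        "tms_time": trial.tms_time,
                        "perturbation_onset": None,
                    }
                )
    pd.DataFrame(manifest_rows).to_csv(root / "manifest.csv", index=False)
    return root


def read_dataset(root: str | Path) -> list[SubjectDataset]:
    """Read a cohort from disk (inverse of :func:`write_dataset`)."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    datasets = []
    for sid, grp in manifest.groupby("subject_id", sort=True):
        sdir = root / str(sid)
        model = _model_from_json(json.loads((sdir / "subject.json").read_text()))
        sched_meta = json.loads((sdir / "schedule.json").read_text())
        schedule = TrialSchedule(
            [
                ScheduleEntry(ConditionName(e["condition"]), TrialKind(e["kind"]), e["perturbation"])
                for e in sched_meta
            ]
        )
        trials = []
        sweeps: dict[str, list[TrialRecording]] = {}
        for _, row in grp.iterrows():
            trial = _read_trial(root / row["file"])
            if row["kind"] == "mmax":
                sweeps.setdefault(row["perturbation"], []).append(trial)
            else:
                trials.append(trial)
        datasets.append(SubjectDataset(model=model, schedule=schedule, trials=trials, mmax_sweeps=sweeps))
    return datasets


def validate_dataset(root: str | Path) -> list[dict]:
    """Structural diagnostics for a dataset directory.

    Checks manifest completeness, the 50-ms TMS-lead geometry, sample-rate
    consistency and channel-length agreement.  Returns a machine-readable
    issue list (empty for a pristine dataset).
    """
    root = Path(root)
    issues: list[dict] = []
    manifest_path = root / "manifest.csv"
    if not manifest_path.exists():
        return [{"issue": "missing-manifest", "file": str(manifest_path)}]
    manifest = pd.read_csv(manifest_path)
    sample_rates = set()
    for _, row in manifest.iterrows():
        fpath = root / row["file"]
        if not fpath.exists() or not fpath.with_suffix(".json").exists():
            issues.append({"issue": "missing-file", "file": row["file"]})
            continue
        meta = json.loads(fpath.with_suffix(".json").read_text())
        df = pd.read_csv(fpath)
        fs = meta["sample_rate"]
        sample_rates.add(fs)
        muscles = [c for c in df.columns if c in MUSCLES]
        lengths = {len(df[c]) for c in muscles}
        if len(lengths) != 1:
            issues.append({"issue": "channel-length-mismatch", "file": row["file"]})
        if meta["tms_time"] is not None and meta["perturbation_onset"] is not None:
            lead = meta["perturbation_onset"] - meta["tms_time"]
            if abs(lead - TMS_LEAD_S) > 0.5 / fs:
                issues.append(
                    {
                        "issue": "tms-lead-violation",
                        "file": row["file"],
                        "lead_s": lead,
                    }
                )
        n_expected = meta.get("n_samples")
        if meta["kind"] in ("MEP", "catch"):
            # condition trials must cover the analysis windows
            t_end = len(df) / fs
            anchor = meta["perturbation_onset"] or meta["tms_time"]
            if anchor is not None and t_end < anchor + 0.35:
                issues.append({"issue": "truncated-trial", "file": row["file"], "t_end": t_end})
    if len(sample_rates) > 1:
        issues.append({"issue": "mixed-sample-rates", "rates": sorted(sample_rates)})
    return issues
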