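"""Standard-format I/O: NIfTI-1 volumes, BIDS-style events TSV, result TSVs.

Synthetic ROI voxels are laid out along the first spatial axis of a
(voxels, 1, 1, volumes) NIfTI-1 image; a companion integer NIfTI holds the
ROI/hemisphere label code per voxel, with the code table in the dataset's
JSON metadata.  Event schedules are written one TSV per run with columns
onset, duration, trial_type.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import DesignConfig, RunSchedule, TrialEvent
from .hrf import DesignMatrix, HRFModel, evaluate_hrf
from .simulate import (
    BOLDRun,
    GroundTruthPatterns,
    ParticipantData,
    ScenarioParams,
    SyntheticDataset,
)

EVENTS_COLUMNS = ("onset", "duration", "trial_type")


def write_events_tsv(schedule: RunSchedule, path: Path) -> None:
    rows = [
        {"onset": e.onset, "duration": e.duration, "trial_type": e.kind}
        for e in schedule.events
    ]
    pd.DataFrame(rows, columns=list(EVENTS_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: Path, total_duration: float, tr: float) -> RunSchedule:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path} missing column(s): {missing}")
    events = tuple(
        TrialEvent(onset=float(r.onset), kind=str(r.trial_type), duration=float(r.duration))
        for r in df.itertuples()
    )
    return RunSchedule(events=events, total_duration=total_duration, tr=tr)


def _label_codes(run: BOLDRun) -> tuple[np.ndarray, dict[str, int]]:
    keys = [f"{n}_{h}" for n, h in zip(run.roi_names, run.hemispheres)]
    table = {k: i + 1 for i, k in enumerate(dict.fromkeys(keys))}
    return np.array([table[k] for k in keys], dtype=np.int16), table


def write_bold_nifti(run: BOLDRun, path: Path) -> dict[str, int]:
    """4-D BOLD volume plus companion integer ROI-label volume."""
    data = run.data.astype(np.float32)[:, None, None, :]
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr))
    nib.save(img, str(path))
    codes, table = _label_codes(run)
    lab = nib.Nifti1Image(codes[:, None, None], affine=np.eye(4))
    nib.save(lab, str(path.with_name(path.name.replace("_bold", "_roilabels"))))
    return table


def write_dataset(dataset: SyntheticDataset, outdir: Path) -> Path:
    """Write one NIfTI + events TSV per run and a dataset metadata JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "scenario": dataset.scenario,
        "seed": dataset.seed,
        "config": asdict(dataset.config),
        "params": asdict(dataset.params),
        "participants": [],
    }
    for p, part in enumerate(dataset.participants):
        pdir = outdir / f"sub-{p:02d}"
        pdir.mkdir(exist_ok=True)
        runs_meta = []
        for r, (run, schedule) in enumerate(zip(part.runs, part.schedules)):
            stem = pdir / f"sub-{p:02d}_run-{r:02d}"
            table = write_bold_nifti(run, stem.with_name(stem.name + "_bold.nii.gz"))
            write_events_tsv(schedule, stem.with_name(stem.name + "_events.tsv"))
            runs_meta.append(
                {
                    "run": r,
                    "total_duration": schedule.total_duration,
                    "tr": schedule.tr,
                    "n_volumes": schedule.n_volumes,
                    "label_table": table,
                }
            )
        meta["participants"].append({"id": p, "runs": runs_meta})
    (outdir / "dataset.json").write_text(json.dumps(meta, indent=2))
    return outdir


def read_dataset(path: Path) -> SyntheticDataset:
    """Reconstruct a dataset bundle; validates volume counts against schedules."""
    path = Path(path)
    meta = json.loads((path / "dataset.json").read_text())
    config = DesignConfig(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in meta["config"].items()
        }
    )
    params = ScenarioParams(**meta["params"])
    participants = []
    for pmeta in meta["participants"]:
        p = pmeta["id"]
        runs, schedules = [], []
        for rmeta in pmeta["runs"]:
            r = rmeta["run"]
            stem = path / f"sub-{p:02d}" / f"sub-{p:02d}_run-{r:02d}"
            schedule = read_events_tsv(
                stem.with_name(stem.name + "_events.tsv"),
                total_duration=rmeta["total_duration"],
                tr=rmeta["tr"],
            )
            img = nib.load(str(stem.with_name(stem.name + "_bold.nii.gz")))
            data = np.asarray(img.dataobj, dtype=float)[:, 0, 0, :]
            if data.shape[1] != schedule.n_volumes:
                raise ValueError(
                    f"run {r} of participant {p}: {data.shape[1]} volumes on "
                    f"disk but schedule implies {schedule.n_volumes}"
                )
            lab_img = nib.load(str(stem.with_name(stem.name + "_roilabels.nii.gz")))
            codes = np.asarray(lab_img.dataobj).reshape(-1)
            inverse = {v: k for k, v in rmeta["label_table"].items()}
            keys = [inverse[int(c)] for c in codes]
            roi_names = np.array([k.rsplit("_", 1)[0] for k in keys])
            hemis = np.array([k.rsplit("_", 1)[1] for k in keys])
            runs.append(
                BOLDRun(data=data, tr=rmeta["tr"], roi_names=roi_names, hemispheres=hemis)
            )
            schedules.append(schedule)
        # ground truth is not serialized with the volumes; reading back a
        # written dataset yields measurement data only (like real scans)
        patterns = GroundTruthPatterns(
            amplitudes={},
            hemispheres=runs[0].hemispheres,
            scenario=meta["scenario"],
            gains={},
        )
        participants.append(ParticipantData(tuple(runs), tuple(schedules), patterns))
    return SyntheticDataset(
        participants=tuple(participants),
        config=config,
        params=params,
        scenario=meta["scenario"],
        seed=meta["seed"],
    )


def design_to_tsv(design: DesignMatrix, path: Path) -> None:
    pd.DataFrame(design.values, columns=list(design.regressor_labels)).to_csv(
        path, sep="\t", index=False
    )


def hrf_to_tsv(model: HRFModel, path: Path, grid_step: float = 0.1) -> None:
    t = np.arange(0.0, model.support + grid_step, grid_step)
    pd.DataFrame({"time": t, "value": evaluate_hrf(model, t)}).to_csv(
        path, sep="\t", index=False
    )
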