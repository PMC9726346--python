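"""End-to-end orchestration: simulate → fit → index → stats.

Stages communicate only through their declared file interfaces (NIfTI
volumes, FSL gradient tables, CSV tables, JSON), so each can also be run
on its own from the command line. A single top-level seed spawns
per-subject substreams, making full runs byte-reproducible on the CSV
and JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .alps import measurements_to_frame, subject_alps
from .cohort import (
    CohortConfig,
    SubjectGroundTruth,
    cohort_to_frame,
    default_cohort_config,
    sample_cohort,
)
from .io import load_dwi, save_dwi, save_nifti, save_tensor_field
from .phantom import build_phantom, default_layout, simulate_dwi
from .scheme import build_default_scheme
from .stats import DEFAULT_FAMILY, age_correlations, compare_groups, report
from .tensorfit import fit_tensor

__all__ = ["RunConfig", "RunManifest", "StageError", "run_all", "make_fixture",
           "simulate_stage", "fit_stage", "index_stage", "stats_stage",
           "estimate_subject_alps"]

logger = logging.getLogger("dtialps")


class StageError(RuntimeError):
    """A pipeline stage failed; the manifest records which."""


class RunConfig(BaseModel):
    """Complete configuration of one reproducible pipeline run."""

    cohort: CohortConfig = Field(default_factory=default_cohort_config)
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    voxel_size: tuple[float, float, float] = (1.875, 1.875, 2.5)
    seed: int = 0
    stats_family: tuple[str, ...] = DEFAULT_FAMILY
    save_dwi_volumes: bool = True
    save_tensor_maps: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class RunManifest(BaseModel):
    config_hash: str
    version: str
    seed: int
    stages: dict[str, str]  # stage -> "ok" | error text
    timings_s: dict[str, float]
    artifacts: dict[str, str]
    n_subjects: int


def _simulate_subject(subject: SubjectGroundTruth, layout, scheme, snr):
    tensors, s0 = build_phantom(layout, subject.specs)
    return simulate_dwi(tensors, s0, scheme, layout.affine, snr=snr,
                        seed=subject.seed)


def estimate_subject_alps(subject: SubjectGroundTruth, layout=None, scheme=None,
                          snr: float = 40.0):
    """In-memory simulate → fit → index for one subject.

    Returns the per-hemisphere ALPS measurements without touching disk;
    the file-based stages wrap the same functions.
    """
    layout = layout if layout is not None else default_layout()
    scheme = scheme if scheme is not None else build_default_scheme()
    dwi = _simulate_subject(subject, layout, scheme, snr)
    field = fit_tensor(dwi, mask=layout.labels > 0)
    return subject_alps(field, layout.labels)


def simulate_stage(config: RunConfig, out_dir: Path) -> dict[str, str]:
    """Sample the cohort and write per-subject DWI, labels and ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = default_layout(config.grid_shape, config.voxel_size)
    scheme = build_default_scheme()
    subjects = sample_cohort(config.cohort, config.seed)

    artifacts: dict[str, str] = {}
    labels_path = out_dir / "labels.nii.gz"
    save_nifti(layout.labels.astype(np.int16), layout.affine, labels_path)
    artifacts["labels"] = str(labels_path)

    frame = cohort_to_frame(subjects)
    subjects_csv = out_dir / "subjects.csv"
    frame.to_csv(subjects_csv, index=False, float_format="%.10g")
    artifacts["subjects"] = str(subjects_csv)

    truth = {
        s.subject_id: {
            "group": s.group,
            "age_months": s.age_months,
            "ga_weeks": s.ga_weeks,
            "sex": s.sex,
            "alps_true": s.alps_true,
            "noise_seed": s.seed,
        }
        for s in subjects
    }
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    artifacts["ground_truth"] = str(truth_path)

    if config.save_dwi_volumes:
        dwi_dir = out_dir / "dwi"
        dwi_dir.mkdir(exist_ok=True)
        for s in subjects:
            dwi = _simulate_subject(s, layout, scheme, config.cohort.snr)
            save_dwi(dwi, dwi_dir / s.subject_id)
        artifacts["dwi_dir"] = str(dwi_dir)
    return artifacts


def fit_stage(sim_dir: Path, out_dir: Path) -> dict[str, str]:
    """Fit tensors for every simulated subject found under ``sim_dir``.

    Uses the phantom label volume as the fit mask (the analogue of a
    brain mask: phantom volumes are generated skull-free and aligned).
    """
    from .io import load_nifti

    sim_dir, out_dir = Path(sim_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dwi_dir = sim_dir / "dwi"
    stems = sorted(p.name[: -len(".nii.gz")] for p in dwi_dir.glob("*.nii.gz"))
    if not stems:
        raise StageError(f"no DWI volumes found in {dwi_dir}")
    labels_path = sim_dir / "labels.nii.gz"
    mask = None
    if labels_path.exists():
        labels, _ = load_nifti(labels_path)
        mask = labels > 0
    artifacts = {}
    for stem in stems:
        dwi = load_dwi(dwi_dir / f"{stem}.nii.gz", dwi_dir / f"{stem}.bval",
                       dwi_dir / f"{stem}.bvec")
        field = fit_tensor(dwi, mask=mask)
        save_tensor_field(field, out_dir / stem)
        artifacts[stem] = str(out_dir / stem)
    return artifacts


def index_stage(fit_dir: Path, labels_path: Path, subjects_csv: Path,
                out_dir: Path) -> dict[str, str]:
    """Compute bilateral ALPS per subject and merge into the subject table."""
    from .io import load_nifti, load_tensor_field

    fit_dir, out_dir = Path(fit_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels, _ = load_nifti(labels_path)
    labels = labels.astype(np.int16)
    per_subject = {}
    for sub_dir in sorted(p for p in fit_dir.iterdir() if p.is_dir()):
        field = load_tensor_field(sub_dir)
        per_subject[sub_dir.name] = subject_alps(field, labels)
    if not per_subject:
        raise StageError(f"no fitted subjects found in {fit_dir}")

    long = measurements_to_frame(per_subject)
    long_csv = out_dir / "alps_measurements.csv"
    long.to_csv(long_csv, index=False, float_format="%.10g")

    wide = long.pivot(index="subject_id", columns="hemisphere", values="alps_index")
    wide = wide.rename(columns={"left": "alps_left", "right": "alps_right"})
    subjects = pd.read_csv(subjects_csv)
    merged = subjects.merge(wide, on="subject_id", how="left")
    merged_csv = out_dir / "subjects_alps.csv"
    merged.to_csv(merged_csv, index=False, float_format="%.10g")
    return {"measurements": str(long_csv), "subjects_alps": str(merged_csv)}


def stats_stage(subjects_alps_csv: Path, out_dir: Path,
                family=DEFAULT_FAMILY) -> dict[str, str]:
    """Run the group-comparison and age-correlation analysis."""
    out_dir = Path(out_dir)
    records = pd.read_csv(subjects_alps_csv)
    comparisons = compare_groups(records, family=family)
    correlations, warnings = age_correlations(records)
    for w in warnings:
        logger.warning(w)
    report(comparisons, correlations, out_dir)
    return {
        "demographics": str(out_dir / "demographics.csv"),
        "alps_comparison": str(out_dir / "alps_comparison.csv"),
        "age_correlations": str(out_dir / "age_correlations.csv"),
        "stats_json": str(out_dir / "stats.json"),
    }


def run_all(config: RunConfig, out_dir) -> RunManifest:
    """Execute all four stages; halts on the first failing stage."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, str] = {}
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}
    n_subjects = sum(p.n for p in config.cohort.groups.values())

    plan = [
        ("simulate", lambda: simulate_stage(config, out_dir / "sim")),
        ("fit", lambda: fit_stage(out_dir / "sim", out_dir / "fit")),
        ("index", lambda: index_stage(
            out_dir / "fit", out_dir / "sim" / "labels.nii.gz",
            out_dir / "sim" / "subjects.csv", out_dir / "index")),
        ("stats", lambda: stats_stage(
            out_dir / "index" / "subjects_alps.csv", out_dir / "stats",
            family=config.stats_family)),
    ]
    for name, fn in plan:
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - manifest records the failure
            stages[name] = f"failed: {exc}"
            _write_manifest(config, out_dir, stages, timings, artifacts, n_subjects)
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        stages[name] = "ok"
        artifacts.update({f"{name}:{k}": v for k, v in out.items()})
        logger.info("stage %s finished in %.2fs", name, timings[name])

    return _write_manifest(config, out_dir, stages, timings, artifacts, n_subjects)


def _write_manifest(config, out_dir, stages, timings, artifacts, n_subjects):
    manifest = RunManifest(
        config_hash=config.config_hash(), version=__version__,
        seed=config.seed, stages=stages, timings_s=timings,
        artifacts=artifacts, n_subjects=n_subjects,
    )
    (Path(out_dir) / "manifest.json").write_text(
        manifest.model_dump_json(indent=2)
    )
    return manifest


def make_fixture(scale: str, out_dir, seed: int = 0) -> RunConfig:
    """Build a bundled dataset: 'smoke' (4 subjects, 16³ grid) or 'paper'
    (the full 30 + 25 cohort at study parameters)."""
    if scale == "smoke":
        cfg = default_cohort_config()
        for params in cfg.groups.values():
            params.n = 2
        config = RunConfig(cohort=cfg, grid_shape=(16, 16, 16),
                           voxel_size=(1.875, 1.875, 2.5), seed=seed)
    elif scale == "paper":
        config = RunConfig(cohort=default_cohort_config(), seed=seed)
    else:
        raise ValueError("scale must be 'smoke' or 'paper'")
    simulate_stage(config, Path(out_dir))
    return config
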