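"""Cohort orchestration: per-patient runs, table assembly, statistics.

One malformed patient never aborts a cohort run: failures are collected,
logged with their stage, and the patient is excluded from the association
stage; the caller decides what a partial cohort is worth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .atlas import SEGMENTS
from .config import AnalysisConfig
from .model import AtrialShapeModel, ShapeMetrics
from .stats import AssociationReport, lva_association_analysis, validate_cohort_table

log = logging.getLogger("atriamorph")


class PatientRunError(RuntimeError):
    """A per-patient failure, annotated with the failing stage."""

    def __init__(self, patient_id: str, stage: str, cause: Exception) -> None:
        super().__init__(f"[{patient_id}] {stage}: {cause}")
        self.patient_id = patient_id
        self.stage = stage
        self.cause = cause


def run_patient(
    mesh_path: str | Path,
    landmarks_path: str | Path,
    config: AnalysisConfig | None = None,
    patient_id: str | None = None,
) -> ShapeMetrics:
    """Full measurement chain for one patient; errors carry the stage name."""
    stage = "input"
    try:
        model = AtrialShapeModel.from_files(
            mesh_path, landmarks_path, config=config, patient_id=patient_id
        )
        stage = "fit"
        return model.fit().metrics
    except Exception as exc:
        pid = patient_id or Path(mesh_path).stem
        raise PatientRunError(pid, stage, exc) from exc


@dataclass
class CohortRun:
    table: pd.DataFrame
    report: AssociationReport | None
    failures: list[PatientRunError] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _discover_patients(cohort_dir: Path) -> list[tuple[str, Path, Path]]:
    patients = []
    for pdir in sorted(cohort_dir.iterdir()):
        if not pdir.is_dir():
            continue
        meshes = sorted(
            p for p in pdir.iterdir() if p.suffix.lower() in (".ply", ".stl", ".obj")
        )
        lmk = pdir / "landmarks.json"
        if meshes and lmk.exists():
            patients.append((pdir.name, meshes[0], lmk))
    return patients


def _load_labels(cohort_dir: Path, labels_csv: str | Path | None) -> pd.DataFrame:
    """Per-patient binary segment labels, either from one cohort CSV
    (columns: patient_id, lva_<segment>...) or from per-patient
    ``lva_labels.csv`` files (columns: segment, lva)."""
    if labels_csv is not None:
        df = pd.read_csv(labels_csv)
        if "patient_id" not in df.columns:
            raise ValueError("labels CSV needs a patient_id column")
        return df
    rows = []
    for pdir in sorted(Path(cohort_dir).iterdir()):
        f = pdir / "lva_labels.csv"
        if pdir.is_dir() and f.exists():
            lab = pd.read_csv(f).set_index("segment")["lva"]
            rows.append(
                {"patient_id": pdir.name, **{f"lva_{s}": int(lab[s]) for s in SEGMENTS}}
            )
    if not rows:
        raise IOError(f"no low-voltage labels found under {cohort_dir}")
    return pd.DataFrame(rows)


def run_cohort(
    cohort_dir: str | Path,
    labels_csv: str | Path | None = None,
    config: AnalysisConfig | None = None,
) -> CohortRun:
    """Run every patient directory, join LVA labels, compute statistics.

    Patient directories are ``<cohort_dir>/<id>/`` holding a mesh
    (PLY/STL/OBJ) and ``landmarks.json``.  Patients that fail, or that are
    missing from the labels, are excluded from the association stage with a
    warning.
    """
    config = config or AnalysisConfig()
    cohort_dir = Path(cohort_dir)
    patients = _discover_patients(cohort_dir)
    if len(patients) < 2:
        raise IOError(f"found {len(patients)} patient directories in {cohort_dir}; need >= 2")

    rows, failures = [], []
    for pid, mesh_path, lmk_path in patients:
        try:
            metrics = run_patient(mesh_path, lmk_path, config=config, patient_id=pid)
            rows.append(metrics.as_row())
            log.info("patient %s ok", pid)
        except PatientRunError as exc:
            failures.append(exc)
            log.warning("patient %s failed at %s: %s", pid, exc.stage, exc.cause)
    metrics_df = pd.DataFrame(rows)

    labels = _load_labels(cohort_dir, labels_csv)
    merged = metrics_df.merge(labels, on="patient_id", how="inner")
    dropped = set(metrics_df["patient_id"]) - set(merged["patient_id"])
    for pid in sorted(dropped):
        log.warning("patient %s has no low-voltage labels; excluded from statistics", pid)
    merged["lva_segment_count"] = merged[[f"lva_{s}" for s in SEGMENTS]].sum(axis=1)

    report = None
    if len(merged) >= 3:
        report = lva_association_analysis(validate_cohort_table(merged), config.stats)
    else:
        log.warning("fewer than 3 labelled patients; association stage skipped")
    return CohortRun(table=merged, report=report, failures=failures)
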