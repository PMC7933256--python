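"""Model/Results interface for the per-patient shape analysis.

:class:`AtrialShapeModel` bundles a closed atrial surface with its landmarks
and a configuration; :meth:`AtrialShapeModel.fit` runs the full measurement
chain — best-fit sphere (ICP), signed radial deviation with protrusion
exclusion, anatomical frame, six-segment partition, segmental deviations,
posterior-wall and cutting planes, anterior/posterior volume split — and
returns an :class:`AtrialShapeResults` holding every intermediate object plus
the flat :class:`ShapeMetrics` record and a ``summary()`` table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .asymmetry import AsymmetryResult, asymmetry_index, cutting_plane, posterior_plane
from .atlas import (
    SEGMENTS,
    LandmarkSet,
    PatientFrame,
    SegmentLabeling,
    SegmentalDeviation,
    build_patient_frame,
    partition_surface,
    segmental_deviation,
)
from .config import AnalysisConfig
from .mesh_core import SurfaceMesh, read_mesh
from .sphere import (
    DeviationField,
    FittedSphere,
    SphericityResult,
    deviation_field,
    fit_sphere_icp,
    sphericity,
)


@dataclass
class ShapeMetrics:
    """Flat per-patient record of every reported shape metric."""

    patient_id: str
    total_volume: float  # LAV, mL
    anterior_volume: float  # LA-A, mL
    posterior_volume: float  # LA-P, mL
    asymmetry_index: float  # ASI, fraction
    average_radius: float  # AR, mm
    mean_deviation: float  # S, mm
    sphericity: float  # LAS, fraction
    segment_deviation: dict[str, float]  # D per segment, mm
    excluded_area_fraction: float
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "LAV_ml": self.total_volume,
            "LA_A_ml": self.anterior_volume,
            "LA_P_ml": self.posterior_volume,
            "ASI": self.asymmetry_index,
            "AR_mm": self.average_radius,
            "S_mm": self.mean_deviation,
            "LAS": self.sphericity,
            "D_mm": dict(self.segment_deviation),
            "excluded_area_fraction": self.excluded_area_fraction,
            "provenance": dict(self.provenance),
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def as_row(self) -> dict:
        """Row for a cohort metrics table (statistics-module schema)."""
        row = {
            "patient_id": self.patient_id,
            "LAV": self.total_volume,
            "LA_A": self.anterior_volume,
            "LA_P": self.posterior_volume,
            "ASI": self.asymmetry_index,
            "AR": self.average_radius,
            "S": self.mean_deviation,
            "LAS": self.sphericity,
        }
        for seg in SEGMENTS:
            row[f"D_{seg}"] = self.segment_deviation[seg]
        return row


class AtrialShapeModel:
    """Per-patient shape model: mesh + landmarks + configuration.

    Parameters
    ----------
    mesh : SurfaceMesh
        Closed atrial surface, mm coordinates, PVs/appendage trimmed or left
        as protrusions (the exclusion rule removes them from surface
        metrics; volumes are of the supplied closed mesh as-is).
    landmarks : LandmarkSet
        PV-ostia centroids, LAA ostium, inferior reference.
    config : AnalysisConfig, optional
    patient_id : str, optional — defaults to the mesh name.
    """

    def __init__(
        self,
        mesh: SurfaceMesh,
        landmarks: LandmarkSet,
        config: AnalysisConfig | None = None,
        patient_id: str | None = None,
    ) -> None:
        self.mesh = mesh
        self.landmarks = landmarks
        self.config = config or AnalysisConfig()
        self.patient_id = patient_id or mesh.name
        self._provenance: dict = {
            "software": f"atriamorph {__version__}",
            "config_digest": self.config.digest(),
        }

    @classmethod
    def from_files(
        cls,
        mesh_path: str | Path,
        landmarks_path: str | Path,
        config: AnalysisConfig | None = None,
        patient_id: str | None = None,
    ) -> "AtrialShapeModel":
        mesh = read_mesh(mesh_path)
        landmarks = LandmarkSet.from_json(landmarks_path)
        model = cls(mesh, landmarks, config=config, patient_id=patient_id)
        model._provenance["inputs"] = {
            str(mesh_path): _file_digest(mesh_path),
            str(landmarks_path): _file_digest(landmarks_path),
        }
        return model

    def fit(self) -> "AtrialShapeResults":
        cfg = self.config
        mesh = self.mesh

        sphere = fit_sphere_icp(mesh)
        field_ = deviation_field(
            mesh, sphere, cfg.exclusion_threshold, cfg.exclusion_mode,
            area_weighted=cfg.area_weighted,
        )
        # optional refit-after-exclusion loop (off by default): refit on the
        # included vertices only, until the mask stabilises
        for _ in range(cfg.refit_passes):
            included = field_.included
            sub = mesh.vertices[included]
            refit = fit_sphere_icp(sub, init=sphere)
            new_field = deviation_field(
                mesh, refit, cfg.exclusion_threshold, cfg.exclusion_mode,
                area_weighted=cfg.area_weighted,
            )
            sphere = refit
            if np.array_equal(new_field.included, included):
                field_ = new_field
                break
            field_ = new_field

        spher = sphericity(field_, sphere)
        frame = build_patient_frame(mesh, sphere, self.landmarks)
        labeling = partition_surface(mesh, sphere, frame, field_, cfg.bands)
        segdev = segmental_deviation(field_, labeling)
        post = posterior_plane(mesh, labeling, self.landmarks)
        cut = cutting_plane(post, self.landmarks, offset=cfg.plane_offset)
        asym = asymmetry_index(mesh, cut)

        metrics = ShapeMetrics(
            patient_id=self.patient_id,
            total_volume=asym.total_volume,
            anterior_volume=asym.anterior_volume,
            posterior_volume=asym.posterior_volume,
            asymmetry_index=asym.asymmetry_index,
            average_radius=spher.average_radius,
            mean_deviation=spher.mean_deviation,
            sphericity=spher.sphericity,
            segment_deviation=dict(segdev.deviation),
            excluded_area_fraction=field_.excluded_area_fraction,
            provenance=dict(self._provenance),
        )
        return AtrialShapeResults(
            model=self,
            sphere=sphere,
            deviations=field_,
            sphericity=spher,
            frame=frame,
            labeling=labeling,
            segmental=segdev,
            asymmetry=asym,
            metrics=metrics,
        )


@dataclass
class AtrialShapeResults:
    """Everything the fit produced, with export helpers and ``summary()``."""

    model: AtrialShapeModel
    sphere: FittedSphere
    deviations: DeviationField
    sphericity: SphericityResult
    frame: PatientFrame
    labeling: SegmentLabeling
    segmental: SegmentalDeviation
    asymmetry: AsymmetryResult
    metrics: ShapeMetrics

    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Atrial shape analysis".center(58),
            "=" * 58,
            f"patient id          {m.patient_id}",
            f"vertices / faces    {self.model.mesh.n_vertices} / {len(self.model.mesh.faces)}",
            f"sphere fit          {self.sphere.iterations} ICP iterations, "
            f"converged={self.sphere.converged}",
            "-" * 58,
            f"LAV   total volume        {m.total_volume:9.2f} mL",
            f"LA-A  anterior volume     {m.anterior_volume:9.2f} mL",
            f"LA-P  posterior volume    {m.posterior_volume:9.2f} mL",
            f"ASI   asymmetry index     {100 * m.asymmetry_index:9.1f} %",
            f"AR    average radius      {m.average_radius:9.2f} mm",
            f"S     mean deviation      {m.mean_deviation:9.2f} mm",
            f"LAS   sphericity          {100 * m.sphericity:9.1f} %",
            f"      excluded area       {100 * m.excluded_area_fraction:9.1f} %",
            "-" * 58,
            "segmental wall deviation D (signed, mm):",
        ]
        for seg in SEGMENTS:
            lines.append(f"  {seg.replace('_', ' '):<20}{m.segment_deviation[seg]:+8.2f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def export(self, out_dir: str | Path) -> None:
        """Write metrics JSON, per-vertex deviation CSV/PLY and labels CSV."""
        from .sphere import export_deviation_ply

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pid = self.metrics.patient_id
        self.metrics.to_json(out / f"{pid}_metrics.json")
        self.deviations.export_csv(out / f"{pid}_deviations.csv")
        self.labeling.export_csv(out / f"{pid}_segments.csv")
        export_deviation_ply(self.model.mesh, self.deviations, out / f"{pid}_deviation.ply")


def _file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()[:16]
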