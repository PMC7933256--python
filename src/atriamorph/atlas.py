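"""Anatomical frame, six-segment surface partition, and segmental deviation.

The atrial surface is partitioned into six wall segments — roof, posterior,
septum (anterior septum), inferior septum, inferior-posterior, and lateral —
in a patient frame built from three landmarks:

* the centroids of the pulmonary-vein (PV) ostia, a posterior structure,
* the left-atrial-appendage (LAA) ostium, an anterolateral structure,
* an inferior reference (e.g. the mitral annulus centre).

The superior axis ẑ points from the inferior reference toward the best-fit
sphere centre; the posterior axis p̂ is the PV direction orthogonalised to ẑ;
the lateral axis completes a right-handed frame with its sign fixed so the
LAA lies anterior (negative posterior coordinate) and lateral (positive
lateral coordinate).

Segments are polar/azimuthal bands on the unit sphere around the fitted
centre: polar angle θ from ẑ, azimuth φ from p̂ about ẑ (positive toward the
lateral axis).  With the default band angles the septal bands sit on the
negative-azimuth (anti-LAA) side and the lateral band on the LAA side.  The
band angles are plain configuration values, not anatomy-derived constants,
because published segment boundaries do not exist; remapping them requires no
code change.

The per-segment wall deviation D is the *signed* area-weighted mean of the
radial deviations over the segment's included vertices — signed, so inward
(concave) remodeling of e.g. the posterior wall shows up as a negative D.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mesh_core import SurfaceMesh
from .sphere import DeviationField, FittedSphere

#: canonical segment order, used everywhere a per-segment vector appears
SEGMENTS = (
    "roof",
    "posterior",
    "septum",
    "inferior_septum",
    "inferior_posterior",
    "lateral",
)
EXCLUDED_LABEL = "excluded"


@dataclass(frozen=True)
class LandmarkSet:
    """Anatomical landmarks in mesh coordinates (mm)."""

    pv_ostia: np.ndarray  # (k, 3), k in 2..4
    laa_ostium: np.ndarray  # (3,)
    inferior_reference: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        pv = np.atleast_2d(np.asarray(self.pv_ostia, dtype=np.float64))
        if pv.shape[0] < 1 or pv.shape[1] != 3:
            raise ValueError("pv_ostia must be a (k, 3) array")
        object.__setattr__(self, "pv_ostia", pv)
        object.__setattr__(
            self, "laa_ostium", np.asarray(self.laa_ostium, dtype=np.float64).reshape(3)
        )
        object.__setattr__(
            self,
            "inferior_reference",
            np.asarray(self.inferior_reference, dtype=np.float64).reshape(3),
        )

    @property
    def pv_centroid(self) -> np.ndarray:
        return self.pv_ostia.mean(axis=0)

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        path = Path(path)
        if not path.exists():
            raise IOError(f"landmarks file not found: {path}")
        with open(path) as fh:
            data = json.load(fh)
        try:
            return cls(
                pv_ostia=np.asarray(data["pv_ostia"], dtype=float),
                laa_ostium=np.asarray(data["laa_ostium"], dtype=float),
                inferior_reference=np.asarray(data["inferior_reference"], dtype=float),
            )
        except KeyError as exc:
            raise ValueError(f"landmarks file {path} missing key {exc}") from exc

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "pv_ostia": self.pv_ostia.tolist(),
                    "laa_ostium": self.laa_ostium.tolist(),
                    "inferior_reference": self.inferior_reference.tolist(),
                },
                fh,
                indent=1,
            )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray, scale: float = 1.0) -> "LandmarkSet":
        R, t = np.asarray(rotation), np.asarray(translation)
        return LandmarkSet(
            scale * self.pv_ostia @ R.T + t,
            scale * R @ self.laa_ostium + t,
            scale * R @ self.inferior_reference + t,
        )


@dataclass(frozen=True)
class PatientFrame:
    """Right-handed orthonormal frame anchored at the sphere centre."""

    origin: np.ndarray
    superior: np.ndarray  # ẑ
    posterior: np.ndarray  # p̂
    lateral: np.ndarray  # l̂ = ẑ × p̂ (sign fixed by the LAA)

    def angles(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Polar angle θ (deg, from ẑ) and azimuth φ (deg, from p̂ toward l̂,
        in (-180, 180]) of ``points`` as seen from the origin."""
        rel = np.atleast_2d(points) - self.origin
        z = rel @ self.superior
        p = rel @ self.posterior
        l = rel @ self.lateral
        r = np.linalg.norm(rel, axis=1)
        theta = np.degrees(np.arccos(np.clip(z / np.maximum(r, 1e-300), -1.0, 1.0)))
        phi = np.degrees(np.arctan2(l, p))
        return theta, phi


def build_patient_frame(
    mesh: SurfaceMesh, sphere: FittedSphere, landmarks: LandmarkSet
) -> PatientFrame:
    """Construct the anatomical frame from the fitted sphere and landmarks.

    Raises
    ------
    ValueError
        If the inferior reference coincides with the sphere centre or the PV
        direction is (anti)parallel to the superior axis.
    """
    origin = sphere.center
    z_raw = origin - landmarks.inferior_reference
    nz = np.linalg.norm(z_raw)
    if nz < 1e-9:
        raise ValueError("inferior reference coincides with the sphere centre")
    z = z_raw / nz

    pv_dir = landmarks.pv_centroid - origin
    p_raw = pv_dir - (pv_dir @ z) * z
    npv = np.linalg.norm(p_raw)
    if npv < 1e-9:
        raise ValueError(
            "degenerate landmarks: PV direction parallel to the superior axis"
        )
    p = p_raw / npv
    l = np.cross(z, p)

    laa_rel = landmarks.laa_ostium - origin
    if laa_rel @ l < 0:
        # ẑ and p̂ are anchored by landmarks, so the only freedom left is the
        # lateral sign; flipping it (mirroring the azimuth) puts the LAA on
        # the positive-lateral side regardless of chirality of the export.
        l = -l
    if laa_rel @ p > 0:
        warnings.warn(
            "LAA ostium lies on the posterior side of the frame; "
            "landmarks may be inconsistent",
            stacklevel=2,
        )
    return PatientFrame(origin, z, p, l)


# ---------------------------------------------------------------------------
# Band configuration and partition


@dataclass(frozen=True)
class BandConfig:
    """Polar/azimuthal segment boundaries (degrees).

    ``roof_polar``: θ below which everything is roof.
    ``inferior_polar``: θ at the mid/inferior boundary.
    ``posterior_half_width``: |φ| bound of the posterior band (mid zone).
    ``inferior_posterior_half_width``: |φ| bound of the inferior-posterior
    band (inferior zone).  The septal bands occupy the remaining
    negative-azimuth side, the lateral band the positive-azimuth (LAA) side.
    """

    roof_polar: float = 45.0
    inferior_polar: float = 105.0
    posterior_half_width: float = 60.0
    inferior_posterior_half_width: float = 90.0

    def __post_init__(self) -> None:
        if not (0.0 < self.roof_polar < self.inferior_polar < 180.0):
            raise ValueError("band config: need 0 < roof_polar < inferior_polar < 180")
        if not (0.0 < self.posterior_half_width < 180.0):
            raise ValueError("band config: posterior_half_width outside (0, 180)")
        if not (0.0 < self.inferior_posterior_half_width < 180.0):
            raise ValueError(
                "band config: inferior_posterior_half_width outside (0, 180)"
            )


@dataclass
class SegmentLabeling:
    """Per-vertex segment labels; excluded vertices keep ``'excluded'``."""

    labels: np.ndarray  # array of str
    segments: tuple[str, ...] = SEGMENTS

    def mask(self, segment: str) -> np.ndarray:
        return self.labels == segment

    def counts(self) -> dict[str, int]:
        return {s: int((self.labels == s).sum()) for s in (*self.segments, EXCLUDED_LABEL)}

    def export_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["vertex_id", "segment"])
            for i, lab in enumerate(self.labels):
                wr.writerow([i, lab])


def segment_of_angles(theta: np.ndarray, phi: np.ndarray, bands: BandConfig) -> np.ndarray:
    """Vectorised band lookup: (θ, φ) in degrees → segment name."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.empty(theta.shape, dtype=object)

    roof = theta < bands.roof_polar
    mid = (~roof) & (theta < bands.inferior_polar)
    inf_ = theta >= bands.inferior_polar

    out[roof] = "roof"
    post = mid & (np.abs(phi) < bands.posterior_half_width)
    sept = mid & ~post & (phi <= 0)
    lat_mid = mid & ~post & (phi > 0)
    out[post] = "posterior"
    out[sept] = "septum"
    out[lat_mid] = "lateral"

    ip = inf_ & (np.abs(phi) < bands.inferior_posterior_half_width)
    isept = inf_ & ~ip & (phi <= 0)
    lat_inf = inf_ & ~ip & (phi > 0)
    out[ip] = "inferior_posterior"
    out[isept] = "inferior_septum"
    out[lat_inf] = "lateral"
    return out.astype(str)


def partition_surface(
    mesh: SurfaceMesh,
    sphere: FittedSphere,
    frame: PatientFrame,
    deviations: DeviationField | None = None,
    bands: BandConfig | None = None,
) -> SegmentLabeling:
    """Label every vertex with its wall segment.

    Vertices excluded by the deviation field (protrusions) are labelled
    ``'excluded'`` and carry no weight in any segmental statistic.
    """
    bands = bands or BandConfig()
    theta, phi = frame.angles(mesh.vertices)
    labels = segment_of_angles(theta, phi, bands)
    if deviations is not None:
        labels = labels.copy()
        labels[~deviations.included] = EXCLUDED_LABEL
    return SegmentLabeling(labels)


# ---------------------------------------------------------------------------
# Segmental deviation


@dataclass
class SegmentalDeviation:
    """Signed area-weighted mean deviation D (mm) and included area (mm²)
    per segment; a segment with zero included area carries D = NaN."""

    deviation: dict[str, float]
    included_area: dict[str, float]

    def as_vector(self) -> np.ndarray:
        return np.array([self.deviation[s] for s in SEGMENTS])


def segmental_deviation(
    field: DeviationField, labeling: SegmentLabeling
) -> SegmentalDeviation:
    """Per-segment D: signed area-weighted mean of d_i over included vertices.

    The area-weighted combination of the six D values over their areas equals
    the whole-surface signed mean (consistency identity used in tests).
    """
    if len(labeling.labels) != len(field.deviations):
        raise ValueError("labeling and deviation field cover different meshes")
    dev: dict[str, float] = {}
    area: dict[str, float] = {}
    for seg in SEGMENTS:
        m = labeling.mask(seg) & field.included
        a = float(field.weights[m].sum())
        area[seg] = a
        if a <= 0.0:
            warnings.warn(f"segment {seg!r} has zero included area", stacklevel=2)
            dev[seg] = float("nan")
        else:
            dev[seg] = float(field.deviations[m] @ field.weights[m] / a)
    return SegmentalDeviation(dev, area)
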