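"""Anterior/posterior volume split and the asymmetry index (ASI).

The atrium dilates non-uniformly — anterior expansion dominates because the
spine and sternum constrain the posterior wall — so the fraction of volume
anterior to a cutting plane is a remodeling surrogate.  The plane is oriented
parallel to the posterior wall (total-least-squares plane through the
posterior-segment vertices) and positioned between the PV ostia and the LAA
ostium; ASI = LA-A / LAV.
"""

from __future__ import annotations

from dataclasses import dataclass


from .atlas import LandmarkSet, SegmentLabeling
from .mesh_core import Plane, SurfaceMesh, clip_volumes_by_plane, fit_plane, mesh_volume


@dataclass(frozen=True)
class AsymmetryResult:
    """Total (LAV), anterior (LA-A) and posterior (LA-P) volumes in mL,
    the asymmetry fraction ASI = LA-A/LAV, and the cutting plane used."""

    total_volume: float
    anterior_volume: float
    posterior_volume: float
    asymmetry_index: float
    cutting_plane: Plane

    @property
    def asymmetry_percent(self) -> float:
        return 100.0 * self.asymmetry_index


def posterior_plane(mesh: SurfaceMesh, labeling: SegmentLabeling,
                    landmarks: LandmarkSet | None = None) -> Plane:
    """Total-least-squares plane through the posterior-segment vertices.

    The normal is oriented anteriorly: toward the LAA ostium when landmarks
    are given, otherwise away from the posterior-vertex centroid relative to
    the whole-mesh centroid.
    """
    mask = labeling.mask("posterior")
    if not mask.any():
        raise ValueError("posterior segment is empty; cannot orient the plane")
    pts = mesh.vertices[mask]
    hint = landmarks.laa_ostium if landmarks is not None else mesh.vertices.mean(axis=0)
    return fit_plane(pts, orientation_hint=hint)


def cutting_plane(
    posterior: Plane, landmarks: LandmarkSet, offset: float = 0.5
) -> Plane:
    """Plane parallel to the posterior wall, between the PV ostia and the LAA.

    ``offset`` interpolates the plane point between the PV-ostia centroid
    (0.0) and the LAA ostium (1.0); the default 0.5 is the midpoint.  The
    normal is flipped if needed so the LAA lies on the positive (anterior)
    side.
    """
    point = (1.0 - offset) * landmarks.pv_centroid + offset * landmarks.laa_ostium
    plane = Plane(posterior.normal, point)
    if plane.signed_distance(landmarks.laa_ostium[None])[0] < 0:
        plane = plane.flipped()
    return plane


def asymmetry_index(mesh: SurfaceMesh, plane: Plane) -> AsymmetryResult:
    """Split the closed mesh by ``plane`` and form ASI = LA-A/LAV.

    LA-A is the volume on the plane's positive (anterior) side; the two part
    volumes sum to the total to machine precision.
    """
    total = mesh_volume(mesh)
    anterior, posterior = clip_volumes_by_plane(mesh, plane)
    return AsymmetryResult(total, anterior, posterior, anterior / total, plane)
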