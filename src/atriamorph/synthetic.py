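"""Synthetic left-atrium generator with analytic ground truth.

Real atrial meshes come from manual CT segmentation and cannot be shipped, so
every stage of the pipeline is exercised on synthetic atria: an icosphere of
patient-specific base radius, radially displaced by smooth per-segment bumps
(raised-cosine angular falloff), isotropic Gaussian surface noise, and
optional narrow outward pulmonary-vein / appendage stubs tall enough to
trigger the >10 mm exclusion rule.  Landmarks are emitted consistently with
the canonical frame the bumps were painted in, and binary per-segment
low-voltage labels are drawn from a logistic model on the absolute local
deformation, so the downstream association statistics have a known ground
truth.

Fit-adjusted truth
------------------
The best-fit sphere absorbs the area-weighted mean of any radial displacement
field into its radius (monopole) and the field's first moment into its centre
(dipole), and more beyond the linear regime.  The generator therefore
reports, per segment, the *fit-adjusted* expected deviation: the segmental
mean of the displacement after removing what the sphere fit will absorb
(linear monopole+dipole prediction, polished to the weighted
orthogonal-least-squares fixed point).  Pipelines are compared against
that, not against the raw bump amplitudes.

All randomness flows from one master seed through ``numpy.random.SeedSequence``
with the patient index as spawn key, so adding a patient never perturbs
earlier patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .atlas import (
    SEGMENTS,
    BandConfig,
    LandmarkSet,
    PatientFrame,
    segment_of_angles,
)
from .mesh_core import MM3_PER_ML, Plane, SurfaceMesh, write_mesh

# canonical generator frame: superior +z, posterior +y, lateral +x
_Z = np.array([0.0, 0.0, 1.0])
_P = np.array([0.0, 1.0, 0.0])
_L = np.array([1.0, 0.0, 0.0])

#: pulmonary-vein stub directions (two superior, two inferior; posterior side)
_PV_DIRECTIONS = ((70.0, 35.0), (70.0, -35.0), (105.0, 35.0), (105.0, -35.0))
_LAA_DIRECTION = (80.0, 135.0)


def _direction(theta_deg: float, phi_deg: float) -> np.ndarray:
    th, ph = np.radians(theta_deg), np.radians(phi_deg)
    return np.cos(th) * _Z + np.sin(th) * (np.cos(ph) * _P + np.sin(ph) * _L)


@dataclass(frozen=True)
class LvaModel:
    """Logistic link from the absolute fit-adjusted segment deviation (mm)
    to low-voltage odds: P(label) = logistic(intercept + slope·|D_seg|)."""

    intercept: float = -1.5
    slope: float = 2.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic atrium.

    ``amplitudes`` are signed per-segment bump heights (mm), ordered as
    :data:`atriamorph.atlas.SEGMENTS`; ``elongation`` is the amplitude (mm,
    at the lateral pole) of the anisotropic stretch that emulates the
    anterolateral bulging / posterior-superior flattening of the constrained
    dilating atrium — a quadrupolar deformation the best-fit sphere cannot
    absorb.  ``bump_falloff`` is the angular width (degrees) of the
    raised-cosine edge of each segment bump; ``noise_sigma`` the per-vertex
    radial noise SD (mm); stub heights are measured radially outward from
    the base sphere.
    """

    base_radius: float = 32.0
    amplitudes: tuple[float, ...] = (0.0,) * 6
    elongation: float = 0.0
    bump_falloff: float = 25.0
    noise_sigma: float = 0.0
    subdivisions: int = 4
    pv_stubs: int = 0  # number of pulmonary-vein stubs, 0..4
    laa_stub: bool = False
    stub_height: float = 15.0
    stub_falloff: float = 8.0
    flatten_posterior: bool = False
    flatten_fraction: float = 0.85
    lva_model: LvaModel = field(default_factory=LvaModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if self.subdivisions < 2:
            raise ValueError("subdivisions must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if len(self.amplitudes) != 6:
            raise ValueError("need exactly 6 segment amplitudes")
        if np.max(np.abs(self.amplitudes)) + abs(self.elongation) >= self.base_radius:
            raise ValueError(
                "deformation amplitudes must stay below base_radius "
                "(the surface would self-intersect)"
            )


@dataclass
class SyntheticTruth:
    """Ground truth carried next to each generated atrium."""

    amplitudes: np.ndarray  # raw signed bump amplitudes (6,)
    expected_deviation: np.ndarray  # fit-adjusted per-segment D (6,)
    posterior_plane: Plane | None
    landmarks: LandmarkSet
    lva_labels: np.ndarray  # (6,) of {0, 1}
    lva_segment_count: int
    base_radius: float
    elongation: float = 0.0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "segments": list(SEGMENTS),
                    "amplitudes_mm": self.amplitudes.tolist(),
                    "elongation_mm": self.elongation,
                    "expected_deviation_mm": self.expected_deviation.tolist(),
                    "lva_labels": self.lva_labels.tolist(),
                    "lva_segment_count": self.lva_segment_count,
                    "base_radius_mm": self.base_radius,
                },
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# Geometry helpers


def _template(subdivisions: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit icosphere directions, faces and barycentric vertex weights."""
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    dirs = ico.vertices.view(np.ndarray)
    faces = ico.faces.view(np.ndarray)
    areas = np.zeros(len(dirs))
    t = dirs[faces]
    fa = 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
    np.add.at(areas, faces.ravel(), np.repeat(fa / 3.0, 3))
    return dirs, faces, areas / areas.sum()


def _raised_cosine(cosang: np.ndarray, falloff_deg: float) -> np.ndarray:
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    w = np.where(ang < falloff_deg, 0.5 * (1.0 + np.cos(np.pi * ang / falloff_deg)), 0.0)
    return w


def _elongation_field(dirs: np.ndarray) -> np.ndarray:
    """Unit quadrupolar stretch: outward along the lateral axis, flattened
    posteriorly and superior-inferiorly (relative weights 1 : −0.5 : −0.8).
    Scaled by ``SyntheticSpec.elongation`` (mm at the lateral pole)."""
    return dirs[:, 0] ** 2 - 0.5 * dirs[:, 1] ** 2 - 0.8 * dirs[:, 2] ** 2


def _stub_profile(cosang: np.ndarray, falloff_deg: float, plateau: float = 0.6) -> np.ndarray:
    """Cylinder-like stub: full height inside ``plateau``·falloff, raised-
    cosine edge to zero at ``falloff``.  PV stumps and the appendage neck are
    steep-walled, so only a narrow skirt stays below the exclusion
    threshold."""
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    edge0 = plateau * falloff_deg
    t = np.clip((ang - edge0) / (falloff_deg - edge0), 0.0, 1.0)
    return np.where(ang < falloff_deg, 0.5 * (1.0 + np.cos(np.pi * t)), 0.0)


def _bump_basis(
    dirs: np.ndarray, labels: np.ndarray, falloff_deg: float
) -> np.ndarray:
    """(n, 6) per-segment deformation weights at the template directions.

    Each segment's weight is a smoothed indicator: 1 inside the segment,
    raised-cosine decay to 0 over ``falloff_deg`` of geodesic angle outside.
    Deformation therefore fills its segment (as wall remodeling does) while
    staying C¹-smooth across boundaries, and segmental ground-truth means
    stay analytic up to quadrature on the template.
    """
    cosang = np.clip(dirs @ dirs.T, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    cols = []
    for seg in SEGMENTS:
        inside = labels == seg
        d = ang[:, inside].min(axis=1)
        d[inside] = 0.0
        w = np.where(
            d < falloff_deg, 0.5 * (1.0 + np.cos(np.pi * d / falloff_deg)), 0.0
        )
        cols.append(w)
    return np.column_stack(cols)


def _fit_projection(dirs: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """(n, n) projector removing the monopole+dipole (sphere-fit) components
    of a radial displacement field, in the area-weighted inner product."""
    A = np.column_stack([np.ones(len(dirs)), dirs])  # [1, u]
    AtW = A.T * weights
    coef = np.linalg.solve(AtW @ A, AtW)
    return np.eye(len(dirs)) - A @ coef


def _segment_mean_operator(
    dirs: np.ndarray, weights: np.ndarray, bands: BandConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(6, n) area-weighted segmental-mean operator and the label array."""
    frame = PatientFrame(np.zeros(3), _Z, _P, _L)
    theta, phi = frame.angles(dirs)
    labels = segment_of_angles(theta, phi, bands)
    rows = []
    for seg in SEGMENTS:
        m = labels == seg
        w = np.where(m, weights, 0.0)
        rows.append(w / w.sum())
    return np.vstack(rows), labels


def _fit_adjusted_truth(
    dirs: np.ndarray,
    weights: np.ndarray,
    bump: np.ndarray,
    base_radius: float,
    inferior_reference: np.ndarray,
    pv_centroid: np.ndarray,
    laa_ostium: np.ndarray,
    bands: BandConfig,
) -> np.ndarray:
    """Expected per-segment deviation after best-fit-sphere absorption.

    The sphere the fit will settle on is predicted from the bump field
    alone: the linear (monopole + dipole) projection gives the starting
    radius and centre shifts, which are then polished to the weighted
    orthogonal-least-squares fixed point (the linearisation underestimates
    the radius by O(|centre shift|²/AR) once the dipole is strong).
    Deviations, the anatomical frame and the segment labels are recomputed
    around that predicted centre, because the partition moves with the
    fitted centre and segment means are sensitive to boundary migration.
    """
    A = np.column_stack([np.ones(len(dirs)), dirs])
    AtW = A.T * weights
    coef = np.linalg.solve(AtW @ A, AtW @ bump)
    center = coef[1:]

    verts = (base_radius + bump)[:, None] * dirs
    wsum = weights / weights.sum()
    radius = base_radius + coef[0]
    for _ in range(100):
        diff = verts - center
        dist = np.linalg.norm(diff, axis=1)
        u = diff / dist[:, None]
        ubar = wsum @ u
        vbar = wsum @ verts
        radius_new = (wsum @ np.einsum("ij,ij->i", u, verts) - ubar @ vbar) / (
            1.0 - ubar @ ubar
        )
        center_new = vbar - radius_new * ubar
        if (
            np.linalg.norm(center_new - center) < 1e-9
            and abs(radius_new - radius) < 1e-9
        ):
            center, radius = center_new, radius_new
            break
        center, radius = center_new, radius_new
    dev = np.linalg.norm(verts - center, axis=1) - radius

    z = center - inferior_reference
    z = z / np.linalg.norm(z)
    p = pv_centroid - center
    p = p - (p @ z) * z
    p = p / np.linalg.norm(p)
    l = np.cross(z, p)
    if (laa_ostium - center) @ l < 0:
        l = -l
    frame = PatientFrame(center, z, p, l)
    theta, phi = frame.angles(verts)
    labels = segment_of_angles(theta, phi, bands)

    out = np.empty(6)
    for j, seg in enumerate(SEGMENTS):
        m = labels == seg
        w = weights[m]
        out[j] = dev[m] @ w / w.sum() if w.sum() > 0 else np.nan
    return out


class _TemplateCache:
    """Per-(subdivision, falloff, bands) cached geometry operators."""

    def __init__(self) -> None:
        self._cache: dict[tuple, tuple] = {}

    def get(self, subdivisions: int, falloff: float, bands: BandConfig):
        key = (subdivisions, falloff, bands)
        if key not in self._cache:
            dirs, faces, w = _template(subdivisions)
            proj = _fit_projection(dirs, w)
            segop, labels = _segment_mean_operator(dirs, w, bands)
            basis = _bump_basis(dirs, labels, falloff)
            self._cache[key] = (dirs, faces, w, basis, proj, segop, labels)
        return self._cache[key]


_TEMPLATES = _TemplateCache()


# ---------------------------------------------------------------------------
# Single-atrium generation


def generate_la_mesh(
    spec: SyntheticSpec, bands: BandConfig | None = None
) -> tuple[SurfaceMesh, LandmarkSet, SyntheticTruth]:
    """Generate one synthetic atrium with landmarks and ground truth.

    Fully reproducible from ``spec.seed``.
    """
    bands = bands or BandConfig()
    dirs, faces, w, basis, proj, segop, _ = _TEMPLATES.get(
        spec.subdivisions, spec.bump_falloff, bands
    )
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    amplitudes = np.asarray(spec.amplitudes, dtype=float)
    bump = basis @ amplitudes + spec.elongation * _elongation_field(dirs)
    noise = rng.normal(0.0, spec.noise_sigma, len(dirs)) if spec.noise_sigma else 0.0
    radius = spec.base_radius + bump + noise

    n_stubs = int(spec.pv_stubs)
    if not 0 <= n_stubs <= len(_PV_DIRECTIONS):
        raise ValueError("pv_stubs must be in 0..4")
    stub_disp = np.zeros(len(dirs))
    for tp in _PV_DIRECTIONS[:n_stubs]:
        stub_disp += spec.stub_height * _stub_profile(
            dirs @ _direction(*tp), spec.stub_falloff
        )
    if spec.laa_stub:
        stub_disp += spec.stub_height * _stub_profile(
            dirs @ _direction(*_LAA_DIRECTION), spec.stub_falloff
        )
    radius = radius + stub_disp

    truth_plane: Plane | None = None
    if spec.flatten_posterior:
        # project the posterior band radially onto a plane parallel to the
        # canonical posterior wall, at flatten_fraction of the base radius
        d0 = spec.flatten_fraction * spec.base_radius
        truth_plane = Plane(_P, d0 * _P)
        cosp = dirs @ _P
        band = cosp > (d0 / spec.base_radius)
        radius = np.where(band, d0 / np.maximum(cosp, 1e-9), radius)

    if np.any(radius <= 0):
        raise ValueError("spec produced a self-intersecting surface")
    vertices = radius[:, None] * dirs
    mesh = SurfaceMesh(vertices, faces.copy(), name=f"synthetic_{spec.seed:04d}")
    mesh.watertight = True

    pv_pts = np.array(
        [spec.base_radius * _direction(*tp) for tp in _PV_DIRECTIONS]
    )
    laa = spec.base_radius * _direction(*_LAA_DIRECTION)
    inferior = -(spec.base_radius + 10.0) * _Z
    landmarks = LandmarkSet(pv_pts, laa, inferior)

    # fit-adjusted expected D: bump field only (noise and stubs excluded)
    expected = _fit_adjusted_truth(
        dirs, w, bump, spec.base_radius, inferior, pv_pts.mean(axis=0), laa, bands
    )

    # labels couple to the deformation the pipeline can actually observe,
    # i.e. the fit-adjusted deviation, not the raw bump amplitude
    labels = generate_lva_labels(
        expected, spec.lva_model, rng.integers(0, 2**31 - 1)
    )
    truth = SyntheticTruth(
        amplitudes=amplitudes,
        expected_deviation=expected,
        posterior_plane=truth_plane,
        landmarks=landmarks,
        lva_labels=labels,
        lva_segment_count=int(labels.sum()),
        base_radius=spec.base_radius,
        elongation=spec.elongation,
    )
    return mesh, landmarks, truth


def generate_lva_labels(
    amplitudes: np.ndarray, model: LvaModel, seed: int | np.random.Generator
) -> np.ndarray:
    """Bernoulli per-segment low-voltage labels from a logistic model on
    the absolute per-segment deformation; independent across segments given
    the deformations."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (6,):
        raise ValueError("need exactly 6 amplitudes")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(int(seed)))
    )
    logits = model.intercept + model.slope * np.abs(amplitudes)
    p = 1.0 / (1.0 + np.exp(-logits))
    return (rng.random(6) < p).astype(int)


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class CohortDistribution:
    """Patient-to-patient variability of the synthetic cohort.

    Each patient draws a latent remodeling severity ``s ~ Gamma(shape,
    1/shape)`` (mean 1) that scales the patient's entire deformation field —
    the anterolateral elongation and the per-segment bump profile, each with
    its own between-patient noise.  The severity factor is what couples
    deformation magnitude to the number of low-voltage segments across the
    cohort, mirroring the clinical picture in which more remodeled atria
    carry more fibrotic substrate.  The default profile yields fit-adjusted
    segmental deviations with the sign pattern of remodeled atria — inward
    roof and posterior wall, outward inferior and lateral walls — on a base
    radius of 32 ± 4 mm.  Much of any smooth deformation is absorbed by the
    best-fit sphere (its monopole and dipole parts exactly, more near the
    fit's optimum), so raw amplitudes are necessarily larger than the
    deviations they produce, and the segment means carry only the residual;
    the elongation term is quadrupolar precisely because the sphere cannot
    absorb it.
    """

    mean_amplitudes: tuple[float, ...] = (-2.0, -2.0, -4.0, 3.0, 3.0, 0.0)
    amplitude_sd: tuple[float, ...] = (0.8,) * 6
    elongation_mean: float = 4.0
    elongation_sd: float = 0.8
    severity_shape: float = 4.0
    base_radius_mean: float = 32.0
    base_radius_sd: float = 4.0
    noise_sigma: float = 0.3
    subdivisions: int = 4
    lva_model: LvaModel = field(default_factory=LvaModel)


def _patient_spec(
    dist: CohortDistribution, master_seed: int, index: int
) -> SyntheticSpec:
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    rng = np.random.default_rng(ss)
    severity = rng.gamma(dist.severity_shape, 1.0 / dist.severity_shape)
    amps = severity * (
        np.asarray(dist.mean_amplitudes) + rng.normal(0.0, dist.amplitude_sd, 6)
    )
    elong = severity * (
        dist.elongation_mean + rng.normal(0.0, dist.elongation_sd)
    )
    base = float(np.clip(rng.normal(dist.base_radius_mean, dist.base_radius_sd), 20.0, 50.0))
    # keep deformation well below the base radius: the mesh must not
    # self-intersect and the fit-adjusted truth degrades for extreme bumps
    amps = np.clip(amps, -0.3 * base, 0.3 * base)
    elong = float(np.clip(elong, 0.0, 0.3 * base))
    seed = int(rng.integers(0, 2**31 - 1))
    return SyntheticSpec(
        base_radius=base,
        amplitudes=tuple(amps),
        elongation=elong,
        noise_sigma=dist.noise_sigma,
        subdivisions=dist.subdivisions,
        lva_model=dist.lva_model,
        seed=seed,
    )


def generate_cohort(
    n: int,
    dist: CohortDistribution | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    meshes: bool = True,
    bands: BandConfig | None = None,
) -> list[tuple[SurfaceMesh | None, LandmarkSet, np.ndarray, SyntheticTruth]]:
    """Generate ``n`` synthetic patients.

    With ``meshes=False`` only landmarks, labels and ground truth are
    produced (fast path for statistical calibration studies); with
    ``out_dir`` set, a cohort directory ``patient_XXX/{mesh.ply,
    landmarks.json, lva_labels.csv, truth.json}`` plus a root manifest CSV is
    written.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 patients")
    dist = dist or CohortDistribution()
    cohort = []
    manifest = []
    for i in range(n):
        spec = _patient_spec(dist, seed, i)
        if meshes:
            mesh, landmarks, truth = generate_la_mesh(spec, bands=bands)
        else:
            mesh = None
            landmarks, truth = _truth_only(spec, bands=bands)
        cohort.append((mesh, landmarks, truth.lva_labels, truth))
        manifest.append(
            {
                "patient_id": f"patient_{i:03d}",
                "base_radius_mm": truth.base_radius,
                "lva_segment_count": truth.lva_segment_count,
                **{f"amp_{s}": truth.amplitudes[j] for j, s in enumerate(SEGMENTS)},
            }
        )
        if out_dir is not None:
            pdir = Path(out_dir) / f"patient_{i:03d}"
            pdir.mkdir(parents=True, exist_ok=True)
            if mesh is not None:
                write_mesh(mesh, pdir / "mesh.ply")
            landmarks.to_json(pdir / "landmarks.json")
            truth.to_json(pdir / "truth.json")
            pd.DataFrame(
                {"segment": SEGMENTS, "lva": truth.lva_labels}
            ).to_csv(pdir / "lva_labels.csv", index=False)
    if out_dir is not None:
        pd.DataFrame(manifest).to_csv(Path(out_dir) / "manifest.csv", index=False)
    return cohort


def _truth_only(
    spec: SyntheticSpec, bands: BandConfig | None = None
) -> tuple[LandmarkSet, SyntheticTruth]:
    """Ground truth without building mesh vertices.

    Uses a coarse template for the fit-adjustment quadrature (ample for
    segment means) while consuming the random stream exactly as the mesh
    path would, keeping the two paths seed-aligned.
    """
    bands = bands or BandConfig()
    dirs, _, w, basis, proj, segop, _ = _TEMPLATES.get(3, spec.bump_falloff, bands)
    amplitudes = np.asarray(spec.amplitudes, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if spec.noise_sigma:
        # icosphere at level s has 10·4^s + 2 vertices
        rng.normal(0.0, spec.noise_sigma, 10 * 4**spec.subdivisions + 2)
    pv_pts = np.array([spec.base_radius * _direction(*tp) for tp in _PV_DIRECTIONS])
    laa = spec.base_radius * _direction(*_LAA_DIRECTION)
    inferior = -(spec.base_radius + 10.0) * _Z
    landmarks = LandmarkSet(pv_pts, laa, inferior)
    bump = basis @ amplitudes + spec.elongation * _elongation_field(dirs)
    expected = _fit_adjusted_truth(
        dirs, w, bump, spec.base_radius, inferior,
        pv_pts.mean(axis=0), laa, bands,
    )
    labels = generate_lva_labels(
        expected, spec.lva_model, rng.integers(0, 2**31 - 1)
    )
    truth = SyntheticTruth(
        amplitudes=amplitudes,
        expected_deviation=expected,
        posterior_plane=None,
        landmarks=landmarks,
        lva_labels=labels,
        lva_segment_count=int(labels.sum()),
        base_radius=spec.base_radius,
        elongation=spec.elongation,
    )
    return landmarks, truth


def truth_metrics_table(
    cohort: list[tuple[SurfaceMesh | None, LandmarkSet, np.ndarray, SyntheticTruth]],
) -> pd.DataFrame:
    """Cohort metrics table built from generator ground truth alone.

    Used by the statistical calibration studies (type-I error, power), where
    tens of thousands of patients are needed and running the full mesh
    pipeline would add nothing: D comes from the fit-adjusted truth, the
    volumetric/global columns from the analytic sphere of each patient.
    """
    rows = []
    for i, (_, _, labels, truth) in enumerate(cohort):
        r = truth.base_radius
        lav = 4.0 / 3.0 * np.pi * r**3 / MM3_PER_ML
        d = truth.expected_deviation
        s = float(np.mean(np.abs(d)))  # coarse stand-in on the truth scale
        row = {
            "patient_id": f"patient_{i:03d}",
            "LAV": lav,
            "LA_A": lav / 2.0,
            "LA_P": lav / 2.0,
            "ASI": 0.5,
            "AR": r,
            "S": s,
            "LAS": 1.0 - s / r,
        }
        for j, seg in enumerate(SEGMENTS):
            row[f"D_{seg}"] = d[j]
        for j, seg in enumerate(SEGMENTS):
            row[f"lva_{seg}"] = int(labels[j])
        row["lva_segment_count"] = int(truth.lva_segment_count)
        rows.append(row)
    return pd.DataFrame(rows)
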