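"""Patient-specific best-fit sphere, radial deviation field, and sphericity.

The atrium is compared against the sphere that best fits its endocardial
surface.  Two fitting routes are provided:

* :func:`fit_sphere_icp` — iterative closest point: alternate (a) projecting
  each surface vertex onto the current sphere (the closest-point
  correspondence; for a sphere the template's rigid rotation is pure gauge, so
  the effective similarity-transform parameters are the centre and the scale)
  with (b) a least-squares centre/scale update given those correspondences.
* :func:`fit_sphere_algebraic` — the direct linear least-squares fit obtained
  by expanding ``|p - c|² = r²``; used as an independent oracle for the ICP.

Deviations are measured radially, along the ray from the sphere centre
through each vertex: ``d_i = |v_i - c| - AR``, positive outward (convex,
rendered red in deviation maps), negative inward (concave, blue).  Vertices
deviating more than ``exclusion_threshold`` (default 10 mm) outward are
excluded — these are pulmonary-vein stumps and the appendage, which are
protrusions rather than atrial wall.  The mean deviation S is the
area-weighted mean of |d_i| over included vertices and the sphericity index
is ``LAS = 1 - S/AR`` (1 for a perfect sphere).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mesh_core import SurfaceMesh


@dataclass(frozen=True)
class FittedSphere:
    """Best-fit sphere: ``center`` (mm) and average radius ``radius`` (mm)."""

    center: np.ndarray
    radius: float
    iterations: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "center", np.asarray(self.center, dtype=np.float64).reshape(3)
        )
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")


def fit_sphere_algebraic(points: np.ndarray) -> FittedSphere:
    """Direct linear least-squares sphere through ``points``.

    Expanding ``|p - c|² = r²`` gives the linear system
    ``2 p·c + (r² - c·c) = p·p`` in the unknowns ``c`` and ``r² - c·c``.

    Raises
    ------
    ValueError
        For fewer than 4 points or a coplanar configuration.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("sphere fit needs at least 4 points of dimension 3")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("sphere fit: points are coplanar or degenerate")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("sphere fit: degenerate (non-positive squared radius)")
    return FittedSphere(center, float(np.sqrt(r2)))


def fit_sphere_icp(
    mesh: SurfaceMesh | np.ndarray,
    init: FittedSphere | None = None,
    tolerance: float = 1e-10,
    max_iterations: int = 1000,
) -> FittedSphere:
    """Fit a sphere by iterative closest point registration.

    Starting from the area-weighted centroid and mean radial distance, each
    iteration matches every surface vertex with its closest point on the
    current sphere and then re-estimates centre and scale as the similarity
    transform minimising the summed squared mismatch.  Converged when both
    the centre shift and the radius change drop below ``tolerance`` × the
    current radius (a relative criterion, so the fit — and everything
    derived from it, like the sphericity index — is invariant under uniform
    rescaling of the input).

    On zero-residual data (vertices exactly on a sphere) the fixed point is
    exact and coincides with :func:`fit_sphere_algebraic`; on noisy data it is
    the orthogonal-distance (geometric) least-squares sphere.
    """
    if isinstance(mesh, SurfaceMesh):
        pts = mesh.vertices
        w = mesh.vertex_areas()
        if not np.any(w > 0):
            w = np.ones(len(pts))
    else:
        pts = np.asarray(mesh, dtype=np.float64)
        w = np.ones(len(pts))
    if len(pts) < 4:
        raise ValueError("sphere fit needs at least 4 points")
    w = w / w.sum()

    if init is not None:
        center = init.center.copy()
        radius = float(init.radius)
    else:
        center = w @ pts
        radius = float(w @ np.linalg.norm(pts - center, axis=1))
        if radius <= 0:
            raise ValueError("degenerate point set: all points coincide")

    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        diff = pts - center
        dist = np.linalg.norm(diff, axis=1)
        safe = np.maximum(dist, 1e-300)
        u = diff / safe[:, None]  # correspondence directions on the sphere
        # centre/scale update: minimise Σ w_i |v_i - (c + s u_i)|² jointly in
        # c and s; normal equations give c = v̄ - s ū, s = cov(u, v)/(1 - |ū|²)
        ubar = w @ u
        vbar = w @ pts
        s_num = float(w @ np.einsum("ij,ij->i", u, pts) - ubar @ vbar)
        s_den = float(1.0 - ubar @ ubar)
        if s_den <= 1e-15:
            raise ValueError("degenerate correspondence geometry")
        new_radius = s_num / s_den
        new_center = vbar - new_radius * ubar
        shift = float(np.linalg.norm(new_center - center))
        dr = abs(new_radius - radius)
        center, radius = new_center, new_radius
        if shift < tolerance * abs(radius) and dr < tolerance * abs(radius):
            converged = True
            break
    if radius <= 0:
        raise ValueError("ICP sphere fit collapsed to non-positive radius")
    if not converged:
        warnings.warn(
            f"sphere ICP did not converge in {max_iterations} iterations "
            f"(last shift {shift:.2e} mm)",
            stacklevel=2,
        )
    return FittedSphere(center, radius, iterations=it, converged=converged)


# ---------------------------------------------------------------------------
# Deviation field and sphericity


@dataclass
class DeviationField:
    """Signed radial deviation of each vertex from the best-fit sphere.

    ``deviations[i] = |v_i - center| - AR`` (mm, positive outward);
    ``included`` masks out >10 mm protrusions (PV stumps, appendage);
    ``weights`` are barycentric vertex areas (mm²); ``mean_abs_deviation`` is
    S, the area-weighted mean |d_i| over included vertices.
    """

    deviations: np.ndarray
    included: np.ndarray
    weights: np.ndarray
    mean_abs_deviation: float

    @property
    def excluded_area_fraction(self) -> float:
        total = self.weights.sum()
        return float(self.weights[~self.included].sum() / total) if total else 0.0

    def export_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["vertex_id", "deviation_mm", "included"])
            for i, (d, inc) in enumerate(zip(self.deviations, self.included)):
                wr.writerow([i, f"{d:.6f}", int(inc)])


def deviation_field(
    mesh: SurfaceMesh,
    sphere: FittedSphere,
    exclusion_threshold: float = 10.0,
    exclusion_mode: str = "outward",
    area_weighted: bool = True,
) -> DeviationField:
    """Signed radial deviations with protrusion exclusion.

    ``exclusion_mode='outward'`` drops vertices with d_i > +threshold (the
    default: PV stumps and the appendage protrude outward); ``'absolute'``
    drops |d_i| > threshold.
    """
    if exclusion_mode not in ("outward", "absolute"):
        raise ValueError(f"unknown exclusion_mode {exclusion_mode!r}")
    d = np.linalg.norm(mesh.vertices - sphere.center, axis=1) - sphere.radius
    if exclusion_mode == "outward":
        included = d <= exclusion_threshold
    else:
        included = np.abs(d) <= exclusion_threshold
    if not included.any():
        raise ValueError("all vertices excluded by the deviation threshold")
    weights = mesh.vertex_areas() if area_weighted else np.ones(len(d))
    win = weights[included]
    s = float(np.abs(d[included]) @ win / win.sum())
    return DeviationField(d, included, weights, s)


@dataclass(frozen=True)
class SphericityResult:
    """AR (mm), S (mm) and the sphericity fraction LAS = 1 - S/AR."""

    average_radius: float
    mean_deviation: float
    sphericity: float

    @property
    def sphericity_percent(self) -> float:
        return 100.0 * self.sphericity


def sphericity(field: DeviationField, sphere: FittedSphere) -> SphericityResult:
    """LAS = 1 - S/AR; 1 for a perfect sphere, smaller for deformed atria."""
    s = field.mean_abs_deviation
    return SphericityResult(sphere.radius, s, 1.0 - s / sphere.radius)


def export_deviation_ply(
    mesh: SurfaceMesh, field: DeviationField, path: str | Path
) -> None:
    """Write an ascii PLY with a per-vertex ``quality`` scalar holding d_i,
    for colour-mapped rendering of concave (negative) vs convex (positive)
    regions."""
    v, f, d = mesh.vertices, mesh.faces, field.deviations
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(v)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property float quality\n"
            f"element face {len(f)}\n"
            "property list uchar int vertex_indices\nend_header\n"
        )
        for p, q in zip(v, d):
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {q:.6f}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
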