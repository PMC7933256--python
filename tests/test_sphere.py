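"""Best-fit sphere estimators, deviation field and sphericity index."""

import numpy as np
import pytest

from atriamorph import AtrialShapeModel, SyntheticSpec, generate_la_mesh
from atriamorph.sphere import (
    FittedSphere,
    deviation_field,
    fit_sphere_algebraic,
    fit_sphere_icp,
    sphericity,
)

from conftest import random_rotation


def sample_sphere(rng, center, radius, n=800, anisotropy=None):
    u = rng.normal(size=(n, 3))
    if anisotropy is not None:
        u = u + anisotropy  # biased sampling density, still exactly on sphere
    u /= np.linalg.norm(u, axis=1)[:, None]
    return center + radius * u


class TestAlgebraicFit:
    def test_regular_tetrahedron_circumsphere(self):
        center = np.array([3.0, -1.0, 7.0])
        r = 11.0
        tet = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / np.sqrt(3.0)
        sph = fit_sphere_algebraic(center + r * tet)
        assert np.allclose(sph.center, center, atol=1e-9)
        assert sph.radius == pytest.approx(r, abs=1e-9)

    def test_exact_sphere_samples_recovered(self, rng):
        pts = sample_sphere(rng, np.array([-5.0, 2.0, 9.0]), 27.0)
        sph = fit_sphere_algebraic(pts)
        assert np.allclose(sph.center, [-5, 2, 9], atol=1e-9)
        assert sph.radius == pytest.approx(27.0, abs=1e-9)

    def test_coplanar_points_rejected(self, rng):
        pts = np.column_stack([rng.normal(0, 5, 30), rng.normal(0, 5, 30),
                               np.zeros(30)])
        with pytest.raises(ValueError):
            fit_sphere_algebraic(pts)

    def test_least_squares_beats_perturbed_candidates(self, rng):
        pts = sample_sphere(rng, np.zeros(3), 30.0) + rng.normal(0, 0.5, (800, 3))
        sph = fit_sphere_algebraic(pts)

        def algebraic_residual(c, r):
            return np.sum((np.sum((pts - c) ** 2, axis=1) - r**2) ** 2)

        best = algebraic_residual(sph.center, sph.radius)
        for _ in range(100):
            c = sph.center + rng.normal(0, 0.1, 3)
            r = sph.radius + rng.normal(0, 0.1)
            assert algebraic_residual(c, r) >= best - 1e-6 * best


class TestIcpFit:
    def test_exact_sphere_recovered_to_relative_1e9(self, rng):
        center, r = np.array([12.0, -7.0, 3.0]), 28.0
        pts = sample_sphere(rng, center, r, n=2000)
        sph = fit_sphere_icp(pts)
        assert sph.converged
        assert np.linalg.norm(sph.center - center) / r < 1e-9
        assert abs(sph.radius - r) / r < 1e-9

    def test_noisy_sphere_center_and_radius_within_005mm(self, rng):
        center, r = np.array([3.0, -4.0, 5.0]), 32.0
        pts = sample_sphere(rng, center, r, n=10_000)
        pts = pts + rng.normal(0, 0.5, pts.shape)
        sph = fit_sphere_icp(pts)
        assert np.linalg.norm(sph.center - center) < 0.05
        assert abs(sph.radius - r) < 0.05

    def test_matches_algebraic_oracle_on_exact_spheres(self, rng):
        for _ in range(10):
            center = rng.normal(0, 50, 3)
            r = rng.uniform(20, 45)
            pts = sample_sphere(
                rng, center, r, n=600, anisotropy=rng.normal(0, 1, 3)
            )
            alg = fit_sphere_algebraic(pts)
            icp = fit_sphere_icp(pts)
            assert np.linalg.norm(icp.center - alg.center) < 1e-6 * alg.radius
            assert abs(icp.radius - alg.radius) < 1e-6 * alg.radius

    def test_non_convergence_warns_and_flags(self, rng):
        pts = sample_sphere(rng, np.zeros(3), 30.0, n=500)
        pts = pts + rng.normal(0, 2.0, pts.shape)
        with pytest.warns(UserWarning, match="did not converge"):
            sph = fit_sphere_icp(pts, max_iterations=2)
        assert not sph.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sphere_icp(np.eye(3))


class TestDeviationField:
    def test_zero_on_its_own_sphere(self, icosphere32):
        mesh, _ = icosphere32
        sph = fit_sphere_icp(mesh)
        field = deviation_field(mesh, sph)
        assert np.all(np.abs(field.deviations) < 1e-9)
        assert field.mean_abs_deviation < 1e-9

    def test_definitional_identity(self, deformed_atrium):
        mesh, _, _ = deformed_atrium
        sph = fit_sphere_icp(mesh)
        field = deviation_field(mesh, sph)
        expected = np.linalg.norm(mesh.vertices - sph.center, axis=1) - sph.radius
        assert np.allclose(field.deviations, expected, atol=1e-12)

    def test_signed_values_follow_radial_offsets(self, icosphere32):
        mesh, _ = icosphere32
        m = mesh.copy()
        u = m.vertices / np.linalg.norm(m.vertices, axis=1)[:, None]
        m.vertices = m.vertices + 3.0 * u  # radius 35 everywhere
        sph = FittedSphere(np.zeros(3), 32.0)
        field = deviation_field(m, sph)
        assert np.allclose(field.deviations, 3.0, atol=1e-9)
        m.vertices = m.vertices - 5.0 * u  # radius 30
        field = deviation_field(m, sph)
        assert np.allclose(field.deviations, -2.0, atol=1e-9)

    @pytest.mark.parametrize(
        "mode,expected_excluded",
        [("outward", {1}), ("absolute", {1, 2})],
    )
    def test_threshold_semantics(self, icosphere32, mode, expected_excluded):
        # deviations {+2, +11, -12, +9} on four chosen vertices
        mesh, _ = icosphere32
        m = mesh.copy()
        u = m.vertices / np.linalg.norm(m.vertices, axis=1)[:, None]
        offsets = {0: 2.0, 1: 11.0, 2: -12.0, 3: 9.0}
        for idx, off in offsets.items():
            m.vertices[idx] += off * u[idx]
        field = deviation_field(m, FittedSphere(np.zeros(3), 32.0), 10.0, mode)
        excluded = set(np.nonzero(~field.included)[0])
        assert excluded == expected_excluded

    def test_all_vertices_excluded_is_an_error(self, icosphere32):
        mesh, _ = icosphere32
        with pytest.raises(ValueError):
            deviation_field(mesh, FittedSphere(np.zeros(3), 10.0), 10.0, "outward")

    def test_excluded_vertices_carry_no_weight_in_s(self, icosphere32):
        mesh, _ = icosphere32
        m = mesh.copy()
        u = m.vertices / np.linalg.norm(m.vertices, axis=1)[:, None]
        m.vertices[:10] += 20.0 * u[:10]  # excluded protrusion
        field = deviation_field(m, FittedSphere(np.zeros(3), 32.0))
        win = field.weights[field.included]
        manual = np.abs(field.deviations[field.included]) @ win / win.sum()
        assert field.mean_abs_deviation == pytest.approx(manual, rel=1e-12)
        assert field.excluded_area_fraction > 0


class TestSphericity:
    def test_perfect_sphere_limit(self, icosphere32):
        mesh, _ = icosphere32
        sph = fit_sphere_icp(mesh)
        result = sphericity(deviation_field(mesh, sph), sph)
        assert result.sphericity > 0.9999

    def test_formula_on_cohort_scale_values(self):
        # AR = 32 mm, S = 6 mm  ->  LAS = 1 - 6/32 = 0.8125
        sph = FittedSphere(np.zeros(3), 32.0)
        from atriamorph.sphere import DeviationField

        f = DeviationField(np.array([6.0]), np.array([True]), np.array([1.0]), 6.0)
        result = sphericity(f, sph)
        assert result.sphericity == pytest.approx(0.8125, abs=1e-12)
        assert result.sphericity_percent == pytest.approx(81.25, abs=1e-9)

    def test_s_equal_ar_gives_zero(self):
        from atriamorph.sphere import DeviationField

        sph = FittedSphere(np.zeros(3), 30.0)
        f = DeviationField(np.array([30.0]), np.array([True]), np.array([1.0]), 30.0)
        assert sphericity(f, sph).sphericity == pytest.approx(0.0, abs=1e-12)


class TestInvariances:
    def test_scale_equivariance_and_rigid_invariance(self, deformed_atrium, rng):
        mesh, _, _ = deformed_atrium
        sph = fit_sphere_icp(mesh)
        f = deviation_field(mesh, sph)
        las0 = sphericity(f, sph).sphericity
        k = 1.9
        R = random_rotation(rng)
        t = rng.normal(0, 40, 3)
        m = mesh.copy()
        m.vertices = k * (m.vertices @ R.T) + t
        sph2 = fit_sphere_icp(m)
        f2 = deviation_field(m, sph2, exclusion_threshold=10.0 * k)
        assert sph2.radius == pytest.approx(k * sph.radius, rel=1e-9)
        assert f2.mean_abs_deviation == pytest.approx(
            k * f.mean_abs_deviation, rel=1e-9
        )
        assert sphericity(f2, sph2).sphericity == pytest.approx(las0, abs=1e-9)

    def test_uniform_inflation_absorbed_by_refit(self, deformed_atrium):
        # uniform weights throughout: inflating the surface changes the
        # area quadrature, and the absorption identity is about the fit
        mesh, _, _ = deformed_atrium
        sph = fit_sphere_icp(mesh.vertices)
        f = deviation_field(mesh, sph, area_weighted=False)
        m = mesh.copy()
        u = m.vertices - sph.center
        u /= np.linalg.norm(u, axis=1)[:, None]
        m.vertices = m.vertices + 4.0 * u  # constant radial inflation
        sph2 = fit_sphere_icp(m.vertices)
        f2 = deviation_field(m, sph2, area_weighted=False)
        assert sph2.radius == pytest.approx(sph.radius + 4.0, abs=1e-6)
        assert np.allclose(f2.deviations, f.deviations, atol=1e-6)
        assert f2.mean_abs_deviation == pytest.approx(
            f.mean_abs_deviation, abs=1e-6
        )

    def test_s_monotone_in_deformation_amplitude(self, icosphere32):
        mesh, _ = icosphere32
        sph = FittedSphere(np.zeros(3), 32.0)
        u = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1)[:, None]
        pattern = np.sin(3.0 * mesh.vertices[:, 2] / 32.0)  # fixed shape
        last = -1.0
        for k in (0.0, 0.5, 1.0, 2.0, 4.0):
            m = mesh.copy()
            m.vertices = m.vertices + (k * pattern)[:, None] * u
            s = deviation_field(m, sph).mean_abs_deviation
            assert s >= last - 1e-12
            last = s
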